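"""ROC/AUC evaluation for multi-label predictions.

Per-class AUCs use the one-vs-all construction. ``auc_binary`` is the
rank-based (Mann-Whitney) statistic with half credit for ties, which equals
the trapezoidal area under the empirical ROC curve. The macro average is the
mean of the defined per-class AUCs; the micro average pools every
(sample, class) pair of the defined classes into one binary problem — macro
weights each disease equally, micro weights each decision equally, and the
two can differ substantially under class imbalance.

Classes whose label column is all-positive or all-negative have no defined
AUC; they are reported in ``excluded_classes`` and skipped by both averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .exceptions import ShapeError
from .losses import LabelMatrix

__all__ = ["EvalReport", "auc_binary", "roc_points_binary", "multilabel_auc"]

logger = logging.getLogger(__name__)


def auc_binary(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic.

    Ties between a positive and a negative score count one half. Returns
    ``nan`` (the undefined-AUC signal) when only one class is present.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.shape != y.shape:
        raise ShapeError(f"scores shape {s.shape} != labels shape {y.shape}")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks -> half credit for ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points_binary(scores, labels) -> np.ndarray:
    """Empirical ROC as an array of (fpr, tpr) pairs from (0,0) to (1,1)."""
    fpr, tpr, _ = roc_curve(np.asarray(labels).ravel(),
                            np.asarray(scores, dtype=float).ravel(),
                            drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], (0.0, 0.0)):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


@dataclass
class EvalReport:
    """Per-class, macro and micro AUC plus ROC point lists."""

    per_class_auc: dict[str, float]
    macro_auc: float
    micro_auc: float
    roc_points: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_classes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c, "auc": v, "excluded": c in self.excluded_classes}
                for c, v in self.per_class_auc.items()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_class_auc": {k: (None if np.isnan(v) else float(v))
                              for k, v in self.per_class_auc.items()},
            "macro_auc": float(self.macro_auc),
            "micro_auc": float(self.micro_auc),
            "excluded_classes": list(self.excluded_classes),
        }

    def roc_frame(self) -> pd.DataFrame:
        rows = []
        for cls, pts in self.roc_points.items():
            for fpr, tpr in pts:
                rows.append({"class": cls, "fpr": fpr, "tpr": tpr})
        return pd.DataFrame(rows)


def multilabel_auc(scores, labels, with_roc: bool = False) -> EvalReport:
    """One-vs-all evaluation of an [N x C] score matrix.

    Parameters
    ----------
    scores : array [N, C] of per-class scores (any monotone scale).
    labels : :class:`LabelMatrix` or a pair-compatible binary array.
    with_roc : also collect per-class ROC point lists (off by default; they
        are large).
    """
    if isinstance(labels, LabelMatrix):
        y, names = labels.y, labels.class_names
    else:
        y = np.asarray(labels)
        names = [f"class_{i}" for i in range(y.shape[1])]
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ShapeError(f"scores shape {s.shape} != labels shape {y.shape}")

    per_class: dict[str, float] = {}
    roc: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    defined_cols = []
    for c, name in enumerate(names):
        a = auc_binary(s[:, c], y[:, c])
        per_class[name] = a
        if np.isnan(a):
            excluded.append(name)
            logger.warning("class %r has a single label value; AUC undefined, excluded", name)
        else:
            defined_cols.append(c)
            if with_roc:
                roc[name] = roc_points_binary(s[:, c], y[:, c])

    if defined_cols:
        macro = float(np.mean([per_class[names[c]] for c in defined_cols]))
        micro = auc_binary(s[:, defined_cols].ravel(), y[:, defined_cols].ravel())
    else:
        macro = micro = float("nan")
    return EvalReport(per_class_auc=per_class, macro_auc=macro, micro_auc=micro,
                      roc_points=roc, excluded_classes=excluded)
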