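"""Multi-label classification loss and the combined training objective.

The classification loss is a bias focal loss: per sample and class, with
sigmoid probability p and binary label y,

    -alpha * (1-p)^lambda_l * y * log(p)  -  (1-alpha) * p^lambda_l * (1-y) * log(1-p)

averaged over classes (1/C factor) and over the batch. ``alpha`` trades the
positive term against the negative term (class-imbalance control); the
per-scale exponent ``lambda_l`` down-weights easy samples, focal-loss style.
With lambda_l = 0 and alpha = 0.5 the loss collapses to half the mean binary
cross-entropy.

The combined objective adds the beta-weighted feature-selection (KL) penalty:

    total = sum_l cls_l + beta * sum_l kl_l

Defaults mirror the reference training recipe: alpha = 0.4, lambda =
(0.5, 0.3, 0.1) for scales (P2, P3, P4), beta = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, InputError, ShapeError

__all__ = [
    "LabelMatrix",
    "PredictionSet",
    "LossConfig",
    "LossBreakdown",
    "bias_focal_loss_scale",
    "classification_loss_total",
    "total_loss",
    "focal_loss_tensor",
]

PROB_EPS = 1e-7


@dataclass
class LabelMatrix:
    """Binary labels [N x C] plus class names."""

    y: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.ndim != 2:
            raise ShapeError(f"LabelMatrix expects [N, C], got {self.y.shape}")
        if not np.isin(self.y, (0, 1)).all():
            raise InputError("LabelMatrix entries must be 0 or 1")
        if len(self.class_names) != self.y.shape[1]:
            raise ShapeError("class_names length must equal the number of label columns")


@dataclass
class PredictionSet:
    """Per-scale sigmoid probabilities, one [N x C] array per active scale."""

    probs_per_scale: list[np.ndarray]
    scales: tuple[str, ...] = ()

    def __post_init__(self):
        self.probs_per_scale = [np.asarray(p) for p in self.probs_per_scale]


@dataclass
class LossConfig:
    """Hyperparameters of the combined objective.

    lambda_mode selects how lambda_l enters: "exponent" is the focal form
    above (the printed definition); "multiplier" instead scales each scale's
    plain loss by lambda_l, provided for sensitivity study.
    """

    alpha: float = 0.4
    lambda_per_scale: tuple[float, ...] = (0.5, 0.3, 0.1)
    beta: float = 0.1
    eps: float = PROB_EPS
    lambda_mode: str = "exponent"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.beta < 0:
            raise ConfigurationError("beta must be nonnegative")
        if self.lambda_mode not in ("exponent", "multiplier"):
            raise ConfigurationError(f"unknown lambda_mode {self.lambda_mode!r}")
        self.lambda_per_scale = tuple(float(v) for v in self.lambda_per_scale)


@dataclass
class LossBreakdown:
    """Per-scale and total loss values; total = cls_total + beta * kl_total."""

    cls_per_scale: list[float]
    kl_per_scale: list[float]
    beta: float
    cls_total: float = field(init=False)
    kl_total: float = field(init=False)
    total: float = field(init=False)

    def __post_init__(self):
        self.cls_per_scale = [float(v) for v in self.cls_per_scale]
        self.kl_per_scale = [float(v) for v in self.kl_per_scale]
        self.cls_total = float(sum(self.cls_per_scale))
        self.kl_total = float(sum(self.kl_per_scale))
        self.total = self.cls_total + self.beta * self.kl_total


def _as_labels(labels) -> np.ndarray:
    return labels.y if isinstance(labels, LabelMatrix) else np.asarray(labels)


def bias_focal_loss_scale(probs: np.ndarray, labels, alpha: float, lambda_l: float,
                          eps: float = PROB_EPS, lambda_mode: str = "exponent") -> float:
    """Bias focal loss for one scale, averaged over the batch.

    `probs` are sigmoid outputs in [0, 1]; they are clamped to
    [eps, 1 - eps] before the logarithms.
    """
    p = np.asarray(probs, dtype=float)
    y = _as_labels(labels).astype(float)
    if p.ndim == 1:
        p = p[None, :]
    if y.ndim == 1:
        y = y[None, :]
    if p.shape != y.shape:
        raise ShapeError(f"probs shape {p.shape} does not match labels shape {y.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("probabilities must lie in [0, 1] before clamping")
    p = np.clip(p, eps, 1.0 - eps)
    lam = float(lambda_l)
    if lambda_mode == "exponent":
        pos = -alpha * (1.0 - p) ** lam * y * np.log(p)
        neg = -(1.0 - alpha) * p ** lam * (1.0 - y) * np.log(1.0 - p)
        per_sample = (pos + neg).mean(axis=1)  # the 1/C class average
    elif lambda_mode == "multiplier":
        pos = -alpha * y * np.log(p)
        neg = -(1.0 - alpha) * (1.0 - y) * np.log(1.0 - p)
        per_sample = lam * (pos + neg).mean(axis=1)
    else:
        raise ConfigurationError(f"unknown lambda_mode {lambda_mode!r}")
    return float(per_sample.mean())


def classification_loss_total(preds: PredictionSet, labels, cfg: LossConfig) -> float:
    """Sum of per-scale bias focal losses over the active scales."""
    lams = cfg.lambda_per_scale[: len(preds.probs_per_scale)]
    if len(preds.probs_per_scale) != len(lams):
        raise ConfigurationError(
            f"{len(preds.probs_per_scale)} scales supplied but only "
            f"{len(cfg.lambda_per_scale)} lambda values configured")
    return float(sum(
        bias_focal_loss_scale(p, labels, cfg.alpha, lam, cfg.eps, cfg.lambda_mode)
        for p, lam in zip(preds.probs_per_scale, lams)))


def total_loss(cls_per_scale, kl_per_scale, beta: float) -> LossBreakdown:
    """Assemble the beta-weighted combined objective.

    Scalars are accepted for single-scale (or pre-summed) losses.
    """
    if beta < 0:
        raise ConfigurationError("beta must be nonnegative")
    if np.isscalar(cls_per_scale):
        cls_per_scale = [cls_per_scale]
    if np.isscalar(kl_per_scale):
        kl_per_scale = [kl_per_scale]
    return LossBreakdown(cls_per_scale=list(cls_per_scale),
                         kl_per_scale=list(kl_per_scale), beta=float(beta))


# ---------------------------------------------------------------------------
# differentiable route used by the training loop
# ---------------------------------------------------------------------------

def focal_loss_tensor(probs: Tensor, y: np.ndarray, alpha: float, lambda_l: float,
                      eps: float = PROB_EPS, lambda_mode: str = "exponent") -> Tensor:
    """Tensor version of :func:`bias_focal_loss_scale` (same reduction)."""
    y = np.asarray(y, dtype=probs.data.dtype)
    p = ad.clip(probs, eps, 1.0 - eps)
    yw = Tensor(y)
    nw = Tensor(1.0 - y)
    lam = float(lambda_l)
    if lambda_mode == "exponent":
        pos = (yw * ((1.0 - p) ** lam) * ad.log(p)) * (-alpha)
        neg = (nw * (p ** lam) * ad.log(1.0 - p)) * (-(1.0 - alpha))
        return (pos + neg).mean()
    pos = (yw * ad.log(p)) * (-alpha)
    neg = (nw * ad.log(1.0 - p)) * (-(1.0 - alpha))
    return ((pos + neg) * lam).mean()
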