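"""End-to-end training with early stopping, plus sweep experiment runners.

The loop optimizes the combined objective (bias focal classification loss
plus the beta-weighted patch-level KL penalty) with Adam, decays the learning
rate multiplicatively on a fixed epoch schedule, evaluates validation AUC
after every epoch and keeps the best-scoring snapshot (early stopping: the
returned model is never the last epoch unless the last epoch is the best).

One master seed fans out into independent streams for weight initialization,
batch shuffling, augmentation and the reparameterization noise, so a run is
exactly reproducible from (configs, seed).

Defaults mirror the reference recipe: lr 1e-4, batch size 64, x0.9 decay
every 2 epochs, 20 epochs, Adam.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.transform import resize

from .autodiff import Adam, Tensor, no_grad
from .evaluation import EvalReport, multilabel_auc
from .exceptions import ConfigurationError, InputError, NumericalError
from .losses import LossConfig, focal_loss_tensor, bias_focal_loss_scale
from .model import (IMAGE_MEAN, IMAGE_STD, ModelConfig, PVIBClassifier, build_model,
                    combine_scale_predictions)
from .losses import PredictionSet
from .synthdata import LabeledImageSet
from .vib import GaussianField, kl_loss_scale, kl_penalty_tensor

__all__ = [
    "TrainConfig",
    "RunHistory",
    "AugmentedImages",
    "train_model",
    "predict_probs",
    "evaluate_model",
    "subsample_fraction",
    "beta_sweep",
    "fraction_sweep",
]

logger = logging.getLogger(__name__)

RESIZE_RATIO = 256.0 / 224.0  # enlarge-then-crop ratio of the augmentation recipe


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    lr_decay: float = 0.9
    lr_decay_every: int = 2
    epochs: int = 20
    seed: int = 0
    early_stop_metric: str = "micro_auc"
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.early_stop_metric not in ("micro_auc", "macro_auc"):
            raise ConfigurationError(f"unknown early_stop_metric {self.early_stop_metric!r}")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunHistory:
    """Per-epoch diagnostics plus the early-stopping outcome."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_val_auc: float = -math.inf
    metric: str = "micro_auc"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def val_auc_series(self) -> list[float]:
        return [r["val_auc"] for r in self.records]


# ---------------------------------------------------------------------------
# augmentation pipeline
# ---------------------------------------------------------------------------

class AugmentedImages:
    """Enlarge-then-crop augmentation over a :class:`LabeledImageSet`.

    Images are resized once to crop_size * 256/224 and cached; training
    batches take a random crop, a horizontal flip (p = 0.5) and a contrast
    jitter in [0.9, 1.1]; evaluation uses the deterministic center crop with
    no flip or jitter. (Saturation/hue jitter from the recipe are identity
    operations on grayscale images.) Output is normalized float32
    [N, 1, crop, crop].
    """

    def __init__(self, dataset: LabeledImageSet, crop_size: int | None = None):
        if len(dataset) == 0:
            raise InputError("dataset is empty")
        self.labels = dataset.labels.astype(np.float32)
        self.class_names = list(dataset.class_names)
        h, w = dataset.images.shape[1:]
        self.crop = int(crop_size or min(h, w))
        self.big = int(round(self.crop * RESIZE_RATIO))
        if (h, w) == (self.big, self.big):
            base = dataset.images
        else:
            base = np.empty((len(dataset), self.big, self.big), dtype=np.uint8)
            for i in range(len(dataset)):
                r = resize(dataset.images[i].astype(np.float32) / 255.0,
                           (self.big, self.big), order=1, preserve_range=True,
                           anti_aliasing=False)
                base[i] = np.round(np.clip(r, 0.0, 1.0) * 255.0).astype(np.uint8)
        self.base = base
        off = (self.big - self.crop) // 2
        self._eval_cache = self._normalize(
            self.base[:, off:off + self.crop, off:off + self.crop].astype(np.float32) / 255.0)

    def __len__(self) -> int:
        return self.base.shape[0]

    @staticmethod
    def _normalize(x: np.ndarray) -> np.ndarray:
        return ((x - IMAGE_MEAN) / IMAGE_STD).astype(np.float32)[:, None, :, :]

    def eval_batch(self, indices) -> np.ndarray:
        return self._eval_cache[np.asarray(indices)]

    def train_batch(self, indices, rng: np.random.Generator) -> np.ndarray:
        idx = np.asarray(indices)
        span = self.big - self.crop
        out = np.empty((len(idx), self.crop, self.crop), dtype=np.float32)
        tops = rng.integers(0, span + 1, size=len(idx))
        lefts = rng.integers(0, span + 1, size=len(idx))
        flips = rng.random(len(idx)) < 0.5
        factors = rng.uniform(0.9, 1.1, size=len(idx)).astype(np.float32)
        for j, i in enumerate(idx):
            crop = self.base[i, tops[j]:tops[j] + self.crop,
                             lefts[j]:lefts[j] + self.crop].astype(np.float32) / 255.0
            if flips[j]:
                crop = crop[:, ::-1]
            m = crop.mean()
            out[j] = np.clip(m + factors[j] * (crop - m), 0.0, 1.0)
        return self._normalize(out)


# ---------------------------------------------------------------------------
# prediction / evaluation helpers
# ---------------------------------------------------------------------------

def _forward_eval(model: PVIBClassifier, images: np.ndarray, batch_size: int = 128
                  ) -> tuple[list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    probs_chunks: list[list[np.ndarray]] = []
    mus: list[list[np.ndarray]] = []
    sigmas: list[list[np.ndarray]] = []
    for start in range(0, images.shape[0], batch_size):
        batch = Tensor(images[start:start + batch_size])
        with no_grad():
            probs, fields = model.forward(batch, mode="eval")
        probs_chunks.append([p.data for p in probs])
        if fields:
            if not mus:
                mus = [[] for _ in fields]
                sigmas = [[] for _ in fields]
            for k, (mu, sg) in enumerate(fields):
                mus[k].append(mu.data)
                sigmas[k].append(sg.data)
    n_scales = len(probs_chunks[0])
    per_scale = [np.concatenate([c[s] for c in probs_chunks]) for s in range(n_scales)]
    field_arrays = [(np.concatenate(m), np.concatenate(s)) for m, s in zip(mus, sigmas)]
    return per_scale, field_arrays


def predict_probs(model: PVIBClassifier, data: AugmentedImages | LabeledImageSet,
                  batch_size: int = 128) -> np.ndarray:
    """Fused per-class probabilities on the deterministic eval pipeline."""
    if isinstance(data, LabeledImageSet):
        data = AugmentedImages(data)
    per_scale, _ = _forward_eval(model, data.eval_batch(np.arange(len(data))), batch_size)
    pset = PredictionSet(probs_per_scale=per_scale, scales=model.cfg.scales_active)
    return combine_scale_predictions(pset, fusion=model.cfg.fusion)


def evaluate_model(model: PVIBClassifier, dataset: LabeledImageSet,
                   batch_size: int = 128, with_roc: bool = False) -> EvalReport:
    """End-to-end evaluation of a model on a labeled set."""
    probs = predict_probs(model, dataset, batch_size=batch_size)
    return multilabel_auc(probs, dataset.label_matrix, with_roc=with_roc)


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def train_model(train_set: LabeledImageSet, val_set: LabeledImageSet,
                model_cfg: ModelConfig, loss_cfg: LossConfig, train_cfg: TrainConfig,
                ) -> tuple[PVIBClassifier, RunHistory]:
    """Train and return (best-epoch model, run history).

    The model handed back carries the weights of the epoch with the highest
    validation AUC (the configured early-stop metric), not the final epoch.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise InputError("train and validation sets must be nonempty")
    if list(train_set.class_names) != list(val_set.class_names):
        raise InputError("train and validation sets must share the class schema")

    ss = np.random.SeedSequence(train_cfg.seed).spawn(4)
    init_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    rng_shuffle = np.random.default_rng(ss[1])
    rng_eps = np.random.default_rng(ss[2])
    rng_aug = np.random.default_rng(ss[3])

    model = build_model(model_cfg, seed=init_seed)
    params = model.parameters()
    opt = Adam(params, lr=train_cfg.learning_rate)

    train_imgs = AugmentedImages(train_set)
    val_imgs = AugmentedImages(val_set)
    y_train = train_set.labels
    val_labels = val_set.label_matrix

    n_scales = len(model_cfg.scales_active)
    lams = loss_cfg.lambda_per_scale[:n_scales]
    history = RunHistory(metric=train_cfg.early_stop_metric)
    best_state = None

    for epoch in range(1, train_cfg.epochs + 1):
        opt.lr = train_cfg.learning_rate * (
            train_cfg.lr_decay ** ((epoch - 1) // train_cfg.lr_decay_every))
        order = rng_shuffle.permutation(len(train_set))
        cls_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            x = Tensor(train_imgs.train_batch(idx, rng_aug))
            y = y_train[idx]
            probs, fields = model.forward(x, mode="train", rng=rng_eps)
            cls_terms = [focal_loss_tensor(p, y, loss_cfg.alpha, lam, loss_cfg.eps,
                                           loss_cfg.lambda_mode)
                         for p, lam in zip(probs, lams)]
            loss_t = cls_terms[0]
            for t in cls_terms[1:]:
                loss_t = loss_t + t
            cls_value = float(loss_t.data)
            kl_value = 0.0
            if fields:
                kl_terms = [kl_penalty_tensor(mu, sg) for mu, sg in fields]
                kl_t = kl_terms[0]
                for t in kl_terms[1:]:
                    kl_t = kl_t + t
                kl_value = float(kl_t.data)
                if loss_cfg.beta > 0:
                    loss_t = loss_t + kl_t * loss_cfg.beta
            total = cls_value + loss_cfg.beta * kl_value
            if not np.isfinite(total):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch} (cls={cls_value}, kl={kl_value})")
            model.zero_grad()
            loss_t.backward()
            opt.step()
            cls_sum += cls_value
            kl_sum += kl_value
            n_batches += 1

        # validation pass (deterministic: z = mu)
        val_x = val_imgs.eval_batch(np.arange(len(val_set)))
        per_scale, field_arrays = _forward_eval(model, val_x)
        val_cls = float(sum(
            bias_focal_loss_scale(p, val_labels, loss_cfg.alpha, lam, loss_cfg.eps,
                                  loss_cfg.lambda_mode)
            for p, lam in zip(per_scale, lams)))
        val_kl = float(sum(kl_loss_scale(GaussianField(mu=m, sigma=s))
                           for m, s in field_arrays))
        fused = combine_scale_predictions(
            PredictionSet(probs_per_scale=per_scale, scales=model_cfg.scales_active),
            fusion=model_cfg.fusion)
        report = multilabel_auc(fused, val_labels)
        val_auc = report.micro_auc if train_cfg.early_stop_metric == "micro_auc" \
            else report.macro_auc
        history.records.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_cls": cls_sum / n_batches,
            "train_kl": kl_sum / n_batches,
            "val_cls": val_cls,
            "val_kl": val_kl,
            "val_macro_auc": report.macro_auc,
            "val_micro_auc": report.micro_auc,
            "val_auc": val_auc,
        })
        logger.info("epoch %d: train_cls=%.4f train_kl=%.4f val_auc=%.4f",
                    epoch, cls_sum / n_batches, kl_sum / n_batches, val_auc)
        if val_auc > history.best_val_auc:
            history.best_val_auc = float(val_auc)
            history.best_epoch = epoch
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def subsample_fraction(dataset: LabeledImageSet, fraction: float, seed: int
                       ) -> LabeledImageSet:
    """Deterministic subsample of a labeled set (fraction in (0, 1])."""
    if not 0.0 < fraction <= 1.0:
        raise InputError("fraction must lie in (0, 1]")
    n = int(round(fraction * len(dataset)))
    if n < 1:
        raise InputError(f"fraction {fraction} yields an empty subsample")
    if n == len(dataset):
        return dataset
    rng = np.random.default_rng([seed, int(round(fraction * 1_000_000))])
    idx = np.sort(rng.permutation(len(dataset))[:n])
    return dataset.subset(idx)


def beta_sweep(betas: list[float], splits: dict[str, LabeledImageSet],
               model_cfg: ModelConfig, loss_cfg: LossConfig, train_cfg: TrainConfig,
               include_baseline: bool = False
               ) -> tuple[pd.DataFrame, dict[str, RunHistory]]:
    """Train one model per beta (plus an optional VIB-free baseline).

    Returns a table of validation / test micro AUCs and the per-run
    histories (loss-curve diagnostics).
    """
    if not betas and not include_baseline:
        raise ConfigurationError("beta_sweep needs at least one beta")
    rows = []
    histories: dict[str, RunHistory] = {}
    runs: list[tuple[str, ModelConfig, LossConfig]] = []
    if include_baseline:
        base_cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "vib_position": "none"})
        runs.append(("baseline", base_cfg, loss_cfg))
    for b in betas:
        lc = LossConfig(alpha=loss_cfg.alpha, lambda_per_scale=loss_cfg.lambda_per_scale,
                        beta=float(b), eps=loss_cfg.eps, lambda_mode=loss_cfg.lambda_mode)
        runs.append((f"beta={b}", model_cfg, lc))
    for label, mcfg, lcfg in runs:
        model, hist = train_model(splits["train"], splits["val"], mcfg, lcfg, train_cfg)
        histories[label] = hist
        row = {"run": label, "beta": getattr(lcfg, "beta", 0.0),
               "best_epoch": hist.best_epoch, "val_auc": hist.best_val_auc}
        for split_name in splits:
            if split_name.startswith("test"):
                row[f"{split_name}_micro_auc"] = evaluate_model(model, splits[split_name]).micro_auc
        rows.append(row)
    return pd.DataFrame(rows), histories


def fraction_sweep(fractions: list[float], splits: dict[str, LabeledImageSet],
                   model_cfg: ModelConfig, loss_cfg: LossConfig, train_cfg: TrainConfig,
                   ) -> pd.DataFrame:
    """Train on nested subsamples of the training set.

    For each fraction the table reports micro AUC on the (subsampled)
    training set, the validation set and every test split — the shape of the
    source-domain vs shifted-domain generalization experiment.
    """
    rows = []
    for frac in fractions:
        sub = subsample_fraction(splits["train"], frac, seed=train_cfg.seed)
        model, hist = train_model(sub, splits["val"], model_cfg, loss_cfg, train_cfg)
        row = {"fraction": frac, "n_train": len(sub),
               "best_epoch": hist.best_epoch,
               "train_micro_auc": evaluate_model(model, sub).micro_auc,
               "val_micro_auc": evaluate_model(model, splits["val"]).micro_auc}
        for split_name in splits:
            if split_name.startswith("test"):
                row[f"{split_name}_micro_auc"] = evaluate_model(model, splits[split_name]).micro_auc
        rows.append(row)
    return pd.DataFrame(rows)
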