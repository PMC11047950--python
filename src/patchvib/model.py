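"""Model assembly: backbone -> (optional P-VIB) -> neck -> head at three scales.

The architecture follows the multi-scale recipe of modern multi-label
chest-image classifiers: a convolutional backbone exposes feature maps at
pyramid scales P2/P3/P4 (strides 8/16/32 of the input); each active scale is
optionally passed through a P-VIB feature-selection layer, then an
efficient-channel-attention (ECA) neck, then a class-specific residual
attention (CSRA) head, whose logits are squashed by a sigmoid into per-class
probabilities. The P-VIB layer can sit before the neck (the recommended
placement: select features at the pixel level, then fuse non-locally) or
after it, and every block is switchable so the ablation lattice
(+/- neck, +/- multi-scale, VIB position) is reachable from configuration
alone.

The bundled ``small_cnn`` backbone is a compact four-stage stride pyramid
meant for CPU-scale experiments; the named large backbones are registry
hooks for users who bring their own implementation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .exceptions import ConfigurationError, ShapeError
from .losses import PredictionSet
from .vib import GaussianField, PatchVIB

__all__ = [
    "ModelConfig",
    "SmallCNNBackbone",
    "ECANeck",
    "CSRAHead",
    "PVIBClassifier",
    "build_model",
    "model_forward",
    "combine_scale_predictions",
    "save_checkpoint",
    "load_checkpoint",
    "register_backbone",
    "eca_neck",
    "csra_head",
    "backbone_forward",
]

SCALES = ("P2", "P3", "P4")

# user-extensible registry; named large backbones are hooks only
_BACKBONE_REGISTRY: dict[str, type] = {}


def register_backbone(name: str, factory) -> None:
    """Register a backbone constructor ``factory(cfg, rng) -> Module``."""
    _BACKBONE_REGISTRY[name] = factory


@dataclass
class ModelConfig:
    """Architecture switches. P4 must always be active (the single-scale
    ablation keeps only the coarsest head)."""

    num_classes: int = 4
    in_channels: int = 1
    backbone_name: str = "small_cnn"
    backbone_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    scales_active: tuple[str, ...] = ("P2", "P3", "P4")
    vib_position: str = "before_neck"  # before_neck | after_neck | none
    use_neck: bool = True
    vib_out_channels: str | dict = "same"
    head_temperature: float = 0.5
    head_residual_weight: float = 1.0
    head_bias_prior: float = 0.15
    fusion: str = "mean"  # mean | one of the scale names
    image_size: int = 224

    def __post_init__(self):
        self.scales_active = tuple(s for s in SCALES if s in tuple(self.scales_active))
        if not self.scales_active:
            raise ConfigurationError("scales_active must be nonempty")
        if "P4" not in self.scales_active:
            raise ConfigurationError("P4 must be among the active scales")
        if self.vib_position not in ("before_neck", "after_neck", "none"):
            raise ConfigurationError(f"unknown vib_position {self.vib_position!r}")
        if self.fusion not in ("mean",) + SCALES:
            raise ConfigurationError(f"unknown fusion {self.fusion!r}")
        if not 0.0 < self.head_bias_prior < 1.0:
            raise ConfigurationError("head_bias_prior must lie in (0, 1)")
        self.backbone_channels = tuple(int(c) for c in self.backbone_channels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def _conv_init(rng, out_c, in_c, k, dtype=np.float32):
    """He-normal initialization for a ReLU conv layer."""
    std = math.sqrt(2.0 / (in_c * k * k))
    return Parameter(rng.normal(0.0, std, (out_c, in_c, k, k)).astype(dtype))


class GroupNorm(Module):
    """Per-sample group normalization with learnable channel affine."""

    def __init__(self, channels: int, groups: int = 8):
        g = min(groups, channels)
        while channels % g:
            g -= 1
        self.groups = g
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.group_norm(x, self.gamma, self.beta, self.groups)


class SmallCNNBackbone(Module):
    """Four-stage stride pyramid: patchify stem (stride 4), then P2/P3/P4 at 8/16/32.

    Channels default to (16, 32, 64, 128) for (stem, P2, P3, P4). The stem is
    a single 7x7 stride-4 convolution straight from the image; the later
    blocks are conv 3x3 (stride 2) -> group norm -> ReLU. The normalization
    is what lets the network train from scratch in a handful of epochs at the
    small default learning rate.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c0, c1, c2, c3 = cfg.backbone_channels
        self.w_stem = _conv_init(rng, c0, cfg.in_channels, 7)
        self.b_stem = Parameter(np.zeros(c0, dtype=np.float32))
        self.w_p2 = _conv_init(rng, c1, c0, 3)
        self.b_p2 = Parameter(np.zeros(c1, dtype=np.float32))
        self.w_p3 = _conv_init(rng, c2, c1, 3)
        self.b_p3 = Parameter(np.zeros(c2, dtype=np.float32))
        self.w_p4 = _conv_init(rng, c3, c2, 3)
        self.b_p4 = Parameter(np.zeros(c3, dtype=np.float32))
        self.n_stem = GroupNorm(c0)
        self.n_p2, self.n_p3, self.n_p4 = GroupNorm(c1), GroupNorm(c2), GroupNorm(c3)
        self.out_channels = {"P2": c1, "P3": c2, "P4": c3}

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        h = ad.relu(self.n_stem.forward(ad.conv2d(x, self.w_stem, self.b_stem, stride=4, padding=3)))
        p2 = ad.relu(self.n_p2.forward(ad.conv2d(h, self.w_p2, self.b_p2, stride=2, padding=1)))
        p3 = ad.relu(self.n_p3.forward(ad.conv2d(p2, self.w_p3, self.b_p3, stride=2, padding=1)))
        p4 = ad.relu(self.n_p4.forward(ad.conv2d(p3, self.w_p4, self.b_p4, stride=2, padding=1)))
        return {"P2": p2, "P3": p3, "P4": p4}


def _make_backbone(cfg: ModelConfig, rng: np.random.Generator) -> Module:
    if cfg.backbone_name == "small_cnn":
        return SmallCNNBackbone(cfg, rng)
    if cfg.backbone_name in _BACKBONE_REGISTRY:
        return _BACKBONE_REGISTRY[cfg.backbone_name](cfg, rng)
    if cfg.backbone_name in ("res2net50", "resnet50", "densenet121"):
        raise ConfigurationError(
            f"backbone {cfg.backbone_name!r} is an external hook; register an "
            f"implementation with register_backbone() to use it")
    raise ConfigurationError(f"unknown backbone {cfg.backbone_name!r}")


# ---------------------------------------------------------------------------
# neck and head
# ---------------------------------------------------------------------------

def _eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive odd kernel size from the channel count (the published rule)."""
    t = int(abs((math.log2(channels) + b) / gamma))
    return t if t % 2 else t + 1


class ECANeck(Module):
    """Efficient channel attention: GAP -> 1D conv over channels -> sigmoid gate."""

    def __init__(self, channels: int, rng: np.random.Generator, kernel_size: int | None = None):
        if channels < 1:
            raise ConfigurationError("ECANeck needs at least one channel")
        k = kernel_size or _eca_kernel_size(channels)
        if k % 2 == 0:
            raise ConfigurationError("ECA kernel size must be odd")
        self.kernel_size = k
        self.w = Parameter(rng.normal(0.0, 1.0 / math.sqrt(k), (1, 1, k, 1)).astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[:2]
        desc = x.mean(axis=(2, 3))                      # [N, C] channel descriptor
        desc = desc.reshape(n, 1, c, 1)                 # 1D conv over the channel axis
        gate = ad.sigmoid(ad.conv2d(desc, self.w, stride=1,
                                    padding=(self.kernel_size // 2, 0)))
        return x * gate.reshape(n, c, 1, 1)


class CSRAHead(Module):
    """Class-specific residual attention head.

    A 1x1 convolution scores every class at every position; the logit is the
    average-pool score plus ``residual_weight`` times a temperature-softmax
    spatial attention over the same score map. The bias starts at
    logit(bias_prior) so the initial sigmoid outputs match a realistic
    positive rate instead of 0.5 — on imbalanced multi-label targets this
    skips a long calibration phase at the start of training.
    """

    def __init__(self, in_channels: int, num_classes: int, rng: np.random.Generator,
                 temperature: float = 0.5, residual_weight: float = 1.0,
                 bias_prior: float = 0.15):
        if temperature <= 0:
            raise ConfigurationError("head temperature must be positive")
        if not 0.0 < bias_prior < 1.0:
            raise ConfigurationError("bias_prior must lie in (0, 1)")
        std = 1.0 / math.sqrt(in_channels)
        self.w = Parameter(rng.normal(0.0, std, (num_classes, in_channels, 1, 1)).astype(np.float32))
        self.b = Parameter(np.full(num_classes, math.log(bias_prior / (1.0 - bias_prior)),
                                   dtype=np.float32))
        self.temperature = float(temperature)
        self.residual_weight = float(residual_weight)

    def forward(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        k = self.w.data.shape[0]
        score = ad.conv2d(x, self.w, self.b)            # [N, K, h, w]
        hw = score.data.shape[2] * score.data.shape[3]
        flat = score.reshape(n, k, hw)
        base = flat.mean(axis=2)
        att = ad.softmax(flat * (1.0 / self.temperature), axis=2)
        residual = (att * flat).sum(axis=2)
        return base + residual * self.residual_weight


# ---------------------------------------------------------------------------
# assembled classifier
# ---------------------------------------------------------------------------

class PVIBClassifier(Module):
    """The full backbone -> [P-VIB] -> [neck] -> [P-VIB] -> head pipeline."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.backbone = _make_backbone(cfg, rng)
        chan = self.backbone.out_channels
        self.vib_layers: dict[str, PatchVIB] = {}
        self.necks: dict[str, ECANeck] = {}
        self.heads: dict[str, CSRAHead] = {}
        for s in cfg.scales_active:
            c = chan[s]
            if cfg.vib_position != "none":
                out_c = c if cfg.vib_out_channels == "same" else int(cfg.vib_out_channels[s])
                self.vib_layers[s] = PatchVIB(c, out_c, rng=rng)
                c = out_c
            if cfg.use_neck:
                self.necks[s] = ECANeck(c, rng=rng)
            self.heads[s] = CSRAHead(c, cfg.num_classes, rng=rng,
                                     temperature=cfg.head_temperature,
                                     residual_weight=cfg.head_residual_weight,
                                     bias_prior=cfg.head_bias_prior)

    def forward(self, x: Tensor, mode: str = "eval",
                rng: np.random.Generator | None = None
                ) -> tuple[list[Tensor], list[tuple[Tensor, Tensor]]]:
        """Return per-scale probability tensors and per-scale (mu, sigma)."""
        cfg = self.cfg
        feats = self.backbone.forward(x)
        probs: list[Tensor] = []
        fields: list[tuple[Tensor, Tensor]] = []
        for s in cfg.scales_active:
            h = feats[s]
            if cfg.vib_position == "before_neck":
                h, mu, sigma, _ = self.vib_layers[s].forward(h, mode=mode, rng=rng)
                fields.append((mu, sigma))
            if cfg.use_neck:
                h = self.necks[s].forward(h)
            if cfg.vib_position == "after_neck":
                h, mu, sigma, _ = self.vib_layers[s].forward(h, mode=mode, rng=rng)
                fields.append((mu, sigma))
            logits = self.heads[s].forward(h)
            probs.append(ad.sigmoid(logits))
        return probs, fields


def build_model(cfg: ModelConfig, seed: int | None = None) -> PVIBClassifier:
    """Construct a classifier with seeded weight initialization."""
    return PVIBClassifier(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# numpy-facing wrappers
# ---------------------------------------------------------------------------

def _as_batch_tensor(images: np.ndarray, in_channels: int) -> Tensor:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:  # [N, H, W] grayscale
        arr = arr[:, None, :, :]
    if arr.ndim != 4 or arr.shape[1] != in_channels:
        raise ShapeError(f"expected [N, {in_channels}, H, W] images, got {arr.shape}")
    return Tensor(arr)


def backbone_forward(images: np.ndarray, cfg: ModelConfig,
                     model: PVIBClassifier | None = None,
                     seed: int | None = None) -> dict[str, np.ndarray]:
    """Feature maps per active scale as plain arrays (strides 8/16/32)."""
    model = model or build_model(cfg, seed=seed)
    feats = model.backbone.forward(_as_batch_tensor(images, cfg.in_channels))
    return {s: feats[s].data for s in cfg.scales_active}


def eca_neck(feature: np.ndarray, neck: ECANeck) -> np.ndarray:
    """Channel-attention recalibration of a feature batch [N, C, H, W]."""
    return neck.forward(Tensor(np.asarray(feature, dtype=np.float32))).data


def csra_head(feature: np.ndarray, head: CSRAHead) -> np.ndarray:
    """Per-class logits [N, num_classes] from a feature batch."""
    return head.forward(Tensor(np.asarray(feature, dtype=np.float32))).data


def model_forward(model: PVIBClassifier, images: np.ndarray, mode: str = "eval",
                  rng: np.random.Generator | None = None
                  ) -> tuple[PredictionSet, list[GaussianField]]:
    """Run the full pipeline on preprocessed images, returning plain arrays.

    ``images`` must already be normalized float input [N, C, H, W] (or
    [N, H, W] for grayscale); see :func:`prepare_eval_images`.
    """
    x = _as_batch_tensor(images, model.cfg.in_channels)
    probs, fields = model.forward(x, mode=mode, rng=rng)
    pset = PredictionSet(probs_per_scale=[p.data.copy() for p in probs],
                        scales=model.cfg.scales_active)
    gfields = [GaussianField(mu=mu.data[0] if mu.data.shape[0] == 1 else mu.data,
                             sigma=sg.data[0] if sg.data.shape[0] == 1 else sg.data)
               for mu, sg in fields]
    return pset, gfields


def combine_scale_predictions(preds: PredictionSet, fusion: str = "mean") -> np.ndarray:
    """Fuse per-scale probabilities into one [N, C] matrix (mean by default)."""
    if not preds.probs_per_scale:
        raise ConfigurationError("PredictionSet has no scales")
    if fusion == "mean":
        return np.mean(np.stack(preds.probs_per_scale), axis=0)
    if fusion in preds.scales:
        return preds.probs_per_scale[list(preds.scales).index(fusion)]
    raise ConfigurationError(f"unknown fusion {fusion!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

IMAGE_MEAN = 0.5
IMAGE_STD = 0.25


def normalize_images(images_uint8: np.ndarray) -> np.ndarray:
    """uint8 [N, H, W] -> normalized float32 [N, 1, H, W]."""
    x = images_uint8.astype(np.float32) / 255.0
    x = (x - IMAGE_MEAN) / IMAGE_STD
    return x[:, None, :, :]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: PVIBClassifier, extra: dict | None = None) -> None:
    """Serialize weights + ModelConfig (+ optional metadata) into one .npz file."""
    state = model.state_dict()
    meta = {"model_config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[PVIBClassifier, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["model_config"])
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
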