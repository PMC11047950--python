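"""Seeded generator of multi-label lesion images with co-occurrence structure.

The generator emulates the three dataset properties that make multi-label
chest-radiograph classification hard, without requiring any download:

* **co-occurrence** — labels are driven by shared latent factors, so some
  pathologies appear together more often than chance;
* **class imbalance** — per-class positive rates are configurable and include
  a rare class by default;
* **domain shift** — a shifted variant stretches the anatomy horizontally
  (aspect-ratio distortion), moves it off-center and adds extra noise,
  mimicking acquisition differences between institutions.

Label model: each sample draws M binary latent factors z_m ~ Bernoulli(1/2);
class c is positive with probability

    p_c = positive_rate[c] + sum_m loading[m, c] * (z_m - 1/2)

so the marginal positive rate is exactly ``positive_rate[c]`` and classes
loading on a common factor are positively correlated (covariance
loading_1 * loading_2 / 4). Defaults keep every p_c inside [0, 1].

Images are grayscale: a smooth anatomy-like background (vertical gradient,
central bright ellipse, per-image low-frequency field) plus one soft
Gaussian-profile lesion blob per active class at a class-characteristic
location, then speckle noise. Everything is deterministic given the config
seed — identical configs produce byte-identical images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

from .exceptions import ConfigurationError, InputError
from .losses import LabelMatrix

__all__ = [
    "LesionSpec",
    "SynthConfig",
    "DomainShift",
    "LabeledImageSet",
    "sample_labels",
    "generate_dataset",
    "generate_splits",
    "apply_domain_shift",
    "export_manifest",
    "load_manifest",
    "template_match_scores",
]


@dataclass
class LesionSpec:
    """Rendering recipe for one class's lesion blob.

    center: (x, y) location prior as fractions of width/height;
    radius_range: blob sigma range as a fraction of min(H, W);
    contrast: additive peak intensity on the [0, 1] grayscale;
    texture_noise: multiplicative speckle inside the blob.
    """

    center: tuple[float, float]
    radius_range: tuple[float, float] = (0.05, 0.09)
    contrast: float = 0.35
    texture_noise: float = 0.15
    center_jitter: float = 0.03


def _default_lesions(num_classes: int) -> list[LesionSpec]:
    # class-characteristic positions inside the "anatomy" ellipse
    anchors = [(0.35, 0.35), (0.65, 0.35), (0.35, 0.65), (0.65, 0.65),
               (0.5, 0.3), (0.5, 0.7), (0.3, 0.5), (0.7, 0.5)]
    contrasts = [0.35, 0.32, 0.36, 0.40, 0.34, 0.34, 0.34, 0.34]
    return [LesionSpec(center=anchors[c % len(anchors)], contrast=contrasts[c % len(contrasts)])
            for c in range(num_classes)]


def _default_loading(num_classes: int) -> np.ndarray:
    # two latent factors: one ties the first two classes, one the rest
    loading = np.zeros((2, num_classes))
    if num_classes >= 1:
        loading[0, 0] = 0.3
    if num_classes >= 2:
        loading[0, 1] = 0.3
    if num_classes >= 3:
        loading[1, 2] = 0.2
    if num_classes >= 4:
        loading[1, 3] = 0.08
    return loading


@dataclass
class SynthConfig:
    """Study conditions for the synthetic lesion-image benchmark."""

    num_classes: int = 4
    image_size: tuple[int, int] = (224, 224)  # (H, W)
    n_samples: int = 2000
    positive_rate: tuple[float, ...] = (0.3, 0.3, 0.15, 0.05)
    cooccurrence: np.ndarray | None = None  # [n_factors, num_classes] loading matrix
    lesions: list[LesionSpec] | None = None
    background_level: float = 0.3
    background_noise: float = 0.03
    speckle_noise: float = 0.02
    seed: int = 0
    class_names: list[str] | None = None

    def __post_init__(self):
        if self.cooccurrence is None:
            self.cooccurrence = _default_loading(self.num_classes)
        self.cooccurrence = np.asarray(self.cooccurrence, dtype=float)
        if self.cooccurrence.ndim != 2 or self.cooccurrence.shape[1] != self.num_classes:
            raise ConfigurationError(
                f"cooccurrence loading must be [n_factors, {self.num_classes}], "
                f"got {self.cooccurrence.shape}")
        if len(self.positive_rate) != self.num_classes:
            raise ConfigurationError("positive_rate length must equal num_classes")
        rates = np.asarray(self.positive_rate, dtype=float)
        if np.any(rates < 0) or np.any(rates > 1):
            raise ConfigurationError("positive_rate entries must lie in [0, 1]")
        # activation probabilities must stay inside [0, 1] for every factor draw
        half_span = 0.5 * np.abs(self.cooccurrence).sum(axis=0)
        if np.any(rates + half_span > 1.0 + 1e-12) or np.any(rates - half_span < -1e-12):
            raise ConfigurationError(
                "loading matrix pushes activation probabilities outside [0, 1]")
        if self.lesions is None:
            self.lesions = _default_lesions(self.num_classes)
        if self.class_names is None:
            self.class_names = [f"lesion_{chr(ord('A') + c)}" for c in range(self.num_classes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cooccurrence"] = self.cooccurrence.tolist()
        return d


@dataclass
class DomainShift:
    """Deployment-domain distortion: aspect stretch, off-center anatomy, noise."""

    aspect_ratio_factor: float = 1.22
    translation: float = 0.08  # fraction of image width
    extra_noise_sigma: float = 0.05

    def __post_init__(self):
        if self.aspect_ratio_factor <= 0:
            raise ConfigurationError("aspect_ratio_factor must be positive")


@dataclass
class LabeledImageSet:
    """Grayscale images [N, H, W] (uint8) with an exact binary label matrix."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def label_matrix(self) -> LabelMatrix:
        return LabelMatrix(y=self.labels, class_names=list(self.class_names))

    def subset(self, indices) -> "LabeledImageSet":
        idx = np.asarray(indices)
        return LabeledImageSet(images=self.images[idx], labels=self.labels[idx],
                               class_names=list(self.class_names))


# ---------------------------------------------------------------------------
# label sampling
# ---------------------------------------------------------------------------

def sample_labels(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an [n, C] binary label matrix from the latent-factor model."""
    rates = np.asarray(cfg.positive_rate, dtype=float)
    loading = cfg.cooccurrence
    z = rng.integers(0, 2, size=(n, loading.shape[0])).astype(float)  # Bernoulli(1/2)
    p = rates[None, :] + (z - 0.5) @ loading
    p = np.clip(p, 0.0, 1.0)
    return (rng.random((n, cfg.num_classes)) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yy /= max(h - 1, 1)
    xx /= max(w - 1, 1)
    img = cfg.background_level + 0.15 * yy  # vertical gradient
    # central bright "anatomy" ellipse
    d2 = ((xx - 0.5) / 0.40) ** 2 + ((yy - 0.5) / 0.44) ** 2
    img += 0.22 * np.exp(-0.5 * d2 ** 2)
    if cfg.background_noise > 0:
        low = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 16.0)
        sd = low.std()
        if sd > 0:
            img += cfg.background_noise * low / sd
    return img


def _render_image(cfg: SynthConfig, labels_row: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_size
    img = _background(cfg, rng)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for c in np.flatnonzero(labels_row):
        spec = cfg.lesions[c]
        cx = (spec.center[0] + rng.uniform(-spec.center_jitter, spec.center_jitter)) * (w - 1)
        cy = (spec.center[1] + rng.uniform(-spec.center_jitter, spec.center_jitter)) * (h - 1)
        r = rng.uniform(*spec.radius_range) * min(h, w)
        blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * r * r))
        if spec.texture_noise > 0:
            tex = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
            sd = tex.std()
            if sd > 0:
                blob = blob * (1.0 + spec.texture_noise * tex / sd)
        img += spec.contrast * blob
    if cfg.speckle_noise > 0:
        img += cfg.speckle_noise * rng.standard_normal((h, w))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(cfg: SynthConfig, n_samples: int | None = None,
                     seed: int | None = None) -> LabeledImageSet:
    """Render a full labeled set; deterministic given (config, seed)."""
    n = cfg.n_samples if n_samples is None else int(n_samples)
    if n < 1:
        raise InputError("n_samples must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = sample_labels(cfg, n, rng)
    h, w = cfg.image_size
    images = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        images[i] = np.round(_render_image(cfg, labels[i], rng) * 255.0).astype(np.uint8)
    return LabeledImageSet(images=images, labels=labels, class_names=list(cfg.class_names))


def generate_splits(cfg: SynthConfig, n_train: int, n_val: int, n_test: int,
                    shift: DomainShift | None = None, seed: int | None = None
                    ) -> dict[str, LabeledImageSet]:
    """Train/val/test(source)/test(shifted) splits from independent seed streams."""
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    shift = shift or DomainShift()
    train = generate_dataset(cfg, n_train, seed=seeds[0])
    val = generate_dataset(cfg, n_val, seed=seeds[1])
    test = generate_dataset(cfg, n_test, seed=seeds[2])
    test_shifted = apply_domain_shift(test, shift, seed=seeds[3])
    return {"train": train, "val": val, "test_source": test, "test_shifted": test_shifted}


# ---------------------------------------------------------------------------
# domain shift
# ---------------------------------------------------------------------------

def apply_domain_shift(dataset: LabeledImageSet, shift: DomainShift,
                       seed: int = 0) -> LabeledImageSet:
    """Re-render each image under the deployment-domain distortion.

    The anatomy is stretched horizontally by ``aspect_ratio_factor``,
    translated off-center by ``translation`` of the width, and overlaid with
    extra Gaussian noise; the canvas resolution is unchanged and labels are
    preserved bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    f = shift.aspect_ratio_factor
    n, h, w = dataset.images.shape
    cx = (w - 1) / 2.0
    tx = shift.translation * w
    # output -> input coordinate map (xy order): undo translation, then
    # compress x back around the center by 1/f
    matrix = np.array([[1.0 / f, 0.0, cx * (1.0 - 1.0 / f) - tx / f],
                       [0.0, 1.0, 0.0],
                       [0.0, 0.0, 1.0]])
    tform = AffineTransform(matrix=matrix)
    out = np.empty_like(dataset.images)
    for i in range(n):
        img = dataset.images[i].astype(float) / 255.0
        warped = warp(img, tform, order=1, mode="edge", preserve_range=True)
        if shift.extra_noise_sigma > 0:
            warped = warped + shift.extra_noise_sigma * rng.standard_normal((h, w))
        out[i] = np.round(np.clip(warped, 0.0, 1.0) * 255.0).astype(np.uint8)
    return LabeledImageSet(images=out, labels=dataset.labels.copy(),
                           class_names=list(dataset.class_names))


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def export_manifest(dataset: LabeledImageSet, directory: str | os.PathLike,
                    name: str = "manifest.csv") -> Path:
    """Write PNG images plus a CSV manifest (image_path + one column per class)."""
    directory = Path(directory)
    img_dir = directory / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(len(dataset)):
            rel = f"images/img_{i:05d}.png"
            Image.fromarray(dataset.images[i], mode="L").save(img_dir / f"img_{i:05d}.png")
            row = {"image_path": rel}
            row.update({c: int(v) for c, v in zip(dataset.class_names, dataset.labels[i])})
            rows.append(row)
        manifest = directory / name
        pd.DataFrame(rows).to_csv(manifest, index=False)
    except OSError as err:
        raise InputError(f"failed to export dataset under {directory}: {err}") from err
    return manifest


def load_manifest(manifest_path: str | os.PathLike) -> LabeledImageSet:
    """Read a manifest CSV and its PNGs back into a :class:`LabeledImageSet`."""
    manifest_path = Path(manifest_path)
    try:
        df = pd.read_csv(manifest_path)
    except OSError as err:
        raise InputError(f"cannot read manifest {manifest_path}: {err}") from err
    if "image_path" not in df.columns:
        raise InputError(f"manifest {manifest_path} lacks an image_path column")
    class_names = [c for c in df.columns if c != "image_path"]
    base = manifest_path.parent
    images = []
    for rel in df["image_path"]:
        with Image.open(base / rel) as im:
            images.append(np.asarray(im.convert("L"), dtype=np.uint8))
    labels = df[class_names].to_numpy(dtype=np.int8)
    return LabeledImageSet(images=np.stack(images), labels=labels, class_names=class_names)


# ---------------------------------------------------------------------------
# solvability probe
# ---------------------------------------------------------------------------

def template_match_scores(dataset: LabeledImageSet, cfg: SynthConfig) -> np.ndarray:
    """Correlation of each image with each class's canonical lesion template.

    A deliberately simple detector used to certify that the generated task is
    solvable (per-class AUC well above chance) before any learning happens.
    """
    h, w = dataset.images.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    templates = []
    for spec in cfg.lesions:
        cx, cy = spec.center[0] * (w - 1), spec.center[1] * (h - 1)
        r = 0.5 * (spec.radius_range[0] + spec.radius_range[1]) * min(h, w)
        # widened footprint absorbs center jitter
        tmpl = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * (1.5 * r) ** 2))
        templates.append(tmpl - tmpl.mean())
    tmat = np.stack([t.ravel() for t in templates], axis=1)  # [HW, C]
    imgs = dataset.images.reshape(len(dataset), -1).astype(float) / 255.0
    imgs = imgs - imgs.mean(axis=1, keepdims=True)
    return imgs @ tmat
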