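"""Patch-level variational information bottleneck (P-VIB).

The layer treats each spatial position of a convolutional feature map as its
own small latent problem: two parallel 3x3 same-padded convolutions predict a
Gaussian posterior mean ``mu`` and (via an exponential map) a standard
deviation ``sigma`` at every position and channel, and the latent feature is
drawn with the reparameterization trick ``z = mu + eps * sigma``. Because the
posterior parameters come from convolutions rather than a flattening step, the
output keeps the spatial shape of the input and the layer can be dropped
anywhere into a CNN.

The feature-selection penalty per scale is the mean over positions and
channels of

    mu^2 + sigma^2 - 2*log(sigma) - 1

which is twice the KL divergence KL(N(mu, sigma^2) || N(0, 1)) per element;
the doubling is deliberate (it is absorbed by the beta weight of the combined
objective) and :func:`kl_oracle` provides an independent quadrature route used
to validate the closed form.

Conventions: feature maps are [C, H, W] (single map) or [N, C, H, W]
(batch); ``sigma`` is a standard deviation, strictly positive by
construction (the second convolution predicts log sigma, clamped to
[-10, 10]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .exceptions import ConfigurationError, InputError, ShapeError

__all__ = [
    "FeatureMap",
    "GaussianField",
    "LatentSample",
    "PatchVIB",
    "pvib_forward",
    "kl_loss_scale",
    "kl_loss_total",
    "kl_penalty_tensor",
    "kl_oracle",
]

LOG_SIGMA_CLAMP = 10.0


@dataclass
class FeatureMap:
    """A single feature map [C, H, W] produced at one pyramid scale."""

    values: np.ndarray
    scale_index: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError(f"FeatureMap expects [C, H, W], got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("FeatureMap contains non-finite values")


@dataclass
class GaussianField:
    """Per-position Gaussian posterior parameters over a feature map grid.

    ``mu`` and ``sigma`` share one shape; ``sigma`` holds standard
    deviations and must be strictly positive everywhere.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ShapeError(f"mu/sigma shape mismatch: {self.mu.shape} vs {self.sigma.shape}")

    @property
    def out_channels(self) -> int:
        return self.mu.shape[0]


@dataclass
class LatentSample:
    """A reparameterized draw; ``epsilon_used`` is None in deterministic mode."""

    z: np.ndarray
    epsilon_used: np.ndarray | None


class PatchVIB(Module):
    """The P-VIB layer: parallel 3x3 convolutions predicting (mu, log sigma).

    Parameters
    ----------
    in_channels : input feature channels C_l.
    out_channels : latent channels; defaults to ``in_channels`` so the layer
        is drop-in shape-preserving.
    rng : numpy Generator used once for weight initialization.

    The mean path is initialized with modest-variance weights (std
    1/sqrt(fan_in)) and zero bias; the log-sigma path starts near zero
    (small weights, zero bias) so sigma begins near 1 and the initial KL
    penalty is small.
    """

    def __init__(self, in_channels: int, out_channels: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        out_channels = in_channels if out_channels in (None, "same") else int(out_channels)
        if in_channels < 1 or out_channels < 1:
            raise ConfigurationError("PatchVIB channel counts must be >= 1")
        self.in_channels = int(in_channels)
        self.out_channels = out_channels
        fan_in = in_channels * 9
        std = 1.0 / np.sqrt(fan_in)
        self.w_mu = Parameter(rng.normal(0.0, std, (out_channels, in_channels, 3, 3)).astype(dtype))
        self.b_mu = Parameter(np.zeros(out_channels, dtype=dtype))
        self.w_logsig = Parameter(rng.normal(0.0, 0.1 * std, (out_channels, in_channels, 3, 3)).astype(dtype))
        self.b_logsig = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor, mode: str = "train",
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor, Tensor, np.ndarray | None]:
        """Run the layer on a batch [N, C_l, H, W].

        Returns ``(z, mu, sigma, epsilon)`` as tensors on the autodiff tape;
        ``epsilon`` is the raw noise array (None in eval mode).
        """
        if mode not in ("train", "eval"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        if x.data.ndim != 4:
            raise ShapeError(f"PatchVIB.forward expects [N, C, H, W], got {x.data.shape}")
        if x.data.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"PatchVIB configured for {self.in_channels} input channels, got {x.data.shape[1]}")
        mu = ad.conv2d(x, self.w_mu, self.b_mu, stride=1, padding=1)
        logsig = ad.clip(
            ad.conv2d(x, self.w_logsig, self.b_logsig, stride=1, padding=1),
            -LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP)
        sigma = ad.exp(logsig)
        if mode == "train":
            if rng is None:
                raise ConfigurationError("train-mode sampling requires an rng")
            if mu.data.dtype == np.float32:
                eps = rng.standard_normal(mu.data.shape, dtype=np.float32)
            else:
                eps = rng.standard_normal(mu.data.shape).astype(mu.data.dtype)
            z = mu + Tensor(eps) * sigma
        else:
            eps = None
            z = mu
        return z, mu, sigma, eps


def pvib_forward(feature: FeatureMap, layer: PatchVIB, mode: str = "train",
                 rng: np.random.Generator | None = None
                 ) -> tuple[LatentSample, GaussianField]:
    """Apply a P-VIB layer to a single feature map, returning plain arrays.

    In train mode a fresh standard-normal epsilon is drawn per element; in
    eval mode ``z = mu`` and ``epsilon_used`` is None. Spatial shape is
    preserved.
    """
    if not isinstance(feature, FeatureMap):
        feature = FeatureMap(np.asarray(feature))
    x = Tensor(feature.values[None, ...])
    z, mu, sigma, eps = layer.forward(x, mode=mode, rng=rng)
    field = GaussianField(mu=mu.data[0], sigma=sigma.data[0])
    sample = LatentSample(z=z.data[0], epsilon_used=None if eps is None else eps[0])
    return sample, field


# ---------------------------------------------------------------------------
# KL feature-selection losses
# ---------------------------------------------------------------------------

def kl_loss_scale(field: GaussianField) -> float:
    """Feature-selection penalty for one scale.

    The mean over every position and channel of
    ``mu^2 + sigma^2 - 2*log(sigma) - 1`` — twice the per-element Gaussian
    KL against the standard-normal prior. Zero exactly when mu == 0 and
    sigma == 1 everywhere.
    """
    if np.any(field.sigma <= 0):
        raise InputError("GaussianField.sigma must be strictly positive")
    mu, sigma = field.mu, field.sigma
    term = mu ** 2 + sigma ** 2 - 2.0 * np.log(sigma) - 1.0
    return float(np.mean(term))


def kl_loss_total(fields: list[GaussianField]) -> float:
    """Sum of per-scale penalties over the supplied scales (1-3 of them)."""
    if not fields:
        raise ConfigurationError("kl_loss_total requires at least one GaussianField")
    return float(sum(kl_loss_scale(f) for f in fields))


def kl_penalty_tensor(mu: Tensor, sigma: Tensor) -> Tensor:
    """Differentiable version of :func:`kl_loss_scale` for the training loop."""
    term = mu * mu + sigma * sigma - ad.log(sigma) * 2.0 - 1.0
    return term.mean()


def kl_oracle(mu: float, sigma: float) -> float:
    """Quadrature route to the per-element penalty — tests only.

    Integrates ``p log(p/q)`` for p = N(mu, sigma^2), q = N(0, 1) and returns
    twice the result, matching the closed-form elementwise term.
    """
    if sigma <= 0:
        raise InputError("sigma must be positive")
    p = stats.norm(loc=mu, scale=sigma)
    q = stats.norm(loc=0.0, scale=1.0)

    def integrand(z):
        return p.pdf(z) * (p.logpdf(z) - q.logpdf(z))

    lo, hi = mu - 12 * sigma, mu + 12 * sigma
    val, err = integrate.quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-12, limit=200)
    if not np.isfinite(val) or err > 1e-6:
        from .exceptions import NumericalError
        raise NumericalError(f"quadrature failed to converge (err={err})")
    return 2.0 * val
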