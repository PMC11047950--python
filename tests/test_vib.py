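"""The P-VIB layer: reparameterized sampling and the KL feature-selection loss."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import patchvib as pv
from patchvib import autodiff as ad
from patchvib.exceptions import ConfigurationError, InputError
from patchvib.vib import kl_penalty_tensor

from conftest import ZeroNoise


@pytest.fixture()
def layer64():
    return pv.PatchVIB(3, rng=np.random.default_rng(0), dtype=np.float64)


class TestSampling:
    def test_zero_noise_returns_mu(self, layer64):
        feature = pv.FeatureMap(np.random.default_rng(1).normal(size=(3, 6, 5)), 1)
        sample, field = pv.pvib_forward(feature, layer64, mode="train", rng=ZeroNoise())
        np.testing.assert_array_equal(sample.z, field.mu)

    def test_eval_mode_is_deterministic_mu(self, layer64):
        feature = pv.FeatureMap(np.random.default_rng(2).normal(size=(3, 4, 4)), 2)
        sample, field = pv.pvib_forward(feature, layer64, mode="eval")
        np.testing.assert_array_equal(sample.z, field.mu)
        assert sample.epsilon_used is None

    def test_sample_moments_recover_standard_normal(self):
        # weights zero -> mu = 0, sigma = 1 everywhere; 1e5 latent elements
        layer = pv.PatchVIB(1, out_channels=10, rng=np.random.default_rng(0), dtype=np.float64)
        for p in layer.parameters():
            p.data[:] = 0.0
        feature = pv.FeatureMap(np.zeros((1, 100, 100)), 1)
        sample, _ = pv.pvib_forward(feature, layer, mode="train", rng=np.random.default_rng(7))
        n = sample.z.size
        assert n == 100_000
        assert abs(sample.z.mean()) < 3.0 / math.sqrt(n)
        assert abs(sample.z.var() - 1.0) < 3.0 * math.sqrt(2.0 / (n - 1))

    @pytest.mark.parametrize("shape", [(1, 1), (5, 3), (8, 8)])
    def test_spatial_shape_preserved(self, layer64, shape):
        feature = pv.FeatureMap(np.random.default_rng(3).normal(size=(3, *shape)), 1)
        sample, field = pv.pvib_forward(feature, layer64, mode="train",
                                        rng=np.random.default_rng(0))
        assert sample.z.shape == (layer64.out_channels, *shape)
        assert field.mu.shape == field.sigma.shape == sample.z.shape

    def test_train_mode_bit_reproducible_under_seed(self, layer64):
        feature = pv.FeatureMap(np.random.default_rng(4).normal(size=(3, 7, 7)), 1)
        s1, _ = pv.pvib_forward(feature, layer64, mode="train", rng=np.random.default_rng(9))
        s2, _ = pv.pvib_forward(feature, layer64, mode="train", rng=np.random.default_rng(9))
        np.testing.assert_array_equal(s1.z, s2.z)

    def test_sigma_strictly_positive(self, layer64):
        feature = pv.FeatureMap(np.random.default_rng(5).normal(size=(3, 5, 5)) * 50, 1)
        _, field = pv.pvib_forward(feature, layer64, mode="eval")
        assert np.all(field.sigma > 0)

    def test_channel_mismatch_is_configuration_error(self, layer64):
        bad = ad.Tensor(np.zeros((1, 5, 4, 4)))
        with pytest.raises(ConfigurationError):
            layer64.forward(bad, mode="eval")

    def test_nonfinite_input_rejected(self, layer64):
        with pytest.raises(InputError):
            pv.FeatureMap(np.full((3, 2, 2), np.nan), 1)

    def test_unknown_mode_rejected(self, layer64):
        feature = pv.FeatureMap(np.zeros((3, 2, 2)), 1)
        with pytest.raises(ConfigurationError):
            pv.pvib_forward(feature, layer64, mode="predict")


class TestKLLoss:
    def test_prior_matching_is_exactly_zero(self):
        field = pv.GaussianField(mu=np.zeros((4, 3, 3)), sigma=np.ones((4, 3, 3)))
        assert pv.kl_loss_scale(field) == 0.0

    @pytest.mark.parametrize("mu,sigma,expected", [
        (1.0, 1.0, 1.0),
        (0.0, math.e, math.e ** 2 - 3.0),
        # pinned quadrature regression value for (0.5, 0.7)
        (0.5, 0.7, 0.4533498878774649),
    ])
    def test_single_element_values(self, mu, sigma, expected):
        field = pv.GaussianField(mu=np.array([[[mu]]]), sigma=np.array([[[sigma]]]))
        assert pv.kl_loss_scale(field) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_matches_quadrature_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            mu = rng.uniform(-3, 3)
            sigma = rng.uniform(0.1, 5.0)
            closed = mu ** 2 + sigma ** 2 - 2.0 * math.log(sigma) - 1.0
            assert closed == pytest.approx(pv.kl_oracle(mu, sigma), rel=1e-6, abs=1e-9)

    @given(st.floats(-4, 4), st.floats(0.05, 6.0))
    def test_nonnegative_everywhere(self, mu, sigma):
        field = pv.GaussianField(mu=np.array([[[mu]]]), sigma=np.array([[[sigma]]]))
        assert pv.kl_loss_scale(field) >= 0.0

    def test_zero_only_at_the_prior(self):
        for mu in np.linspace(-2, 2, 9):
            for sigma in np.geomspace(0.25, 4, 9):
                if mu == 0.0 and sigma == 1.0:
                    continue
                field = pv.GaussianField(mu=np.array([[[mu]]]), sigma=np.array([[[sigma]]]))
                assert pv.kl_loss_scale(field) > 0.0

    def test_total_is_additive_over_scales(self):
        rng = np.random.default_rng(0)
        fields = [pv.GaussianField(mu=rng.normal(size=(2, 3, 3)),
                                   sigma=rng.uniform(0.5, 2, size=(2, 3, 3)))
                  for _ in range(3)]
        parts = [pv.kl_loss_scale(f) for f in fields]
        assert pv.kl_loss_total(fields) == pytest.approx(sum(parts), rel=1e-12)
        assert pv.kl_loss_total(fields[:1]) == pytest.approx(parts[0], rel=1e-12)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ConfigurationError):
            pv.kl_loss_total([])

    def test_nonpositive_sigma_rejected(self):
        field = pv.GaussianField(mu=np.zeros((1, 1, 1)), sigma=np.ones((1, 1, 1)))
        field.sigma[0] = 0.0
        with pytest.raises(InputError):
            pv.kl_loss_scale(field)

    def test_oracle_sanity_points(self):
        assert pv.kl_oracle(0.0, 1.0) == pytest.approx(0.0, abs=1e-10)
        assert pv.kl_oracle(1.0, 1.0) == pytest.approx(1.0, rel=1e-9)


class TestGradientFlow:
    def test_layer_gradients_match_finite_differences(self):
        """Reparameterization contract: d/dtheta of a function of z (and of
        the KL penalty) flows through mu and sigma correctly."""
        rng = np.random.default_rng(0)
        layer = pv.PatchVIB(2, rng=rng, dtype=np.float64)
        x = ad.Tensor(rng.normal(size=(1, 2, 4, 4)))
        eps_rng_seed = 5

        def build():
            z, mu, sigma, _ = layer.forward(x, mode="train",
                                            rng=np.random.default_rng(eps_rng_seed))
            return (z * z).mean() + kl_penalty_tensor(mu, sigma)

        out = build()
        layer.zero_grad()
        out.backward()
        fd_eps = 1e-6
        for name, p in layer.named_parameters():
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in p.data.shape) if p.data.ndim else ()
                orig = p.data[idx]
                p.data[idx] = orig + fd_eps
                f1 = float(build().data)
                p.data[idx] = orig - fd_eps
                f2 = float(build().data)
                p.data[idx] = orig
                fd = (f1 - f2) / (2 * fd_eps)
                assert abs(fd - p.grad[idx]) <= 1e-4 * max(1.0, abs(fd)), name

    def test_tensor_and_array_kl_agree(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(size=(3, 4, 4))
        sigma = rng.uniform(0.3, 2.5, size=(3, 4, 4))
        t = kl_penalty_tensor(ad.Tensor(mu), ad.Tensor(sigma))
        f = pv.kl_loss_scale(pv.GaussianField(mu=mu, sigma=sigma))
        assert float(t.data) == pytest.approx(f, rel=1e-12)
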