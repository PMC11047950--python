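"""Model assembly: backbone pyramid, ECA neck, CSRA head, ablation switches."""

import numpy as np
import pytest

import patchvib as pv
from patchvib import autodiff as ad
from patchvib.exceptions import ConfigurationError
from patchvib.model import (CSRAHead, ECANeck, backbone_forward, csra_head,
                            eca_neck, _eca_kernel_size)


def small_images(n=2, size=64, seed=0):
    return np.random.default_rng(seed).normal(size=(n, size, size)).astype(np.float32)


class TestBackbone:
    def test_stride_pyramid_shapes_at_224(self):
        cfg = pv.ModelConfig()
        feats = backbone_forward(small_images(1, 224), cfg, seed=0)
        assert feats["P2"].shape[2:] == (28, 28)
        assert feats["P3"].shape[2:] == (14, 14)
        assert feats["P4"].shape[2:] == (7, 7)
        assert all(f.shape[0] == 1 for f in feats.values())

    def test_single_scale_ablation_returns_only_p4(self):
        cfg = pv.ModelConfig(scales_active=("P4",), image_size=64)
        feats = backbone_forward(small_images(3), cfg, seed=0)
        assert set(feats) == {"P4"}
        assert feats["P4"].shape == (3, cfg.backbone_channels[3], 2, 2)

    def test_resolution_strictly_decreases_across_scales(self):
        cfg = pv.ModelConfig(image_size=64)
        feats = backbone_forward(small_images(1), cfg, seed=0)
        sizes = [feats[s].shape[2] for s in ("P2", "P3", "P4")]
        assert sizes[0] > sizes[1] > sizes[2]

    def test_unknown_backbone_rejected_and_hooks_work(self):
        with pytest.raises(ConfigurationError):
            pv.build_model(pv.ModelConfig(backbone_name="resnet50"), seed=0)
        with pytest.raises(ConfigurationError):
            pv.build_model(pv.ModelConfig(backbone_name="mystery"), seed=0)

        class Tiny(ad.Module):
            out_channels = {"P2": 2, "P3": 2, "P4": 2}

            def __init__(self, cfg, rng):
                self.w = ad.Parameter(rng.normal(size=(2, cfg.in_channels, 3, 3)).astype(np.float32))

            def forward(self, x):
                p2 = ad.conv2d(x, self.w, stride=8, padding=1)
                p3 = ad.conv2d(x, self.w, stride=16, padding=1)
                p4 = ad.conv2d(x, self.w, stride=32, padding=1)
                return {"P2": p2, "P3": p3, "P4": p4}

        pv.register_backbone("tiny_probe", lambda cfg, rng: Tiny(cfg, rng))
        model = pv.build_model(pv.ModelConfig(backbone_name="tiny_probe", image_size=64),
                               seed=0)
        preds, _ = pv.model_forward(model, small_images(2))
        assert preds.probs_per_scale[0].shape == (2, 4)


class TestECANeck:
    def test_rescaling_is_constant_within_channel(self):
        rng = np.random.default_rng(0)
        neck = ECANeck(8, rng=rng)
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        out = eca_neck(x, neck)
        ratio = out / x
        for n in range(2):
            for c in range(8):
                vals = ratio[n, c]
                assert np.allclose(vals, vals.flat[0], atol=1e-5)
                assert 0.0 < vals.flat[0] < 1.0  # sigmoid gate

    def test_zero_input_maps_to_zero(self):
        neck = ECANeck(4, rng=np.random.default_rng(1))
        out = eca_neck(np.zeros((1, 4, 3, 3), dtype=np.float32), neck)
        assert np.all(out == 0.0)

    def test_spatial_shape_unchanged(self):
        neck = ECANeck(6, rng=np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(2, 6, 7, 9)).astype(np.float32)
        assert eca_neck(x, neck).shape == x.shape

    def test_adaptive_kernel_is_odd(self):
        for c in (4, 16, 32, 64, 128, 256):
            k = _eca_kernel_size(c)
            assert k % 2 == 1 and k >= 1


class TestCSRAHead:
    def test_zero_residual_weight_is_gap_linear_classifier(self):
        rng = np.random.default_rng(0)
        head = CSRAHead(8, 3, rng=rng, residual_weight=0.0)
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        logits = csra_head(x, head)
        gap = x.mean(axis=(2, 3))  # [N, C]
        w = head.w.data[:, :, 0, 0]
        expected = gap @ w.T + head.b.data
        np.testing.assert_allclose(logits, expected, atol=1e-5)

    def test_uniform_map_attention_equals_base(self):
        rng = np.random.default_rng(1)
        head = CSRAHead(5, 4, rng=rng, residual_weight=0.3)
        x = np.ones((1, 5, 6, 6), dtype=np.float32) * 0.7
        logits = csra_head(x, head)
        head0 = CSRAHead(5, 4, rng=np.random.default_rng(1), residual_weight=0.0)
        base = csra_head(x, head0)
        np.testing.assert_allclose(logits, base * (1 + 0.3), atol=1e-5)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            CSRAHead(4, 2, rng=np.random.default_rng(0), temperature=0.0)


class TestAssembledModel:
    def test_probabilities_in_unit_interval_and_fields_per_scale(self):
        model = pv.build_model(pv.ModelConfig(image_size=64), seed=0)
        preds, fields = pv.model_forward(model, small_images(2))
        assert len(preds.probs_per_scale) == 3
        assert len(fields) == 3
        for p in preds.probs_per_scale:
            assert np.all((p > 0) & (p < 1))
        for f in fields:
            assert np.all(f.sigma > 0)

    def test_vib_none_returns_no_fields(self):
        model = pv.build_model(pv.ModelConfig(image_size=64, vib_position="none"), seed=0)
        _, fields = pv.model_forward(model, small_images(2))
        assert fields == []

    def test_eval_mode_deterministic(self):
        model = pv.build_model(pv.ModelConfig(image_size=64), seed=0)
        x = small_images(2)
        p1, _ = pv.model_forward(model, x)
        p2, _ = pv.model_forward(model, x)
        for a, b in zip(p1.probs_per_scale, p2.probs_per_scale):
            np.testing.assert_array_equal(a, b)

    def test_train_mode_seeded_reproducible(self):
        model = pv.build_model(pv.ModelConfig(image_size=64), seed=0)
        x = small_images(2)
        p1, _ = pv.model_forward(model, x, mode="train", rng=np.random.default_rng(4))
        p2, _ = pv.model_forward(model, x, mode="train", rng=np.random.default_rng(4))
        for a, b in zip(p1.probs_per_scale, p2.probs_per_scale):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("vib_position", ["before_neck", "after_neck"])
    @pytest.mark.parametrize("use_neck,scales", [
        (True, ("P2", "P3", "P4")), (False, ("P2", "P3", "P4")),
        (True, ("P4",)), (False, ("P4",)),
    ])
    def test_ablation_lattice_reachable_from_config(self, vib_position, use_neck, scales):
        cfg = pv.ModelConfig(image_size=64, vib_position=vib_position,
                             use_neck=use_neck, scales_active=scales)
        model = pv.build_model(cfg, seed=0)
        preds, fields = pv.model_forward(model, small_images(1))
        assert len(preds.probs_per_scale) == len(scales)
        assert len(fields) == len(scales)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            pv.ModelConfig(scales_active=())
        with pytest.raises(ConfigurationError):
            pv.ModelConfig(scales_active=("P2",))  # P4 must stay
        with pytest.raises(ConfigurationError):
            pv.ModelConfig(vib_position="inside_backbone")
        with pytest.raises(ConfigurationError):
            pv.ModelConfig(fusion="max")


class TestFusionAndCheckpoint:
    def test_combine_single_scale_is_identity(self):
        p = np.random.default_rng(0).uniform(size=(3, 4))
        preds = pv.PredictionSet(probs_per_scale=[p], scales=("P4",))
        np.testing.assert_array_equal(pv.combine_scale_predictions(preds), p)

    def test_combine_mean_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.uniform(size=(3, 4)) for _ in range(3))
        preds = pv.PredictionSet(probs_per_scale=[a, b, c], scales=("P2", "P3", "P4"))
        fused = pv.combine_scale_predictions(preds)
        np.testing.assert_allclose(fused, (a + b + c) / 3)
        perm = pv.PredictionSet(probs_per_scale=[c, a, b], scales=("P2", "P3", "P4"))
        np.testing.assert_allclose(pv.combine_scale_predictions(perm), fused)

    def test_single_scale_fusion_selection(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.uniform(size=(2, 4)) for _ in range(3))
        preds = pv.PredictionSet(probs_per_scale=[a, b, c], scales=("P2", "P3", "P4"))
        np.testing.assert_array_equal(
            pv.combine_scale_predictions(preds, fusion="P3"), b)

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        model = pv.build_model(pv.ModelConfig(image_size=64), seed=7)
        x = small_images(2, seed=5)
        before, _ = pv.model_forward(model, x)
        path = tmp_path / "ckpt.npz"
        pv.save_checkpoint(path, model, extra={"note": "test"})
        restored, extra = pv.load_checkpoint(path)
        assert extra == {"note": "test"}
        assert restored.cfg == model.cfg
        after, _ = pv.model_forward(restored, x)
        for a, b in zip(before.probs_per_scale, after.probs_per_scale):
            np.testing.assert_array_equal(a, b)
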