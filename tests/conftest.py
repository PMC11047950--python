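import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import patchvib as pv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_synth_cfg():
    return pv.SynthConfig(image_size=(64, 64), seed=0)


@pytest.fixture(scope="session")
def tiny_splits(tiny_synth_cfg):
    """Small 64-px splits shared by the training/CLI tests."""
    return pv.generate_splits(tiny_synth_cfg, n_train=160, n_val=60, n_test=60, seed=0)


@pytest.fixture(scope="session")
def tiny_trained(tiny_splits):
    """One short P-VIB training run shared by several tests."""
    model_cfg = pv.ModelConfig(image_size=64)
    loss_cfg = pv.LossConfig()
    train_cfg = pv.TrainConfig(epochs=3, batch_size=32, seed=0)
    model, history = pv.train_model(tiny_splits["train"], tiny_splits["val"],
                                    model_cfg, loss_cfg, train_cfg)
    return model, history


@pytest.fixture(scope="session")
def default_scale_run():
    """The full-scale reference run: default synthetic benchmark
    (4 classes, 2000/500/500 at 224 px, seed 0), default model, 10 epochs.

    Session-scoped because it is by far the most expensive computation in
    the suite; the learnability and early-stopping checks share it.
    """
    scfg = pv.SynthConfig(seed=0)
    splits = pv.generate_splits(scfg, n_train=2000, n_val=500, n_test=500, seed=0)
    model_cfg = pv.ModelConfig()
    loss_cfg = pv.LossConfig()
    train_cfg = pv.TrainConfig(epochs=10, seed=0, early_stop_metric="macro_auc")
    model, history = pv.train_model(splits["train"], splits["val"],
                                    model_cfg, loss_cfg, train_cfg)
    return model, history, splits


class ZeroNoise:
    """Stand-in rng whose standard normal draws are all zero."""

    def standard_normal(self, shape, dtype=np.float64):
        return np.zeros(shape, dtype=dtype)
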