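import numpy as np
import pytest
from hypothesis import settings

import biaxcann as bc
from biaxcann.training import LossConfig, OptimizerConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    # fresh, fixed-seed generator per test: results do not depend on which
    # other tests ran before
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise, zero-heterogeneity cohort from the default reduced truth."""
    cfg = bc.SyntheticConfig(seed=1, noise_sd=0.0, heterogeneity_sd=0.0)
    return bc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study-like conditions (noise and heterogeneity on)."""
    return bc.generate_cohort(bc.SyntheticConfig(seed=1))


def fast_opt(epochs=1000, seed=0, **kw):
    """Scaled-down optimizer protocol used throughout the tests.

    The larger step size compensates for the shorter run (the per-step Adam
    displacement is ~lr, so steps x lr must exceed the kPa-scale weights);
    cosine decay settles the final iterates.
    """
    kw.setdefault("learning_rate", 0.01)
    kw.setdefault("lr_decay", 1e-3)
    kw.setdefault("batch_size", 32)
    kw.setdefault("patience", epochs)
    return OptimizerConfig(epochs=epochs, seed=seed, **kw)


@pytest.fixture
def sample_loss_cfg():
    return LossConfig(mode="sample", alpha_reg=0.0)
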