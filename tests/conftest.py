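import numpy as np
import pytest

from tensorfc import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small two-class cohort in the default (class-specific) regime."""
    classes, truth = generate_cohort(SyntheticConfig.small(seed=0))
    return classes, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """Very small cohort for fast end-to-end checks."""
    cfg = SyntheticConfig.small(
        seed=3, T=30, R=10, n_per_class=(8, 8),
        background_rank=(3, 3), signal_ranks=((2, 2), (2, 2)),
    )
    classes, truth = generate_cohort(cfg)
    return classes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
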