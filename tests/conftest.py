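import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A small but fully structured synthetic cohort (30 samples)."""
    from crcland.simulate import CohortConfig, generate_cohort

    config = CohortConfig(seed=11, n_per_country=15)
    variants, clinical, truth = generate_cohort(config, return_truth=True)
    return variants, clinical, truth
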