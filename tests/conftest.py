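import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fast_cohort():
    """Small Mexican-hat-truth cohort with Gaussian staircase noise (fast
    mode), shared across tests that only need a well-formed threshold table."""
    from expectprofile import experiments as ex

    return ex.simulate_profile_cohort(8, tasks=("OD",), seed=11, fast=True)
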