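import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmtid import (FitConfig, single_diffusion_time_protocol,
                   two_diffusion_time_protocol)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_dt():
    return two_diffusion_time_protocol()


@pytest.fixture(scope="session")
def single_dt():
    return single_diffusion_time_protocol()


@pytest.fixture
def fast_config():
    """Small multi-start budget for unit tests; studies use their own."""
    return FitConfig(n_starts=10, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
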