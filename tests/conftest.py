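import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiomrs.datamodel import AcquisitionParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def acq_small() -> AcquisitionParams:
    """Short single-channel acquisition for fast unit tests."""
    return AcquisitionParams(n_points=512, n_shots=1, n_channels=1)


@pytest.fixture
def acq_default() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
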