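import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atosense.model import TCSParameters

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> TCSParameters:
    return TCSParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
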