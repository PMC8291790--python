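import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bridgeforge.fixtures import packaged_worked_example

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_example():
    return packaged_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
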