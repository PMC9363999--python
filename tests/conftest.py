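import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from mbamkit import (  # noqa: E402
    build_wang_r0,
    default_mbam_protocol,
    default_theta,
    uniform_schedule,
    wang_reduction_sequence,
)


@pytest.fixture(scope="session")
def wang_r0():
    return build_wang_r0()


@pytest.fixture(scope="session")
def theta0():
    return default_theta()


@pytest.fixture(scope="session")
def protocol():
    return default_mbam_protocol()


@pytest.fixture(scope="session")
def schedule37(protocol):
    return uniform_schedule(protocol, 37)


@pytest.fixture(scope="session")
def schedule1ms(protocol):
    return uniform_schedule(protocol, 5000)


@pytest.fixture(scope="session")
def wang_sequence():
    return wang_reduction_sequence()


@pytest.fixture(scope="session")
def wang_models(wang_sequence):
    return {m.name: m for m, _ in wang_sequence}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
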