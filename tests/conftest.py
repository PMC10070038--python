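import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import binpower as bp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def s1():
    return bp.scenario("S1")


@pytest.fixture(scope="session")
def s2():
    return bp.scenario("S2")


@pytest.fixture(scope="session")
def s3():
    return bp.scenario("S3")


@pytest.fixture(scope="session")
def s2_resolved(s2):
    return bp.resolve(*s2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
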