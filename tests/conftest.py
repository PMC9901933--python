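import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pupephys.simulate import SimParams, generate_session, generate_urethane_session


@pytest.fixture(scope="session")
def p8_session():
    """Default-condition P8-like session (600 s free behavior + stimulations)."""
    params = SimParams(seed=11, duration_s=600.0)
    session, truth = generate_session(params)
    return session, truth, params


@pytest.fixture(scope="session")
def urethane_session():
    """Pre/post anesthesia session at reduced desk scale (600 s per period)."""
    params = SimParams(seed=12, pre_duration_s=600.0, post_duration_s=600.0)
    session, truth = generate_urethane_session(params)
    return session, truth, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
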