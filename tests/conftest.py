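import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_session():
    """A short fixed session (RB condition) for likelihood plumbing."""
    from ktom.arena import SessionRecord

    r = np.random.default_rng(7)
    a_self = (r.random(30) < 0.5).astype(int)
    a_op = (r.random(30) < 0.65).astype(int)
    return SessionRecord(a_self, a_op, (a_self == a_op).astype(int), "RB")
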