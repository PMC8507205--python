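import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_read(rng, length, read_id="r", q_lo=2, q_hi=41):
    from concatseq.seqio import PhredRead

    bases = "".join(rng.choice(list("ACGT"), size=length))
    quals = rng.integers(q_lo, q_hi + 1, size=length)
    return PhredRead(id=read_id, bases=bases, quals=quals)


@pytest.fixture
def make_read():
    return random_read
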