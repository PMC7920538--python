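import numpy as np
import pytest

import cnpipe as cp

FS = 30000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sound_schedule():
    """One block of 50 sound pulses: fast fixture for encode/decode tests."""
    return cp.make_schedule("sound_only", n_blocks=1, pulses_per_block=50)


@pytest.fixture(scope="session")
def full_sound_schedule():
    """The standard five-block, 1000-pulse sound protocol."""
    return cp.make_schedule("sound_only")


def poisson_train(rate_hz: float, duration: float, seed: int, unit_id: str = "u") -> cp.SpikeTrain:
    r = np.random.default_rng(seed)
    n = r.poisson(rate_hz * duration)
    return cp.SpikeTrain(unit_id, np.sort(r.uniform(0, duration, n)), duration)
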