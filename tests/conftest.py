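import numpy as np
import pytest

from caar.signal_io import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def white_noise():
    def make(n=1000, seed=0, sd=1.0):
        return TimeSeries(np.random.default_rng(seed).normal(0.0, sd, n))

    return make


@pytest.fixture
def impulse_train():
    """Unit impulses every 50 samples, length 1000 (periodicity fixture)."""
    x = np.zeros(1000)
    x[::50] = 1.0
    return TimeSeries(x)
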