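import numpy as np
import pytest

from spikenets.io import SpikeTrainSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spikes(rng):
    """20 neurons, Poisson-ish trains over 60 s."""
    ids = [f"u{i:02d}" for i in range(20)]
    rates = rng.uniform(0.5, 8.0, size=20)
    times = [np.sort(rng.uniform(0, 60.0, size=rng.poisson(60.0 * r)))
             for r in rates]
    return SpikeTrainSet(ids, times, duration=60.0, bin_width=0.01)
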