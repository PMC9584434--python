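import numpy as np
import pytest

from oscnet.timeseries import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dataset():
    """3 genes x 5 times with distinct dynamic character."""
    times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    values = np.array([
        [1.0, 2.0, 4.0, 2.0, 1.0],     # peaked
        [5.0, 5.0, 5.0, 5.0, 5.0],     # flat
        [0.5, 1.5, 0.5, 1.5, 0.5],     # alternating
    ])
    return TimeSeriesSet(["g1", "g2", "g3"], times, values, "toy")


@pytest.fixture
def oscillating_pair():
    """Two anti-phase sinusoids sampled densely: a regulator/target pair."""
    times = np.linspace(0, 4 * np.pi, 36)
    reg = 1.5 + np.sin(times)
    tgt = 1.5 + np.cos(times)
    return TimeSeriesSet(["R", "T"], times, np.vstack([reg, tgt]), "pair")
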