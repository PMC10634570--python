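import numpy as np
import pytest

import strsa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """8 conditions (4 social), 8 blocks, no catch events."""
    spec = strsa.DesignSpec(
        n_videos=8, n_social=4, n_blocks=8, n_catch_events_per_block=0, seed=7
    )
    return spec, strsa.generate_design(spec)


@pytest.fixture
def noise_epochs(rng):
    """Pure-noise epochs: 6 conditions x 8 trials, 8 channels, 500 Hz."""
    labels = np.repeat(np.arange(6), 8)
    data = rng.standard_normal((len(labels), 8, 100))
    times = -40.0 + np.arange(100) * 2.0
    return strsa.EpochSet(data, times, 500.0, labels)


def random_rdm(rng, n):
    """Random valid RDM on n conditions."""
    v = rng.random(n * (n - 1) // 2) + 0.05
    return strsa.devectorize_rdm(v)
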