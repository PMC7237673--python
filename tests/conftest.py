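import numpy as np
import pytest

import emgsynergy as es


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Rank-3 activation matrix with known non-negative factors, no noise."""
    return es.generate_synergy_dataset(L=10, K_true=3, N=200, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Rank-3 activation matrix with additive truncated noise (sd 0.05)."""
    return es.generate_synergy_dataset(L=10, K_true=3, N=200, noise_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def walk_trial():
    return es.generate_raw_trial("walk", n_channels=10, fs=1500.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
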