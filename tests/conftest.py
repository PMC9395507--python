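import numpy as np
import pytest

from eegclean import Montage, Recording, SimSpec, default_montage, simulate_clean_eeg


@pytest.fixture(scope="session")
def sim_short():
    """30 s, 12-channel clean simulated recording (session-cached)."""
    return simulate_clean_eeg(SimSpec(seed=11, duration_s=30.0))


@pytest.fixture(scope="session")
def sim_long():
    """60 s clean simulated recording for spectral checks."""
    return simulate_clean_eeg(SimSpec(seed=12, duration_s=60.0))


@pytest.fixture
def montage12():
    return default_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_recording(data, fs=250.0, labels=None, montage=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, labels=labels, montage=montage)
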