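import numpy as np
import pytest

from postdecision import cohort as coh


@pytest.fixture(scope="session")
def small_config():
    return coh.CohortConfig(n_subjects=6, n_blocks=3, seed=42)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return coh.generate_behavior(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free cohort: clean generative signals, exact constructions."""
    return coh.CohortConfig(n_subjects=6, n_blocks=2, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_trials(clean_config):
    return coh.generate_behavior(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=256.0, t0=None, channels=("CPP", "FCtheta"),
                alignment="response"):
    """Single-channel-per-array helper: broadcast data to all channels."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    n_trials, n_t = data.shape
    if t0 is None:
        t0 = -(n_t // 2) / fs
    times = t0 + np.arange(n_t) / fs
    full = np.repeat(data[:, None, :], len(channels), axis=1)
    return coh.EpochSet(data=full, times=times, channels=tuple(channels),
                        alignment=alignment, sampling_rate=fs,
                        trial_index=np.arange(n_trials))
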