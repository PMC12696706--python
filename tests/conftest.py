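import numpy as np
import pytest

from docbci.core import SCALP_CHANNELS, EEGRecording, SessionPlan
from docbci.synthetic_eeg import make_cohort


@pytest.fixture(scope="session")
def short_plan() -> SessionPlan:
    """Scaled-down session: enough epochs for spectra, fast to simulate."""
    return SessionPlan(n_trials=3, n_practice=1, rest_duration_s=40.0)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(3, 4, seed=11)


@pytest.fixture(scope="session")
def uws_profile(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def mcs_profile(small_cohort):
    return small_cohort[-1]


def tone_recording(freq: float, fs: float = 250.0, seconds: float = 10.0,
                   amplitude: float = 10.0, n_channels: int = 3,
                   noise: float = 0.0, seed: int = 0,
                   condition: str = "rest") -> EEGRecording:
    """Multichannel pure-tone recording on real montage channel names."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(seconds * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_channels, 1))
    if noise > 0:
        data = data + rng.normal(0.0, noise, size=data.shape)
    return EEGRecording(data=data, fs=fs,
                        channel_names=list(SCALP_CHANNELS[:n_channels]),
                        condition=condition)


@pytest.fixture(scope="session")
def flat_weights():
    bands = ("delta", "theta", "alpha", "beta", "gamma")
    regions = ("frontal", "parietal", "temporal", "occipital")
    return {r: {b: 0.2 for b in bands} for r in regions}


@pytest.fixture(scope="session")
def unit_modulation():
    bands = ("delta", "theta", "alpha", "beta", "gamma")
    regions = ("frontal", "parietal", "temporal", "occipital")
    return {r: {b: 1.0 for b in bands} for r in regions}
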