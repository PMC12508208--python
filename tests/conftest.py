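import numpy as np
import pytest

from tremorsep.signal import OrientationSignal
from tremorsep.synth import ActivityProfile, generate_recording


@pytest.fixture
def fs():
    return 100.0


@pytest.fixture
def resting_profile():
    return ActivityProfile.default("resting")


@pytest.fixture
def clean_profile():
    """Resting profile without corruption (no noise, drift or gaps)."""
    return ActivityProfile.default("resting", noise_std_deg=0.0,
                                   drift_slope_deg_per_s=0.0,
                                   missing_fraction=0.0)


@pytest.fixture
def recording(resting_profile):
    return generate_recording(resting_profile, seed=7)


def tone(freq_hz, duration_s=10.0, fs=100.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


@pytest.fixture
def tone_factory():
    return tone


@pytest.fixture
def as_signal(fs):
    def _make(values, **meta):
        return OrientationSignal(np.asarray(values, float), fs=fs, meta=meta)
    return _make
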