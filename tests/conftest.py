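import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    """Default harmonic reference set: 1 s windows at 250 Hz, N=4."""
    from ssvepchair.decode import ReferenceSet

    return ReferenceSet.for_frequencies()


@pytest.fixture(scope="session")
def noise_free_trials():
    """One noise-free trial per class, 4 s at 250 Hz."""
    from ssvepchair.simulate import CLASSES, TrialSpec, generate_trial

    return {
        label: generate_trial(TrialSpec(label=label, snr_db="noise-free", seed=11))
        for label in CLASSES
    }


@pytest.fixture
def tone_window():
    """Factory for a single-window sinusoid at a given frequency."""
    from ssvepchair.preprocess import EpochWindow

    def make(freq, fs=250.0, n=250, amp=1.0, phase=0.0, label=None):
        t = np.arange(n) / fs
        return EpochWindow(
            amp * np.sin(2 * np.pi * freq * t + phase), fs, 0.0, label=label
        )

    return make
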