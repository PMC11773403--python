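import numpy as np
import pytest

from corticomark.synthetic import CohortConfig, EEGSimParams, generate_cohort

# Reduced simulation profiles used throughout the unit tests to keep the
# suite fast; the full 63-channel/5-minute profile is exercised in the
# acceptance tests.
FAST_EEG = EEGSimParams(n_channels=16, duration=60.0, sfreq=125.0)
TINY_EEG = EEGSimParams(n_channels=8, duration=30.0, sfreq=125.0,
                        sensorimotor_channels=("C3", "C1", "Cz"))


@pytest.fixture(scope="session")
def small_cohort():
    """30 planted-effect participants with day-0 EEG only."""
    cfg = CohortConfig(n_participants=30, seed=7, eeg=TINY_EEG,
                       eeg_session_days=(0,))
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
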