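import pytest
from hypothesis import HealthCheck, settings

from neurofuse.fbcsp import build_filter_bank
from neurofuse.fusion import CVConfig
from neurofuse.synthetic import EEGSimConfig, FTCDSimConfig, generate_paired_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

PAIR = ("baseline", "left")


@pytest.fixture(scope="session")
def small_bank():
    """Four 7 Hz bands over 2-30 Hz, matching the desk-scale EEG configs."""
    return build_filter_bank(2.0, 30.0, 4, 7.0)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable paired dataset: 12 trials/class, short trials."""
    eeg = EEGSimConfig(
        n_trials_per_class=12, n_channels=8, fs=128.0, trial_len=3.0,
        paradigm="MI", snr_db=10.0, seed=42, classes=PAIR,
    )
    ftcd = FTCDSimConfig(
        n_trials_per_class=12, trial_len=1.5, seed=43, paradigm="MI", classes=PAIR,
    )
    return generate_paired_dataset(eeg, ftcd, PAIR)


@pytest.fixture(scope="session")
def null_dataset():
    """Label-free paired dataset: no class effect in either modality."""
    eeg = EEGSimConfig(
        n_trials_per_class=12, n_channels=8, fs=128.0, trial_len=3.0,
        paradigm="MI", snr_db=10.0, seed=52, classes=PAIR,
        class_band_gains={c: (1.0, 1.0) for c in PAIR},
    )
    ftcd = FTCDSimConfig(
        n_trials_per_class=12, trial_len=1.5, seed=53, paradigm="MI", classes=PAIR,
        class_velocity_offsets={c: (0.0, 0.0) for c in PAIR},
    )
    return generate_paired_dataset(eeg, ftcd, PAIR)


@pytest.fixture()
def quick_cv(small_bank):
    return CVConfig(n_folds=4, n_pairs_sweep=(1, 2), bank=small_bank,
                    mode="paper", seed=0)
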