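import numpy as np
import pytest

import simondecode as sd


@pytest.fixture(scope="session")
def montage16():
    return sd.make_montage(16)


@pytest.fixture(scope="session")
def montage8():
    return sd.make_montage(8)


def random_epochs(n_trials, montage, n_times=96, sfreq=250.0, seed=0,
                  n_classes=4):
    """Unstructured noise epochs with balanced labels."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n_trials) % n_classes
    rng.shuffle(labels)
    return sd.EpochSet(
        subject_id=f"R{seed}",
        data=rng.standard_normal((n_trials, len(montage), n_times)),
        time_ms=np.arange(n_times) * 1000.0 / sfreq,
        labels=labels,
        montage=montage,
        sfreq=sfreq,
    )


@pytest.fixture(scope="session")
def micro_cohort():
    """Six tiny subjects (24 trials, 8 channels, 125 Hz), preprocessed.

    Small enough for sub-second training; carries the planted components
    so classifiers have signal to find.
    """
    cfg = sd.desk_scale_config(seed=42, n_trials=24, n_channels=8,
                               sfreq=125.0)
    cohort = sd.simulate_cohort(6, cfg)
    dataset = {
        rec.subject_id: sd.preprocess_recording(rec)[0]
        for rec in cohort.recordings
    }
    return cfg, cohort, dataset
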