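import pytest

from mseegnet.synthetic import SyntheticConfig, generate_trial_set


@pytest.fixture(scope="session")
def tiny_trials():
    """Small easy 2-class set (C=9, T=250) for fast end-to-end tests."""
    cfg = SyntheticConfig(n_subjects=1, n_trials_per_class=30, n_classes=2,
                          n_electrodes=9, duration=1.0, modulation_depth=0.9,
                          seed=11)
    return generate_trial_set(cfg)


@pytest.fixture(scope="session")
def multi_subject_trials():
    """3 subjects x 2 sessions, 4 classes, small trials for protocol tests."""
    cfg = SyntheticConfig(n_subjects=3, n_sessions=2, n_trials_per_class=5,
                          n_classes=4, n_electrodes=9, duration=1.0,
                          modulation_depth=0.8, seed=5)
    return generate_trial_set(cfg)
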