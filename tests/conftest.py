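"""Shared fixtures: small seeded cohorts and a fast hyperparameter grid."""

import numpy as np
import pytest

import eegaffect as ea


@pytest.fixture(scope="session")
def small_grid():
    """A compact (C, gamma) grid keeping SVM tests fast."""
    return ea.SVMConfig(c_grid=(1.0, 8.0), gamma_grid=(2.0 ** -5, 2.0 ** -3))


@pytest.fixture(scope="session")
def short_strong_spec():
    """Strong T7/T8 gamma effect, short trials (20 s stimuli, 3 trials)."""
    return ea.strong_effect_spec(
        seed=11, stimulus_duration=20.0, rest_duration=5.0, n_trials_per_subject=3
    )


@pytest.fixture(scope="session")
def short_strong_recordings(short_strong_spec):
    return [ea.generate_trial(short_strong_spec, 0, t) for t in range(3)]


@pytest.fixture(scope="session")
def short_strong_features(short_strong_recordings):
    return ea.cohort_features(short_strong_recordings)


@pytest.fixture(scope="session")
def protocol_trial():
    """One full-protocol trial: 60 s happy, 12 s rest, 60 s unhappy at 128 Hz."""
    return ea.generate_trial(ea.null_spec(seed=3), 0, 0)
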