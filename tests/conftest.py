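"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

import eegclassify as eeg
from eegclassify.ensemble import EnsembleConfig, ModelSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-effect 6+6 cohort, 30 s at 128 Hz — fast but separable."""
    params = eeg.SynthParams(
        n_control=6, n_patient=6, duration=30.0, seed=42,
        patient_multipliers={"delta": 1.0, "theta": 1.5,
                             "alpha": 0.5, "beta": 1.0},
        subject_effect_sd=0.1)
    return eeg.gen_cohort(params)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    ep = eeg.segment_cohort([eeg.bandpass(r) for r in small_cohort])
    return eeg.build_feature_matrix(ep)


@pytest.fixture(scope="session")
def fast_ensemble():
    """Single fixed-hyperparameter model: no search, quick protocol runs."""
    return EnsembleConfig(members=[
        ModelSpec("logistic_regression", search_space={"C": [1.0]})])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
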