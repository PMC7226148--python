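"""Shared fixtures: small synthetic cohorts and preprocessed recordings."""

import numpy as np
import pytest

from eegworkload.preprocess import apply_bandpass, design_bandpass
from eegworkload.synthetic import (
    ConditionSpec,
    SimulationConfig,
    generate_subject,
    subject_seed,
)

SHORT_CONDITIONS = (
    ConditionSpec("baseline_pre", 2.32, 20.0, 0),
    ConditionSpec("low", 3.34, 40.0, 1),
    ConditionSpec("medium", 3.66, 40.0, 2),
    ConditionSpec("high", 3.77, 40.0, 3),
    ConditionSpec("baseline_post", 2.35, 20.0, 0),
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=3, conditions=SHORT_CONDITIONS, seed=1234)


@pytest.fixture(scope="session")
def subject_bundle(small_config):
    """One simulated subject: (Recording, annotations, ground truth)."""
    return generate_subject(small_config, 0, subject_seed(small_config.seed, 0))


@pytest.fixture(scope="session")
def bandpass_spec():
    return design_bandpass(0.5, 32.0, 256.0, order=4, passes="zero_phase")


@pytest.fixture(scope="session")
def filtered_subject(subject_bundle, bandpass_spec):
    rec, annots, truth = subject_bundle
    return apply_bandpass(rec, bandpass_spec), annots, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240199)
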