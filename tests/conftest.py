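"""Shared fixtures: small synthetic studies and the session-scoped
simulation studies used by the heavier end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from grtmeta import (
    GroupModel,
    ParticipantParams,
    StudyConfig,
    default_group_model,
    fit_grt_wind,
    generate_study,
)
from grtmeta.io import aggregate_counts
from grtmeta.synth import recovery_harness


@pytest.fixture
def headline_group() -> GroupModel:
    """Generating model with opposite-sign correlations: confidence
    sensitivity grows with metacognitive evidence."""
    return default_group_model()


@pytest.fixture
def independence_group() -> GroupModel:
    """Zero-correlation model: recognition evidence independent of the
    metacognitive axis within every stimulus."""
    return GroupModel(
        means=np.array([[1.0, 1.0], [-1.0, 1.0], [0.0, 0.0]]),
        correlations=np.zeros(3),
    )


@pytest.fixture
def neutral_participant() -> ParticipantParams:
    """kappa=2, lambda=0.5 gives unit perceptual noise on both axes."""
    return ParticipantParams("n1", kappa=2.0, lam=0.5, c_y=0.0, c_x1=-1.0, c_x2=1.0)


@pytest.fixture(scope="session")
def small_study():
    """5 participants x 100 trials/condition; used wherever a real but
    cheap dataset is needed."""
    config = StudyConfig(n_participants=5, trials_per_condition=100, seed=42)
    trials, truth = generate_study(config)
    return trials, truth, config


@pytest.fixture(scope="session")
def small_tables(small_study):
    trials, _, _ = small_study
    return aggregate_counts(trials, judgment="TOT")


@pytest.fixture(scope="session")
def small_fit(small_tables):
    return fit_grt_wind(small_tables, n_restarts=5, seed=1)


@pytest.fixture(scope="session")
def recovery_report():
    """The reference simulation study: 20 participants, 200 trials per
    condition, fit with 20 random restarts."""
    config = StudyConfig(n_participants=20, trials_per_condition=200, seed=7)
    return recovery_harness(config, n_restarts=20, fit_seed=11)
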