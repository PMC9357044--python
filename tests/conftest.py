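"""Shared fixtures: tiny hand-built cohorts and session-scoped trained models.

Heavy artifacts (simulated cohorts, one trained recurrent survival model)
are session-scoped so the suite trains once and reuses everywhere.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynsurv import (ClinicalPathway, Cohort, DDHLConfig, Observation,
                     SimConfig, StaticProfile, generate_cohort,
                     generate_planted_clusters, train_ddhl)


def make_static(**kw) -> StaticProfile:
    base = dict(age_at_entry=65.0, family_history=False, ethnicity="white",
                grade_group=1, mri_stage="T1", likert=2, psa_baseline=5.0,
                prostate_volume=50.0, psa_density=0.1, core_positivity=0.1)
    base.update(kw)
    return StaticProfile(**base)


def make_pathway(pid="P1", static=None, obs=(), outcome=None) -> ClinicalPathway:
    return ClinicalPathway(
        patient_id=pid, static=static or make_static(),
        observations=[Observation(**o) if isinstance(o, dict) else o for o in obs],
        outcome=outcome)


@pytest.fixture(scope="session")
def sim_cohort():
    """Default-condition simulated cohort (n=300) with ground truth."""
    return generate_cohort(SimConfig(n_patients=300, seed=0))


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong-signal planted cohort with 4 latent strata (n=600)."""
    return generate_planted_clusters(
        SimConfig(n_patients=600, seed=0, n_latent_strata=4), separation=3.0)


@pytest.fixture(scope="session")
def trained_ddhl(planted_cohort):
    """One recurrent Weibull model trained on 480 planted-cohort patients."""
    cohort, _ = planted_cohort
    train = Cohort(cohort.pathways[:480])
    cfg = DDHLConfig(max_epochs=150, patience=20, learning_rate=2e-3,
                     global_shape=True, ranking_loss_weight=0.2, seed=0)
    return train_ddhl(train, None, cfg)


@pytest.fixture(scope="session")
def planted_test_pathways(planted_cohort):
    cohort, _ = planted_cohort
    return cohort.pathways[480:]
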