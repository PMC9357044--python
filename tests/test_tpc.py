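"""Temporal predictive clustering: curves, actor-critic updates, outputs."""

import numpy as np
import pytest

from dynsurv import Cohort, DDHLConfig, TPCConfig
from dynsurv.ddhl import DDHLModel
from dynsurv.preprocess import FeatureSchema, fit_schema
from dynsurv.tpc import (ClusterModel, assign_trajectory, blackbox_curve,
                         cluster_survival, critic_update, init_tpc,
                         partial_dependence_rank, pca_project, prune_clusters,
                         total_divergence, train_tpc)


@pytest.fixture(scope="module")
def tpc_setup(trained_ddhl, planted_cohort):
    cohort, gt = planted_cohort
    cfg = TPCConfig(seed=0, epochs=60)
    model = train_tpc(trained_ddhl, cohort, cfg)
    model = prune_clusters(model, trained_ddhl, cohort, cfg)
    return trained_ddhl, cohort, gt, model


# ---------------------------------------------------------------------------
# black-box curves

def test_blackbox_curve_is_probability_vector(trained_ddhl,
                                              planted_test_pathways):
    grid = np.asarray(TPCConfig().horizon_grid)
    for p in planted_test_pathways[:20]:
        mass = blackbox_curve(trained_ddhl, p, 500, grid)
        assert mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(mass >= -1e-12)


def test_blackbox_curve_all_tail_when_risk_is_negligible(sim_cohort):
    cohort, _ = sim_cohort
    schema = fit_schema(cohort)
    model = DDHLModel(DDHLConfig(seed=0), schema, log_lam0=20.0)  # huge scale
    model.params["W2"][:] = 0.0
    model.params["b2"][:] = 0.0
    model.trained = True
    mass = blackbox_curve(model, cohort.pathways[0], 0,
                          np.asarray(TPCConfig().horizon_grid))
    assert mass[-1] > 0.999


# ---------------------------------------------------------------------------
# initialization & critic

def test_config_rejects_degenerate_settings():
    with pytest.raises(ValueError):
        TPCConfig(K_max=1)
    with pytest.raises(ValueError):
        TPCConfig(horizon_grid=(100.0, 100.0))


def test_init_is_seeded_and_lowers_k_for_tiny_cohorts(trained_ddhl,
                                                      planted_cohort):
    cohort, _ = planted_cohort
    small = Cohort(cohort.pathways[:30])
    cfg = TPCConfig(seed=3)
    a = init_tpc(trained_ddhl, small, cfg)
    b = init_tpc(trained_ddhl, small, cfg)
    np.testing.assert_array_equal(a.W, b.W)
    np.testing.assert_array_equal(a.curves, b.curves)
    tiny = Cohort(cohort.pathways[:8])
    with pytest.warns(UserWarning, match="lowering K"):
        m = init_tpc(trained_ddhl, tiny, cfg)
    assert 2 <= m.K < 12


def test_critic_update_never_increases_divergence():
    """The member-mean representative is the KL-minimizing summary."""
    rng = np.random.default_rng(7)
    n, K, G = 120, 5, 12
    C = rng.dirichlet(np.ones(G), size=n)
    labels = rng.integers(0, K, n)
    model = ClusterModel(K=K, centroids=np.zeros((K, 3)),
                         curves=rng.dirichlet(np.ones(G), size=K),
                         W=np.zeros((3, K)), b=np.zeros(K),
                         grid=np.arange(1, G) * 100.0)
    before = total_divergence(model, C, labels)
    critic_update(model, C, labels)
    after = total_divergence(model, C, labels)
    assert after <= before + 1e-12
    # a second update with unchanged assignments is a fixed point
    critic_update(model, C, labels)
    assert total_divergence(model, C, labels) == pytest.approx(after)


def test_train_tpc_is_seeded(trained_ddhl, planted_cohort):
    cohort, _ = planted_cohort
    sub = Cohort(cohort.pathways[:80])
    cfg = TPCConfig(seed=5, epochs=15)
    m1 = train_tpc(trained_ddhl, sub, cfg)
    m2 = train_tpc(trained_ddhl, sub, cfg)
    np.testing.assert_array_equal(m1.W, m2.W)
    np.testing.assert_array_equal(m1.curves, m2.curves)


# ---------------------------------------------------------------------------
# pruning, ordering, survival curves

def test_pruned_model_is_risk_ordered(tpc_setup):
    _, _, _, model = tpc_setup
    assert model.K >= 2
    risk5 = model.five_year_risk()
    assert np.all(np.diff(risk5) >= 0)  # canonical numbering: ascending risk
    assert np.allclose(model.curves.sum(axis=1), 1.0, atol=1e-9)


def test_cluster_km_ordering_matches_representative_ordering(tpc_setup):
    ddhl, cohort, _, model = tpc_setup
    E = np.asarray([ddhl.embed(p, p.observations[-1].t if p.observations else 0)
                    for p in cohort.pathways])
    labels = model.assign(E)
    curves = cluster_survival(cohort, labels)
    km5 = [1.0 - curves[c].survival_at(5 * 365) for c in sorted(curves)]
    # clusters are renumbered 1..K by ascending 5-year KM event fraction
    assert km5 == sorted(km5)


def test_cluster_survival_single_cluster_reduces_to_cohort_km(sim_cohort):
    from dynsurv import kaplan_meier
    cohort, _ = sim_cohort
    labels = np.zeros(len(cohort.pathways), dtype=int)
    curves = cluster_survival(cohort, labels)
    assert list(curves) == [1]
    T = [p.outcome.time for p in cohort.pathways]
    d = [p.outcome.event for p in cohort.pathways]
    np.testing.assert_allclose(curves[1].survival,
                               kaplan_meier(T, d).survival)


def test_cluster_survival_label_permutation_equivariance(sim_cohort):
    cohort, _ = sim_cohort
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 3, len(cohort.pathways))
    perm = {0: 7, 1: 2, 2: 5}
    a = cluster_survival(cohort, labels)
    b = cluster_survival(cohort, np.array([perm[x] for x in labels]))
    for c in a:
        np.testing.assert_allclose(a[c].survival, b[c].survival)


# ---------------------------------------------------------------------------
# trajectories

def test_trajectory_single_time(tpc_setup):
    ddhl, cohort, _, model = tpc_setup
    traj = assign_trajectory(model, ddhl, cohort.pathways[0], [365])
    assert len(traj.labels) == 1
    assert traj.probabilities.shape == (1, model.K)
    np.testing.assert_allclose(traj.probabilities.sum(axis=1), 1.0)


def test_stable_low_risk_patient_settles_in_lowest_cluster(tpc_setup):
    """A stably benign patient's risk-ordered label never rises and ends
    in the lowest-risk cluster once follow-up has accumulated."""
    ddhl, cohort, gt, model = tpc_setup
    checked = 0
    for p in cohort.pathways[480:]:
        if (gt.patients[p.patient_id].stratum != 0 or p.outcome.event
                or len(p.observations) < 10):
            continue
        times = [o.t for o in p.observations][1::2]
        traj = assign_trajectory(model, ddhl, p, times)
        assert np.all(np.diff(traj.labels) <= 0)
        assert traj.labels[-1] == 0
        checked += 1
        if checked == 5:
            break
    assert checked >= 3


def test_deteriorating_patient_moves_to_higher_risk_cluster(tpc_setup):
    """When progression is detected, patients never drop to a cluster with
    a lower representative 5-year risk than the one they held at the
    previous visit (and typically move up)."""
    ddhl, cohort, gt, model = tpc_setup
    risk5 = model.five_year_risk()
    moved = total = 0
    for p in cohort.pathways[480:]:
        if not p.outcome.event or len(p.observations) < 3:
            continue
        d = p.outcome.time
        if p.observations[-1].t != d:
            continue
        prev = p.observations[-2].t
        traj = assign_trajectory(model, ddhl, p, [prev, d])
        total += 1
        moved += risk5[traj.labels[1]] >= risk5[traj.labels[0]]
    assert total >= 20
    assert moved / total >= 0.9


# ---------------------------------------------------------------------------
# PCA projection

def test_pca_line_explains_everything():
    t = np.linspace(0, 1, 40)
    E = np.outer(t, [1.0, 2.0, -0.5]) + 3.0
    coords, evr = pca_project(E)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)
    assert coords.shape == (40, 2)


def test_pca_translation_invariance():
    rng = np.random.default_rng(2)
    E = rng.normal(size=(50, 6))
    a, _ = pca_project(E)
    b, _ = pca_project(E + 13.7)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_pca_isotropic_cloud_splits_variance():
    rng = np.random.default_rng(3)
    E = rng.normal(size=(4000, 2))
    _, evr = pca_project(E)
    assert evr[0] == pytest.approx(0.5, abs=0.05)
    assert evr[1] == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# partial dependence

def test_partial_dependence_ranks_null_variable_last(tpc_setup):
    ddhl, cohort, _, model = tpc_setup
    sub = Cohort(cohort.pathways[:120])
    ranks = partial_dependence_rank(model, ddhl, sub,
                                    ["psa", "age", "grade_group"])
    flip = dict(ranks)
    # age has no simulated effect on progression; PSA drives detection
    assert flip["age"] <= 0.05
    assert flip["psa"] >= flip["age"]
    assert ranks[0][0] != "age"


def test_partial_dependence_rejects_unknown_variable(tpc_setup):
    ddhl, cohort, _, model = tpc_setup
    with pytest.raises(ValueError, match="not in the feature schema"):
        partial_dependence_rank(model, ddhl, Cohort(cohort.pathways[:5]),
                                ["bmi"])
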