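"""Recurrent Weibull model: gradients, contracts, training behaviour."""

import copy

import numpy as np
import pytest

from dynsurv import Cohort, DDHLConfig, Outcome, train_ddhl
from dynsurv.ddhl import (AUX_TARGET_IDX, DDHLModel, _loss_and_grads,
                          intercept_weibull_loglik)
from dynsurv.preprocess import MODEL_INPUT_DIM, FeatureSchema, build_sequence, fit_schema
from dynsurv.weibull import weibull_loglik
from .conftest import make_pathway, make_static


# ---------------------------------------------------------------------------
# gradients

@pytest.mark.parametrize("pooling,global_shape", [("mean", True),
                                                  ("last", False),
                                                  ("both", False)])
def test_gradients_match_finite_differences(pooling, global_shape):
    """Analytic backprop through GRU, head, Weibull NLL, ranking and
    step-ahead losses agrees with central finite differences."""
    rng = np.random.default_rng(1)
    cfg = DDHLConfig(hidden_dim=5, head_hidden_dim=4, stepahead_weight=0.7,
                     ranking_loss_weight=0.3, pooling=pooling,
                     global_shape=global_shape, seed=3)
    model = DDHLModel(cfg, FeatureSchema(), np.log(1500.0))
    B, T = 5, 6
    X = rng.normal(size=(B, T, MODEL_INPUT_DIM))
    lengths = np.array([6, 3, 1, 4, 2])
    T_out = rng.uniform(400, 3000, B)
    t_obs = rng.uniform(0, 300, B)
    t_obs[2] = 0.0
    delta = np.array([1.0, 0.0, 1.0, 0.0, 1.0])

    _, grads = _loss_and_grads(model, X, lengths, t_obs, T_out, delta)
    eps = 1e-6
    for key, garr in grads.items():
        arr = model.params[key]
        for idx in [tuple(rng.integers(0, s) for s in arr.shape)
                    for _ in range(3)]:
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = _loss_and_grads(model, X, lengths, t_obs, T_out, delta)[0]
            arr[idx] = orig - eps
            lm = _loss_and_grads(model, X, lengths, t_obs, T_out, delta)[0]
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert garr[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


# ---------------------------------------------------------------------------
# forward contracts

def _fresh_model(schema, **cfg_kw):
    cfg = DDHLConfig(**cfg_kw)
    return DDHLModel(cfg, schema, log_lam0=np.log(1500.0))


def test_forward_deterministic_and_positive(sim_cohort):
    cohort, _ = sim_cohort
    schema = fit_schema(cohort)
    model = _fresh_model(schema, seed=2)
    seq = build_sequence(cohort.pathways[0], 1000, schema)
    e1, wp1 = model.forward(seq)
    e2, wp2 = model.forward(seq)
    np.testing.assert_array_equal(e1, e2)
    assert wp1.shape == wp2.shape and wp1.scale == wp2.scale
    assert 0 < wp1.shape < np.inf and 0 < wp1.scale < np.inf


def test_forward_ignores_padding(sim_cohort):
    """Batch padding beyond a sequence's length never changes its output."""
    cohort, _ = sim_cohort
    schema = fit_schema(cohort)
    model = _fresh_model(schema, seed=2)
    seq = build_sequence(cohort.pathways[1], 800, schema)
    X = seq.model_input()
    n = X.shape[0]
    X_padded = np.vstack([X, np.full((3, X.shape[1]), 7.7)])
    H1, k1, l1 = model.forward_batch(X[None], np.array([n]))
    H2, k2, l2 = model.forward_batch(X_padded[None], np.array([n]))
    np.testing.assert_allclose(H1, H2)
    assert k1[0] == k2[0] and l1[0] == l2[0]


def test_dynamic_risk_contracts(trained_ddhl, planted_test_pathways):
    model = trained_ddhl
    for p in planted_test_pathways[:25]:
        curve = model.dynamic_risk(p, 900, [0, 365, 1095, 1825, 3650])
        assert curve.risk[0] == 0.0
        assert np.all(np.diff(curve.risk) >= 0)
        assert np.all(curve.risk < 1.0)


def test_untrained_model_refuses_risk(sim_cohort):
    cohort, _ = sim_cohort
    model = _fresh_model(fit_schema(cohort), seed=0)
    with pytest.raises(RuntimeError, match="untrained"):
        model.dynamic_risk(cohort.pathways[0], 0, [365])


def test_exponential_head_is_memoryless(sim_cohort):
    """With a stubbed head pinning (k, lam) = (1, 1000), the conditional
    risk reproduces the exponential closed form at any as-of."""
    cohort, _ = sim_cohort
    schema = fit_schema(cohort)
    model = DDHLModel(DDHLConfig(seed=0), schema, log_lam0=np.log(1000.0))
    model.params["W2"][:] = 0.0
    model.params["b2"][:] = 0.0  # a=0 -> k=1; b=0 -> lam=1000
    model.trained = True
    for as_of in (0, 500, 2000):
        r = model.dynamic_risk(cohort.pathways[0], as_of, [1000.0]).risk[0]
        assert r == pytest.approx(1 - np.exp(-1.0), rel=1e-9)


# ---------------------------------------------------------------------------
# training

def _tiny_cohort(sim_cohort, n=60):
    cohort, _ = sim_cohort
    return Cohort(cohort.pathways[:n])


def test_training_is_bit_reproducible(sim_cohort):
    tiny = _tiny_cohort(sim_cohort)
    cfg = DDHLConfig(max_epochs=5, patience=5, seed=11)
    m1 = train_ddhl(tiny, None, cfg)
    m2 = train_ddhl(tiny, None, cfg)
    for key in m1.params:
        np.testing.assert_array_equal(m1.params[key], m2.params[key])
    assert m1.training_log == m2.training_log


def test_zero_epochs_returns_initialized_model(sim_cohort):
    tiny = _tiny_cohort(sim_cohort)
    cfg = DDHLConfig(max_epochs=0, seed=4)
    trained = train_ddhl(tiny, None, cfg)
    fresh = DDHLModel(cfg, trained.schema, trained.log_lam0)
    for key in fresh.params:
        np.testing.assert_array_equal(trained.params[key], fresh.params[key])
    assert not trained.trained


def test_all_censored_warns(sim_cohort):
    tiny = _tiny_cohort(sim_cohort, 40)
    tiny = Cohort([copy.deepcopy(p) for p in tiny.pathways])
    for p in tiny.pathways:
        p.outcome = Outcome(event=False, time=p.outcome.time,
                            censor_reason="last_investigation")
    with pytest.warns(UserWarning, match="all-censored"):
        train_ddhl(tiny, None, DDHLConfig(max_epochs=1, seed=0))


def test_beats_intercept_only_weibull(trained_ddhl, planted_test_pathways):
    """On strong-signal data the history-informed fit's held-out likelihood
    exceeds the best covariate-free Weibull fit."""
    test = Cohort([p for p in planted_test_pathways])
    base_ll = intercept_weibull_loglik(test)
    lls = []
    for p in test.pathways:
        T = p.outcome.time
        as_of = max([0] + [o.t for o in p.observations if o.t < T])
        _, wp = trained_ddhl.forward(
            build_sequence(p, as_of, trained_ddhl.schema))
        lls.append(weibull_loglik(wp.shape, wp.scale, float(T),
                                  float(p.outcome.event)))
    assert np.mean(lls) > base_ll


def test_recovers_covariate_driven_risk_ranking():
    """Weibull data whose log-scale is linear in one covariate: predicted
    risk ordering matches the true risk ordering (rank corr >= 0.9)."""
    from scipy.stats import spearmanr
    from dynsurv.weibull import conditional_risk

    rng = np.random.default_rng(5)
    paths, true_risk = [], []
    for i in range(1000):
        psad = float(rng.uniform(0.05, 0.4))
        lam = float(np.exp(9.0 - 4.0 * psad))
        t_star = lam * rng.weibull(1.5)
        t = int(max(2, min(t_star, 2500)))
        ev = bool(t_star < 2500)
        s = make_static(psa_density=psad, psa_baseline=psad * 50.0,
                        prostate_volume=50.0)
        paths.append(make_pathway(
            f"R{i}", s, obs=[dict(t=150, psa=psad * 50.0, precise=3)],
            outcome=Outcome(event=ev, time=t,
                            cause_scenario="iv" if ev else "none",
                            censor_reason="none" if ev else "last_investigation")))
        true_risk.append(conditional_risk(1.5, lam, 0.0, [1095])[0])
    model = train_ddhl(Cohort(paths[:800]), None,
                       DDHLConfig(max_epochs=120, patience=15,
                                  learning_rate=2e-3, global_shape=True,
                                  seed=1))
    pred = [model.dynamic_risk(p, 0, [1095]).risk[0] for p in paths[800:]]
    rho = spearmanr(pred, true_risk[800:]).statistic
    assert rho >= 0.9


def test_risk_rises_at_qualifying_psa_reading(trained_ddhl,
                                              planted_test_pathways):
    """Dynamic updating: when the PSA crossing that constitutes the
    endpoint is observed, predicted risk increases for >= 90% of the
    affected patients."""
    model = trained_ddhl
    n = inc = 0
    for p in planted_test_pathways:
        if not p.outcome.event or p.outcome.cause_scenario not in ("ii", "iv"):
            continue
        d = p.outcome.time
        if not p.observations or p.observations[-1].t != d or d < 2:
            continue
        before = model.dynamic_risk(p, d - 1, [1825]).risk[0]
        after = model.dynamic_risk(p, d, [1825]).risk[0]
        n += 1
        inc += after > before
    assert n >= 20
    assert inc / n >= 0.9


def test_checkpoint_round_trip(tmp_path, trained_ddhl, planted_test_pathways):
    trained_ddhl.save(tmp_path / "model")
    back = DDHLModel.load(tmp_path / "model")
    p = planted_test_pathways[0]
    a = trained_ddhl.dynamic_risk(p, 700, [1095, 1825]).risk
    b = back.dynamic_risk(p, 700, [1095, 1825]).risk
    np.testing.assert_array_equal(a, b)
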