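"""Baseline and landmarking Cox proportional-hazards comparators.

The partial-likelihood maximization is delegated to scikit-survival
(Breslow tie handling); risk-set construction, landmark covariate
resolution, the Breslow baseline cumulative hazard and the conditional
risk prediction are implemented here.

A landmark model at day L is fitted on patients still event-free and
uncensored at L, with each patient's latest LOCF-resolved covariate
values at L and the time origin shifted to L.  ``landmark=0`` with
baseline covariates reproduces the standard baseline-covariates-only
Cox model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import ClinicalPathway, Cohort
from .ddhl import RiskCurve
from .preprocess import (FeatureSchema, encode_state, feature_names,
                         fit_schema, impute_baseline, resolve_state_at)

logger = logging.getLogger(__name__)

# reference one-hot levels dropped from the Cox design (a Cox model has no
# intercept, but two complete one-hot groups would be collinear)
_REFERENCE_LEVELS = {"grade_group=1", "precise=1", "likert=1", "mri_stage=T1"}


@dataclass
class CoxModel:
    coefficients: dict  # feature name -> coefficient
    landmark: int
    baseline_hazard_times: np.ndarray  # days since landmark
    baseline_hazard: np.ndarray  # Breslow cumulative hazard steps
    schema: FeatureSchema
    kept: list = field(default_factory=list)  # column indices into encode_state

    def linear_predictor(self, x_full: np.ndarray) -> float:
        coef = np.array(list(self.coefficients.values()))
        return float(x_full[self.kept] @ coef)

    def cumulative_hazard(self, t: float, warn: bool = True) -> float:
        """Breslow H0 at time t since landmark; carries the last value."""
        if self.baseline_hazard_times.size == 0:
            return 0.0
        if warn and t > self.baseline_hazard_times[-1]:
            logger.warning("horizon %s beyond last baseline-hazard step %s; "
                           "carrying last value", t, self.baseline_hazard_times[-1])
        i = np.searchsorted(self.baseline_hazard_times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.baseline_hazard[i])


def _design_matrix(cohort: Cohort, landmark: int, schema: FeatureSchema):
    rows = []
    for p in cohort.pathways:
        state = resolve_state_at(p, landmark, schema)
        rows.append(encode_state(state, p.static, schema))
    return np.asarray(rows)


def _breslow(X: np.ndarray, time: np.ndarray, event: np.ndarray,
             coef: np.ndarray):
    """Breslow cumulative baseline hazard at the event times."""
    eta = X @ coef
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    exp_eta = np.exp(eta[order])
    # denominator: sum of exp(eta) over the risk set {j : T_j >= t}
    denom_from = np.cumsum(exp_eta[::-1])[::-1]
    uniq = np.unique(t_sorted[e_sorted > 0])
    H = np.zeros(len(uniq))
    acc = 0.0
    for i, t in enumerate(uniq):
        first = np.searchsorted(t_sorted, t, side="left")
        d = float(e_sorted[t_sorted == t].sum())
        acc += d / denom_from[first]
        H[i] = acc
    return uniq, H


def fit_landmark_cox(train: Cohort, landmark: int = 0,
                     schema: Optional[FeatureSchema] = None) -> CoxModel:
    """Fit a Cox model at a landmark time (0 = baseline model)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    if landmark < 0:
        raise ValueError("landmark must be >= 0")
    schema = schema or fit_schema(train)
    train = impute_baseline(train, schema)
    at_risk = [p for p in train.pathways
               if p.outcome is not None and p.outcome.time > landmark]
    events = np.array([p.outcome.event for p in at_risk], dtype=float)
    if events.sum() < 2:
        raise ValueError(
            f"fewer than 2 events in the landmark-{landmark} risk set")
    sub = Cohort(at_risk)
    X_full = _design_matrix(sub, landmark, schema)
    names = feature_names()
    kept = [i for i, nm in enumerate(names)
            if nm not in _REFERENCE_LEVELS and X_full[:, i].std() > 1e-12]
    X = X_full[:, kept]
    time = np.array([p.outcome.time - landmark for p in at_risk], dtype=float)
    y = Surv.from_arrays(event=events.astype(bool), time=time)
    est = CoxPHSurvivalAnalysis(alpha=1e-6, n_iter=200)
    try:
        est.fit(X, y)
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Cox fit failed at landmark {landmark} "
            f"(n={len(at_risk)}, events={int(events.sum())}): {exc}") from exc
    coef = est.coef_
    if not np.all(np.isfinite(coef)):
        raise RuntimeError(f"non-finite Cox coefficients at landmark {landmark}")
    h_t, h = _breslow(X, time, events, coef)
    return CoxModel(
        coefficients={names[i]: float(c) for i, c in zip(kept, coef)},
        landmark=int(landmark), baseline_hazard_times=h_t, baseline_hazard=h,
        schema=schema, kept=kept)


def fit_baseline_cox(train: Cohort,
                     schema: Optional[FeatureSchema] = None) -> CoxModel:
    """Standard Cox model using baseline variables only."""
    return fit_landmark_cox(train, landmark=0, schema=schema)


def cox_risk(model: CoxModel, pathway: ClinicalPathway, as_of: int,
             horizons) -> RiskCurve:
    """Conditional risk F(dt) = 1 - exp(-[H0(t1) - H0(t0)] e^(x'beta)).

    Covariates are the pathway's values as resolved at the model's
    landmark; times are measured on the model's shifted origin.
    """
    if as_of < model.landmark:
        raise ValueError("as_of must be >= the model landmark")
    state = resolve_state_at(pathway, model.landmark, model.schema)
    x_full = encode_state(state, pathway.static, model.schema)
    eta = model.linear_predictor(x_full)
    t0 = as_of - model.landmark
    horizons = np.asarray(horizons, dtype=float)
    H0 = model.cumulative_hazard(t0, warn=False)
    risk = np.array([
        1.0 - np.exp(-(model.cumulative_hazard(t0 + dt) - H0) * np.exp(eta))
        for dt in horizons])
    return RiskCurve(as_of=int(as_of), horizons=horizons,
                     risk=np.clip(risk, 0.0, 1.0 - 1e-15))
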