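"""Longitudinal model evaluation: time-dependent C-index and Brier score,
Kaplan-Meier estimation, and the repeated 80/20 split protocol.

Metrics follow the dynamic-prediction convention: a prediction made at
time t_pred (using only data collected up to t_pred) is scored over the
window (t_pred, t_pred + horizon], among subjects still event-free at
t_pred.  Horizons are measured from the prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .cohort import ClinicalPathway, Cohort

logger = logging.getLogger(__name__)


@dataclass
class EvalGrid:
    prediction_times: tuple = (0, 365, 730, 1095)  # days of data collection
    horizons: tuple = (3 * 365, 5 * 365)  # days ahead of prediction time

    def __post_init__(self):
        for v in (self.prediction_times, self.horizons):
            arr = np.asarray(v)
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise ValueError("grid vectors must be non-negative and increasing")


# ---------------------------------------------------------------------------
# time-dependent concordance

def td_c_index(risks, outcomes, t_pred: float, horizon: float) -> float:
    """Time-dependent concordance for predictions made at ``t_pred``.

    ``outcomes`` is a sequence of (T, delta).  Ordered pairs (i, j) are
    comparable when subject i has an observed event inside the window
    (t_pred, t_pred + horizon] and subject j outlives T_i.  A higher
    predicted risk for i counts as concordant; ties count 1/2.  Returns
    NaN when no pair is comparable.
    """
    risks = np.asarray(risks, dtype=float)
    T = np.asarray([o[0] for o in outcomes], dtype=float)
    delta = np.asarray([o[1] for o in outcomes], dtype=float)
    cases = np.where((delta > 0) & (T > t_pred) & (T <= t_pred + horizon))[0]
    concordant = 0.0
    pairs = 0
    for i in cases:
        js = np.where(T > T[i])[0]
        pairs += len(js)
        concordant += float(np.sum(risks[i] > risks[js]))
        concordant += 0.5 * float(np.sum(risks[i] == risks[js]))
    if pairs == 0:
        return float("nan")
    return concordant / pairs


# ---------------------------------------------------------------------------
# IPCW Brier score

def _censoring_km(T, delta):
    """Kaplan-Meier of the censoring distribution G(t) = P(C > t)."""
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter()
    kmf.fit(T, event_observed=1 - delta)
    sf = kmf.survival_function_
    return sf.index.values.astype(float), sf.iloc[:, 0].values.astype(float)


def _step_at(xs, ys, t, left_limit=False):
    side = "left" if left_limit else "right"
    i = np.searchsorted(xs, t, side=side) - 1
    return 1.0 if i < 0 else float(ys[i])


def td_brier(risks, outcomes, t_pred: float, horizon: float,
             ipcw: bool = True) -> float:
    """Inverse-probability-of-censoring weighted Brier score.

    Subjects event-free at t_pred contribute (1{event in window} - risk)^2;
    events are weighted by 1/G(T-), window survivors by 1/G(t_pred+horizon),
    both normalized by G(t_pred) since the population is conditioned on
    being at risk at t_pred.  Subjects censored inside the window are
    dropped (their weight is zero).  Without censoring this reduces to the
    unweighted mean squared error.
    """
    risks = np.asarray(risks, dtype=float)
    T = np.asarray([o[0] for o in outcomes], dtype=float)
    delta = np.asarray([o[1] for o in outcomes], dtype=float)
    eligible = T > t_pred
    if not np.any(eligible):
        return float("nan")
    risks, T, delta = risks[eligible], T[eligible], delta[eligible]
    t_end = t_pred + horizon

    if ipcw:
        gx, gy = _censoring_km(T, delta)
        G_tpred = _step_at(gx, gy, t_pred)
        G_end = _step_at(gx, gy, t_end)
    else:
        G_tpred = G_end = 1.0

    total = 0.0
    n = len(T)
    dropped = 0
    for i in range(n):
        if delta[i] > 0 and T[i] <= t_end:
            G = _step_at(gx, gy, T[i], left_limit=True) if ipcw else 1.0
            if G <= 0:
                dropped += 1
                continue
            total += (1.0 - risks[i]) ** 2 * (G_tpred / G)
        elif T[i] > t_end:
            if G_end <= 0:
                dropped += 1
                continue
            total += (0.0 - risks[i]) ** 2 * (G_tpred / G_end)
        # censored inside the window: weight 0
    if dropped:
        logger.info("td_brier dropped %d subjects with zero censoring "
                    "survival", dropped)
    return total / n


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMEstimate:
    """Product-limit survival estimate with a Greenwood log-log 95% band."""

    times: np.ndarray
    survival: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else float(out[0])


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan-Meier estimate with 95% confidence band (log-log)."""
    from lifelines import KaplanMeierFitter
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KMEstimate(
        times=sf.index.values.astype(float),
        survival=sf.iloc[:, 0].values.astype(float),
        lower=ci.iloc[:, 0].values.astype(float),
        upper=ci.iloc[:, 1].values.astype(float),
        n=int(times.size),
    )


# ---------------------------------------------------------------------------
# model arms for the split protocol

class ModelArm:
    """A model entering the protocol: fit on train, predict risks."""

    name = "arm"

    def fit(self, train: Cohort, seed: int, grid: EvalGrid) -> None:
        raise NotImplementedError

    def predict(self, pathway: ClinicalPathway, t_pred: int,
                horizons) -> np.ndarray:
        raise NotImplementedError


class CoxArm(ModelArm):
    name = "cox"

    def fit(self, train, seed, grid):
        from .cox import fit_baseline_cox
        self.model = fit_baseline_cox(train)

    def predict(self, pathway, t_pred, horizons):
        from .cox import cox_risk
        return cox_risk(self.model, pathway, t_pred, horizons).risk


class LandmarkCoxArm(ModelArm):
    name = "landmark-cox"

    def fit(self, train, seed, grid):
        from .cox import fit_landmark_cox
        self.models = {}
        for t in grid.prediction_times:
            self.models[t] = fit_landmark_cox(train, landmark=int(t))

    def predict(self, pathway, t_pred, horizons):
        from .cox import cox_risk
        return cox_risk(self.models[t_pred], pathway, t_pred, horizons).risk


class DDHLArm(ModelArm):
    name = "ddhl"

    def __init__(self, cfg=None):
        from .ddhl import DDHLConfig
        self.cfg = cfg or DDHLConfig()

    def fit(self, train, seed, grid):
        import dataclasses
        from .ddhl import train_ddhl
        cfg = dataclasses.replace(self.cfg, seed=int(seed))
        self.model = train_ddhl(train, None, cfg)

    def predict(self, pathway, t_pred, horizons):
        return self.model.dynamic_risk(pathway, t_pred, horizons).risk


class ConstantArm(ModelArm):
    """Uninformative comparator predicting the training event rate."""

    name = "constant"

    def fit(self, train, seed, grid):
        ev = [p.outcome.event for p in train.pathways]
        self.rate = float(np.mean(ev)) if ev else 0.5

    def predict(self, pathway, t_pred, horizons):
        return np.full(len(np.atleast_1d(horizons)), self.rate)


class OracleArm(ModelArm):
    """Predicts with the simulator's exact conditional risk."""

    name = "oracle"

    def __init__(self, truth_fn: Callable):
        # truth_fn(patient_id, as_of, horizon) -> probability
        self.truth_fn = truth_fn

    def fit(self, train, seed, grid):
        pass

    def predict(self, pathway, t_pred, horizons):
        return np.array([self.truth_fn(pathway.patient_id, t_pred, h)
                         for h in np.atleast_1d(horizons)])


# ---------------------------------------------------------------------------
# protocol

def run_protocol(cohort: Cohort, models: dict, grid: Optional[EvalGrid] = None,
                 n_splits: int = 5, train_fraction: float = 0.8,
                 seed: int = 0) -> pd.DataFrame:
    """Repeated random-split evaluation over a prediction-time x horizon grid.

    For each split the requested models are trained on the train fraction
    and scored on the held-out fraction: at each prediction time only the
    data collected up to that time is used, and subjects whose outcome
    precedes the prediction time are excluded.  Returns a tidy frame with
    mean and sd over splits per (model, prediction_time, horizon, metric).
    A model failure on a split is recorded as missing and the protocol
    continues.
    """
    grid = grid or EvalGrid()
    rng = np.random.default_rng(seed)
    n = len(cohort.pathways)
    n_train = int(round(train_fraction * n))
    records = []
    split_indices = []
    for split in range(n_splits):
        split_seed = int(rng.integers(0, 2 ** 31 - 1))
        perm = np.random.default_rng(split_seed).permutation(n)
        split_indices.append((perm[:n_train].tolist(), perm[n_train:].tolist()))
        train = Cohort([cohort.pathways[i] for i in perm[:n_train]])
        test = Cohort([cohort.pathways[i] for i in perm[n_train:]])
        for name, arm in models.items():
            try:
                arm.fit(train, seed=split_seed, grid=grid)
            except Exception as exc:
                logger.warning("split %d: %s failed to fit: %s", split, name, exc)
                continue
            for t_pred in grid.prediction_times:
                at_risk = [p for p in test.pathways if p.outcome.time > t_pred]
                if not at_risk:
                    continue
                outcomes = [(p.outcome.time, float(p.outcome.event))
                            for p in at_risk]
                try:
                    risk_mat = np.array([
                        arm.predict(p, int(t_pred), np.asarray(grid.horizons))
                        for p in at_risk])
                except Exception as exc:
                    logger.warning("split %d: %s failed to predict at t=%s: %s",
                                   split, name, t_pred, exc)
                    continue
                for hi, horizon in enumerate(grid.horizons):
                    risks = risk_mat[:, hi]
                    records.append({
                        "split": split, "model": name,
                        "prediction_time_days": int(t_pred),
                        "horizon_days": int(horizon),
                        "c_index": td_c_index(risks, outcomes, t_pred, horizon),
                        "brier": td_brier(risks, outcomes, t_pred, horizon),
                    })
    raw = pd.DataFrame.from_records(records)
    if raw.empty:
        return raw
    long = raw.melt(
        id_vars=["split", "model", "prediction_time_days", "horizon_days"],
        value_vars=["c_index", "brier"], var_name="metric")
    out = (long.groupby(["model", "prediction_time_days", "horizon_days",
                         "metric"], as_index=False)
           .agg(mean=("value", "mean"), sd=("value", "std"),
                n_splits=("value", "count")))
    out.attrs["raw"] = raw
    out.attrs["splits"] = split_indices
    return out
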