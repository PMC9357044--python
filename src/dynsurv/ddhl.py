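"""Recurrent Weibull time-to-event model with dynamic risk updates.

The model (a lightweight Dynamic-DeepHit variant) encodes a patient's
clinical pathway with a GRU over the encoded observation sequence
(features + missingness mask + inter-visit gap) and maps the final
hidden state to the shape/scale pair (k, lam) of a conditional Weibull
time-to-event distribution.  Training maximizes the censored Weibull
log-likelihood left-truncated at the sequence's as-of time, so one
network serves every prediction time; each patient contributes one
uniformly sampled as-of per epoch, which teaches the encoder dynamic
prediction.

Risk output is always conditional: F(dt | as_of) = 1 - S(as_of+dt)/S(as_of),
a valid (non-decreasing, F(0)=0) risk function by construction.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import _nn
from .cohort import ClinicalPathway, Cohort
from .preprocess import (CONTINUOUS, FeatureSchema, MODEL_INPUT_DIM,
                         N_FEATURES, SequenceTensor, VELOCITY_FEATURES,
                         build_sequence, fit_schema, impute_baseline)
from .weibull import conditional_risk

# channels the auxiliary step-ahead head predicts: the continuous markers
# and their velocity channels
AUX_TARGET_IDX = list(range(len(CONTINUOUS))) + [
    N_FEATURES + j for j in range(len(VELOCITY_FEATURES))]


@dataclass
class DDHLConfig:
    hidden_dim: int = 32
    encoder_layers: int = 1  # single-layer GRU (the supported depth)
    head_hidden_dim: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    ranking_loss_weight: float = 0.0
    stepahead_weight: float = 0.0  # next-observation auxiliary loss weight
    global_shape: bool = False  # share one Weibull shape across histories
    pooling: str = "mean"  # sequence summary: "mean" over steps or "last"
    val_fraction: float = 0.15  # used when no explicit validation cohort
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_dim, self.head_hidden_dim, self.batch_size) <= 0:
            raise ValueError("dimensions and batch size must be positive")
        if self.encoder_layers != 1:
            raise ValueError("only a single-layer encoder is supported")


@dataclass
class WeibullParams:
    shape: float  # k, dimensionless
    scale: float  # lam, days


@dataclass
class RiskCurve:
    as_of: int
    horizons: np.ndarray  # days since as_of
    risk: np.ndarray  # cumulative conditional event probability


class DDHLModel:
    """Trained (or initialized) recurrent Weibull survival model."""

    def __init__(self, cfg: DDHLConfig, schema: FeatureSchema,
                 log_lam0: float):
        self.cfg = cfg
        self.schema = schema
        self.log_lam0 = float(log_lam0)
        rng = np.random.default_rng(cfg.seed)
        head_in = cfg.hidden_dim * (2 if cfg.pooling == "both" else 1)
        self.params = _nn.init_params(rng, MODEL_INPUT_DIM, cfg.hidden_dim,
                                      cfg.head_hidden_dim,
                                      head_input_dim=head_in)
        self.params.update(_nn.init_aux_head(rng, cfg.hidden_dim,
                                             len(AUX_TARGET_IDX)))
        self.params["a_glob"] = np.zeros(1)
        self.trained = False
        self.training_log: list[dict] = []

    # -- forward -----------------------------------------------------------
    def _head_outputs(self, H: np.ndarray):
        a, b, head_cache = _nn.head_forward(self.params, H)
        if self.cfg.global_shape:
            a = np.full_like(a, self.params["a_glob"][0])
        return a, b, head_cache

    def forward_batch(self, X: np.ndarray, lengths: np.ndarray):
        H, _ = _nn.gru_forward(self.params, X, lengths,
                               pool=self.cfg.pooling)
        a, b, _ = self._head_outputs(H)
        k, lam = _nn.params_to_weibull(a, b, self.log_lam0)
        return H, k, lam

    def forward(self, seq: SequenceTensor):
        """Embed one sequence; return (embedding, WeibullParams)."""
        X = seq.model_input()
        if X.shape[1] != MODEL_INPUT_DIM:
            raise ValueError(
                f"feature dimension {X.shape[1]} != schema dimension {MODEL_INPUT_DIM}")
        H, k, lam = self.forward_batch(X[None, :, :],
                                       np.array([X.shape[0]]))
        return H[0], WeibullParams(shape=float(k[0]), scale=float(lam[0]))

    def embed(self, pathway: ClinicalPathway, as_of: int) -> np.ndarray:
        return self.forward(build_sequence(pathway, as_of, self.schema))[0]

    def dynamic_risk(self, pathway: ClinicalPathway, as_of: int,
                     horizons) -> RiskCurve:
        """Conditional cumulative risk at each horizon since ``as_of``."""
        if not self.trained:
            raise RuntimeError("model is untrained; call train_ddhl first")
        _, wp = self.forward(build_sequence(pathway, int(as_of), self.schema))
        horizons = np.asarray(horizons, dtype=float)
        risk = conditional_risk(wp.shape, wp.scale, float(as_of), horizons)
        return RiskCurve(as_of=int(as_of), horizons=horizons, risk=risk)

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "params.npz", **self.params)
        self.schema.to_json(d / "schema.json")
        meta = {"format": "dynsurv-ddhl-v1", "config": asdict(self.cfg),
                "log_lam0": self.log_lam0, "trained": self.trained}
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "DDHLModel":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        model = cls(DDHLConfig(**meta["config"]),
                    FeatureSchema.from_json(d / "schema.json"),
                    meta["log_lam0"])
        with np.load(d / "params.npz") as npz:
            model.params = {k: npz[k].copy() for k in npz.files}
        model.trained = meta["trained"]
        return model


# ---------------------------------------------------------------------------
# training data assembly

def _prepare_records(cohort: Cohort, schema: FeatureSchema) -> list[dict]:
    recs = []
    for p in cohort.pathways:
        if p.outcome is None:
            raise ValueError(f"pathway {p.patient_id} has no derived outcome")
        T = float(p.outcome.time)
        last = p.observations[-1].t if p.observations else 0
        seq = build_sequence(p, last, schema)
        X = seq.model_input()
        eligible = [L for L in range(1, X.shape[0] + 1)
                    if seq.times[L - 1] < T]
        if not eligible:
            eligible = [1]
        recs.append({"pid": p.patient_id, "X": X, "times": seq.times,
                     "T": max(T, 1.0), "delta": float(p.outcome.event),
                     "eligible": np.asarray(eligible)})
    return recs


def _pad_batch(recs: list[dict], lengths: np.ndarray):
    B = len(recs)
    maxL = int(lengths.max())
    D = recs[0]["X"].shape[1]
    X = np.zeros((B, maxL, D))
    t_obs = np.zeros(B)
    T = np.zeros(B)
    delta = np.zeros(B)
    for i, (r, L) in enumerate(zip(recs, lengths)):
        X[i, :L, :] = r["X"][:L, :]
        t_obs[i] = r["times"][L - 1]
        T[i] = r["T"]
        delta[i] = r["delta"]
    return X, t_obs, T, delta


def _all_prefix_batch(recs: list[dict]):
    """Every eligible prefix of every record, with per-patient weights.

    Each patient's prefixes share one unit of weight so patients with
    long histories do not dominate the objective.
    """
    out_recs, out_lens, out_w = [], [], []
    for r in recs:
        w = 1.0 / len(r["eligible"])
        for L in r["eligible"]:
            out_recs.append(r)
            out_lens.append(L)
            out_w.append(w)
    return out_recs, np.asarray(out_lens), np.asarray(out_w)


# ---------------------------------------------------------------------------
# ranking penalty (optional, off by default)

def _ranking_loss(a, b, t_obs, T, delta, log_lam0, horizon=1095.0, sigma=0.1):
    k, lam = _nn.params_to_weibull(a, b, log_lam0)
    loglam = np.log(lam)
    h0 = np.where(t_obs > 0, np.exp(k * (np.log(np.maximum(t_obs, 1.0)) - loglam)), 0.0)
    s1 = np.log(t_obs + horizon) - loglam
    h1 = np.exp(np.minimum(k * s1, _nn.EXP_CLAMP))
    F = 1.0 - np.exp(h0 - h1)
    # pairs: i an event, j surviving past T_i
    ii, jj = np.where((delta[:, None] > 0) & (T[:, None] < T[None, :]))
    if len(ii) == 0:
        return 0.0, np.zeros_like(a), np.zeros_like(b)
    eta = np.exp((F[jj] - F[ii]) / sigma)
    loss = float(eta.mean())
    dF = np.zeros_like(F)
    np.add.at(dF, jj, eta / sigma / len(ii))
    np.add.at(dF, ii, -eta / sigma / len(ii))
    # dF/d(a,b) through h0 and h1
    s0 = np.where(t_obs > 0, np.log(np.maximum(t_obs, 1.0)) - loglam, 0.0)
    dexp = -np.exp(h0 - h1)  # dF/d(h0-h1) = -exp(h0-h1)
    d_da = dexp * k * (h0 * s0 - h1 * s1)
    d_db = dexp * (-k) * (h0 - h1)
    return loss, dF * d_da, dF * d_db


# ---------------------------------------------------------------------------
# training

def _loss_and_grads(model: DDHLModel, X, lengths, t_obs, T, delta,
                    weights=None):
    p = model.params
    H, (gru_cache, h_seq) = _nn.gru_forward(p, X, lengths,
                                            pool=model.cfg.pooling)
    a, b, head_cache = _nn.head_forward(p, H)
    if model.cfg.global_shape:
        a_eff = np.full_like(a, p["a_glob"][0])
    else:
        a_eff = a
    nll, da, db = _nn.weibull_nll(a_eff, b, T, delta, t_obs, model.log_lam0,
                                  weights)
    loss = nll
    if model.cfg.ranking_loss_weight > 0:
        rl, rda, rdb = _ranking_loss(a_eff, b, t_obs, T, delta, model.log_lam0)
        loss += model.cfg.ranking_loss_weight * rl
        da = da + model.cfg.ranking_loss_weight * rda
        db = db + model.cfg.ranking_loss_weight * rdb
    grads = {}
    if model.cfg.global_shape:
        grads["a_glob"] = np.array([da.sum()])
        da = np.zeros_like(da)
    else:
        grads["a_glob"] = np.zeros(1)
    dh_seq = None
    if model.cfg.stepahead_weight > 0:
        aux_loss, aux_g, dh_seq = _nn.stepahead_loss(p, h_seq, X, lengths,
                                                     AUX_TARGET_IDX)
        loss += model.cfg.stepahead_weight * aux_loss
        grads["Waux"] = model.cfg.stepahead_weight * aux_g["Waux"]
        grads["baux"] = model.cfg.stepahead_weight * aux_g["baux"]
        dh_seq = model.cfg.stepahead_weight * dh_seq
    head_g, dH = _nn.head_backward(p, head_cache, da, db)
    grads.update(head_g)
    grads.update(_nn.gru_backward(p, gru_cache, dH, lengths=lengths,
                                  pool=model.cfg.pooling, dh_seq=dh_seq))
    return loss, grads


def _eval_loss(model: DDHLModel, recs: list[dict]) -> float:
    brecs, lens, w = _all_prefix_batch(recs)
    X, t_obs, T, delta = _pad_batch(brecs, lens)
    H, _ = _nn.gru_forward(model.params, X, lens, pool=model.cfg.pooling)
    a, b, _ = model._head_outputs(H)
    nll, _, _ = _nn.weibull_nll(a, b, T, delta, t_obs, model.log_lam0, w)
    return nll


def train_ddhl(train: Cohort, val: Optional[Cohort], cfg: DDHLConfig,
               schema: Optional[FeatureSchema] = None) -> DDHLModel:
    """Fit the model on ``train`` with early stopping on ``val`` loss.

    Cohorts must have derived outcomes.  When ``val`` is None a fraction
    of the training cohort (cfg.val_fraction) is reserved.  Fully
    reproducible given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if val is None:
        idx = rng.permutation(len(train.pathways))
        n_val = max(1, int(round(cfg.val_fraction * len(idx))))
        val = Cohort([train.pathways[i] for i in idx[:n_val]])
        train = Cohort([train.pathways[i] for i in idx[n_val:]])
    if not val.pathways:
        raise ValueError("validation cohort is empty")

    schema = schema or fit_schema(train)
    train = impute_baseline(train, schema)
    val = impute_baseline(val, schema)

    times = np.array([p.outcome.time for p in train.pathways], dtype=float)
    events = np.array([p.outcome.event for p in train.pathways])
    if not events.any():
        import warnings
        warnings.warn("all-censored training set: Weibull scale is weakly "
                      "identified", stacklevel=2)
    log_lam0 = float(np.log(np.median(times)))

    model = DDHLModel(cfg, schema, log_lam0)
    if cfg.max_epochs == 0:
        return model

    train_recs = _prepare_records(train, schema)
    val_recs = _prepare_records(val, schema)
    opt = _nn.Adam(model.params, lr=cfg.learning_rate)

    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    bad_epochs = 0
    n = len(train_recs)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            # every eligible as-of of every selected patient, each patient
            # contributing one unit of weight
            brecs, lens, w = _all_prefix_batch([train_recs[i] for i in sel])
            X, t_obs, T, delta = _pad_batch(brecs, lens)
            loss, grads = _loss_and_grads(model, X, lens, t_obs, T, delta, w)
            opt.step(model.params, grads)
            ep_loss += loss * len(sel)
        val_loss = _eval_loss(model, val_recs)
        model.training_log.append({"epoch": epoch, "train_loss": ep_loss / n,
                                   "val_loss": val_loss})
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_params = copy.deepcopy(model.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.params = best_params
    model.trained = True
    return model


def intercept_weibull_loglik(cohort: Cohort) -> float:
    """Mean log-likelihood of the best intercept-only Weibull fit.

    Serves as the covariate-free baseline the trained model must beat on
    informative data.  Maximizes the (uncensored-at-0) likelihood over a
    grid refined by scipy.
    """
    from scipy.optimize import minimize
    from .weibull import weibull_loglik

    T = np.array([p.outcome.time for p in cohort.pathways], dtype=float)
    delta = np.array([float(p.outcome.event) for p in cohort.pathways])

    def neg(theta):
        k, lam = np.exp(theta)
        return -weibull_loglik(k, lam, T, delta, 0.0).mean()

    res = minimize(neg, x0=[0.0, np.log(np.median(T))], method="Nelder-Mead")
    return -res.fun
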