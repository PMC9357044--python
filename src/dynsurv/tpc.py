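"""Actor-critic temporal predictive clustering over a frozen survival model.

The trained recurrent Weibull model is treated as a black box: each
patient history is summarized by its predicted discrete time-to-event
distribution (probability mass over horizon-grid intervals plus a
beyond-horizon tail).  Clusters group histories whose predicted
distributions are similar:

  * the *critic* updates each cluster's representative distribution to
    the KL-minimizing summary (the member mean) of its members' curves;
  * the *actor* is a softmax selector over the model's latent embedding,
    trained by policy gradient on the negative KL divergence between a
    history's curve and its sampled cluster's representative, with an
    entropy penalty encouraging confident assignments.

The cluster count is data-driven: clusters start at K_max and are
pruned by occupancy and merged by representative-curve divergence.
Final numbering is canonical: ascending 5-year representative risk
(cluster 1 = lowest risk).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import ClinicalPathway, Cohort
from .ddhl import DDHLModel
from .evaluation import KMEstimate, kaplan_meier
from .preprocess import build_sequence
from .weibull import conditional_risk

logger = logging.getLogger(__name__)

_EPS = 1e-10


def _default_grid() -> tuple:
    # 6-month steps to 10 years
    return tuple(182.5 * i for i in range(1, 21))


@dataclass
class TPCConfig:
    K_max: int = 12
    horizon_grid: tuple = field(default_factory=_default_grid)
    selector_hidden_dim: int = 0  # 0 = linear softmax selector
    learning_rate: float = 0.05
    epochs: int = 150
    entropy_weight: float = 0.01
    min_occupancy: float = 0.02
    merge_divergence: float = 0.10  # symmetric KL below which clusters merge
    seed: int = 0

    def __post_init__(self):
        if self.K_max < 2:
            raise ValueError("K_max must be >= 2")
        grid = np.asarray(self.horizon_grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("horizon_grid must be strictly increasing")


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray  # [K, hidden_dim] embedding-space centroids
    curves: np.ndarray  # [K, len(grid)+1] representative distributions
    W: np.ndarray  # selector weights [hidden_dim, K]
    b: np.ndarray  # selector bias [K]
    grid: np.ndarray

    def predict_proba(self, E: np.ndarray) -> np.ndarray:
        logits = np.atleast_2d(E) @ self.W + self.b
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def assign(self, E: np.ndarray) -> np.ndarray:
        return self.predict_proba(E).argmax(axis=1)

    def five_year_risk(self) -> np.ndarray:
        """Cumulative representative mass within 5 years, per cluster."""
        within = self.grid <= 5 * 365
        return self.curves[:, :-1][:, within].sum(axis=1)


@dataclass
class ClusterTrajectory:
    patient_id: str
    times: np.ndarray
    labels: np.ndarray
    probabilities: np.ndarray  # [n_times, K]


# ---------------------------------------------------------------------------
# black-box interface to the survival model

def blackbox_curve(ddhl: DDHLModel, pathway: ClinicalPathway, as_of: int,
                   grid) -> np.ndarray:
    """Discrete predicted time-to-event distribution over grid intervals.

    First differences of the conditional risk curve on the grid, plus a
    terminal beyond-horizon bin; sums to 1.
    """
    grid = np.asarray(grid, dtype=float)
    F = ddhl.dynamic_risk(pathway, as_of, grid).risk
    mass = np.diff(F, prepend=0.0)
    tail = 1.0 - F[-1]
    return np.concatenate([mass, [tail]])


def _kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """KL(p || q) along the last axis, with an epsilon floor."""
    p = np.clip(p, _EPS, None)
    q = np.clip(q, _EPS, None)
    return np.sum(p * (np.log(p) - np.log(q)), axis=-1)


def _prefix_cache(ddhl: DDHLModel, cohort: Cohort, grid):
    """Embeddings and black-box curves at every usable as-of per patient."""
    cache = []
    for p in cohort.pathways:
        T = p.outcome.time if p.outcome is not None else np.inf
        as_ofs = [0] + [o.t for o in p.observations if o.t < T]
        E, C = [], []
        for a in as_ofs:
            emb, wp = ddhl.forward(build_sequence(p, a, ddhl.schema))
            E.append(emb)
            F = conditional_risk(wp.shape, wp.scale, float(a),
                                 np.asarray(grid, dtype=float))
            mass = np.diff(F, prepend=0.0)
            C.append(np.concatenate([mass, [1.0 - F[-1]]]))
        cache.append({"pid": p.patient_id, "as_ofs": np.asarray(as_ofs),
                      "E": np.asarray(E), "C": np.asarray(C)})
    return cache


# ---------------------------------------------------------------------------
# initialization

def init_tpc(ddhl: DDHLModel, cohort: Cohort, cfg: TPCConfig) -> ClusterModel:
    """K-means initialization in embedding space + selector pretraining."""
    from sklearn.cluster import KMeans
    from sklearn.linear_model import LogisticRegression

    grid = np.asarray(cfg.horizon_grid)
    cache = _prefix_cache(ddhl, cohort, grid)
    E_last = np.asarray([c["E"][-1] for c in cache])
    C_last = np.asarray([c["C"][-1] for c in cache])
    K = cfg.K_max
    if len(cohort.pathways) < K:
        K = max(2, len(cohort.pathways) // 2)
        warnings.warn(f"cohort smaller than K_max; lowering K to {K}",
                      stacklevel=2)
    km = KMeans(n_clusters=K, random_state=cfg.seed, n_init=10)
    labels = km.fit_predict(E_last)
    curves = np.zeros((K, C_last.shape[1]))
    for c in range(K):
        members = C_last[labels == c]
        curves[c] = members.mean(axis=0) if len(members) else np.full(
            C_last.shape[1], 1.0 / C_last.shape[1])
    lr = LogisticRegression(max_iter=500, random_state=cfg.seed)
    lr.fit(E_last, labels)
    H = E_last.shape[1]
    W = np.zeros((H, K))
    b = np.zeros(K)
    for ci, cls in enumerate(lr.classes_):
        if lr.coef_.shape[0] == 1:  # binary case
            sign = 1.0 if ci == 1 else -1.0
            W[:, cls] = sign * lr.coef_[0]
            b[cls] = sign * lr.intercept_[0]
        else:
            W[:, cls] = lr.coef_[ci]
            b[cls] = lr.intercept_[ci]
    return ClusterModel(K=K, centroids=km.cluster_centers_, curves=curves,
                        W=W, b=b, grid=grid)


# ---------------------------------------------------------------------------
# training

def critic_update(model: ClusterModel, C: np.ndarray,
                  labels: np.ndarray) -> None:
    """Set each representative curve to its members' mean (KL-minimizing)."""
    for c in range(model.K):
        members = C[labels == c]
        if len(members):
            model.curves[c] = members.mean(axis=0)


def total_divergence(model: ClusterModel, C: np.ndarray,
                     labels: np.ndarray) -> float:
    return float(_kl(C, model.curves[labels]).sum())


def train_tpc(ddhl: DDHLModel, cohort: Cohort, cfg: TPCConfig,
              model: Optional[ClusterModel] = None) -> ClusterModel:
    """Alternating actor-critic optimization of the cluster model.

    Embeddings are sampled at one uniformly chosen as-of per patient per
    epoch so that clusters reflect temporal histories, not just final
    states.  Returns the model with a loss trace attached.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.horizon_grid)
    model = model or init_tpc(ddhl, cohort, cfg)
    cache = _prefix_cache(ddhl, cohort, grid)
    n = len(cache)
    trace = []
    for epoch in range(cfg.epochs):
        idx = np.array([rng.integers(len(c["as_ofs"])) for c in cache])
        E = np.asarray([c["E"][i] for c, i in zip(cache, idx)])
        C = np.asarray([c["C"][i] for c, i in zip(cache, idx)])
        probs = model.predict_proba(E)
        # sample assignments (the policy action)
        u = rng.uniform(size=n)[:, None]
        sampled = (probs.cumsum(axis=1) > u).argmax(axis=1)
        reward = -_kl(C, model.curves[sampled])
        baseline = reward.mean()
        adv = reward - baseline
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), sampled] = 1.0
        dlogits = adv[:, None] * (onehot - probs)
        # entropy penalty (maximize reward - w * entropy)
        logp = np.log(np.clip(probs, _EPS, None))
        ent = -(probs * logp).sum(axis=1)
        d_ent = -probs * (logp + ent[:, None])
        dlogits -= cfg.entropy_weight * d_ent
        model.W += cfg.learning_rate * E.T @ dlogits / n
        model.b += cfg.learning_rate * dlogits.mean(axis=0)
        # critic: representative curves from hard assignments
        hard = probs.argmax(axis=1)
        critic_update(model, C, hard)
        for c in range(model.K):
            members = E[hard == c]
            if len(members):
                model.centroids[c] = members.mean(axis=0)
        trace.append(total_divergence(model, C, hard) / n)
    model.loss_trace = trace  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# pruning and canonical numbering

def _reindex(model: ClusterModel, keep: list[int]) -> ClusterModel:
    return ClusterModel(K=len(keep), centroids=model.centroids[keep],
                        curves=model.curves[keep], W=model.W[:, keep],
                        b=model.b[keep], grid=model.grid)


def order_by_risk(model: ClusterModel) -> ClusterModel:
    """Renumber clusters by ascending 5-year representative risk."""
    order = np.argsort(model.five_year_risk(), kind="stable")
    return _reindex(model, list(order))


def prune_clusters(model: ClusterModel, ddhl: DDHLModel, cohort: Cohort,
                   cfg: TPCConfig) -> ClusterModel:
    """Drop empty/low-occupancy clusters and merge near-identical ones."""
    grid = np.asarray(cfg.horizon_grid)
    cache = _prefix_cache(ddhl, cohort, grid)
    E_last = np.asarray([c["E"][-1] for c in cache])
    C_last = np.asarray([c["C"][-1] for c in cache])

    def occupancy(m):
        lab = m.assign(E_last)
        return np.array([(lab == c).mean() for c in range(m.K)]), lab

    occ, labels = occupancy(model)
    keep = [c for c in range(model.K) if occ[c] >= cfg.min_occupancy]
    if len(keep) < 2:
        warnings.warn("pruning would leave fewer than 2 clusters; keeping "
                      "the 2 largest", stacklevel=2)
        keep = list(np.argsort(occ)[::-1][:2])
    model = _reindex(model, sorted(keep))

    # iterative merging of near-identical representative curves
    while model.K > 2:
        occ, labels = occupancy(model)
        critic_update(model, C_last, labels)
        div = np.full((model.K, model.K), np.inf)
        for a in range(model.K):
            for bb in range(a + 1, model.K):
                div[a, bb] = float(_kl(model.curves[a], model.curves[bb])
                                   + _kl(model.curves[bb], model.curves[a]))
        a, bb = np.unravel_index(np.argmin(div), div.shape)
        if div[a, bb] >= cfg.merge_divergence:
            break
        keep = [c for c in range(model.K) if c != bb]
        # fold the merged cluster's selector mass into its partner
        model.b[a] = np.logaddexp(model.b[a], model.b[bb])
        model = _reindex(model, keep)

    occ, labels = occupancy(model)
    critic_update(model, C_last, labels)
    return order_by_risk(model)


# ---------------------------------------------------------------------------
# downstream outputs

def assign_trajectory(model: ClusterModel, ddhl: DDHLModel,
                      pathway: ClinicalPathway, times) -> ClusterTrajectory:
    """Cluster label and probabilities at each requested time."""
    times = np.asarray(times, dtype=int)
    E = np.asarray([ddhl.embed(pathway, int(t)) for t in times])
    probs = model.predict_proba(E)
    return ClusterTrajectory(patient_id=pathway.patient_id, times=times,
                             labels=probs.argmax(axis=1),
                             probabilities=probs)


def cluster_survival(cohort: Cohort, labels) -> dict[int, KMEstimate]:
    """Per-cluster Kaplan-Meier curves, numbered by ascending 5-year risk."""
    labels = np.asarray(labels)
    T = np.array([p.outcome.time for p in cohort.pathways], dtype=float)
    delta = np.array([p.outcome.event for p in cohort.pathways], dtype=bool)
    curves = {}
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < 2:
            logger.warning("cluster %s has < 2 members; curve omitted", c)
            continue
        curves[int(c)] = kaplan_meier(T[sel], delta[sel])
    # stable numbering: 1 = lowest 5-year event probability
    risk5 = {c: 1.0 - km.survival_at(5 * 365) for c, km in curves.items()}
    ordered = sorted(curves, key=lambda c: risk5[c])
    return {i + 1: curves[c] for i, c in enumerate(ordered)}


def pca_project(embeddings: np.ndarray):
    """Top-2 principal-component projection with a deterministic sign.

    Returns (coords [n, 2], explained-variance fractions [2]).  The sign
    convention makes the largest-magnitude loading of each component
    positive.
    """
    from sklearn.decomposition import PCA
    E = np.asarray(embeddings, dtype=float)
    if E.shape[0] < 3:
        raise ValueError("need at least 3 embeddings")
    n_comp = min(2, E.shape[1], E.shape[0] - 1)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(E - E.mean(axis=0))
    evr = pca.explained_variance_ratio_.copy()
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    if n_comp < 2 or evr[-1] < 1e-12:
        logger.warning("rank-deficient embeddings: second component is zero")
        if n_comp < 2:
            coords = np.column_stack([coords, np.zeros(E.shape[0])])
            evr = np.append(evr, 0.0)
    return coords, evr[:2]


def partial_dependence_rank(model: ClusterModel, ddhl: DDHLModel,
                            cohort: Cohort, variables: list[str],
                            n_quantiles: int = 5) -> list[tuple[str, float]]:
    """Rank variables by how often perturbing them flips cluster assignment.

    For each patient's latest history the chosen variable is swept over a
    grid (observed quantiles for continuous variables, all levels for
    categorical ones) while everything else is held fixed; the flip
    fraction is the share of (patient, grid value) perturbations that
    change the assigned cluster.
    """
    from .preprocess import (CONTINUOUS, ONEHOT_LEVELS, build_sequence,
                             feature_names)
    names = feature_names()
    name_idx = {nm: i for i, nm in enumerate(names)}
    for v in variables:
        if v not in CONTINUOUS and v not in ONEHOT_LEVELS:
            raise ValueError(f"variable {v!r} not in the feature schema")

    # observed quantile grids for continuous variables
    obs_vals = {v: [] for v in variables if v in CONTINUOUS}
    seqs = []
    for p in cohort.pathways:
        last = p.observations[-1].t if p.observations else 0
        seq = build_sequence(p, last, ddhl.schema)
        seqs.append(seq)
        for v in obs_vals:
            obs_vals[v].append(seq.values[-1, name_idx[v]])
    qgrids = {v: np.quantile(np.asarray(vals),
                             np.linspace(0.1, 0.9, n_quantiles))
              for v, vals in obs_vals.items()}

    def assign_seq(seq):
        emb, _ = ddhl.forward(seq)
        return int(model.assign(emb[None, :])[0])

    results = []
    base_labels = [assign_seq(s) for s in seqs]
    for v in variables:
        flips = 0
        trials = 0
        for seq, base in zip(seqs, base_labels):
            row = seq.values[-1].copy()
            if v in CONTINUOUS:
                grid_vals = qgrids[v]
                for g in grid_vals:
                    seq.values[-1, name_idx[v]] = g
                    trials += 1
                    if assign_seq(seq) != base:
                        flips += 1
            else:
                levels = ONEHOT_LEVELS[v]
                cols = [name_idx[f"{v}={lv}"] for lv in levels]
                for ci in cols:
                    seq.values[-1, cols] = 0.0
                    seq.values[-1, ci] = 1.0
                    trials += 1
                    if assign_seq(seq) != base:
                        flips += 1
            seq.values[-1] = row
        results.append((v, flips / max(trials, 1)))
    results.sort(key=lambda x: -x[1])
    return results
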