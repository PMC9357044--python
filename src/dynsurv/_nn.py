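"""Minimal numpy neural-network internals for the recurrent survival model.

A single-layer GRU over padded variable-length sequences, a small tanh
MLP head, the conditional Weibull negative log-likelihood with analytic
gradients, and an Adam optimizer.  Everything operates on plain
float64 arrays in a flat parameter dict so that training is exactly
reproducible from a seed and gradients can be checked against finite
differences.
"""

from __future__ import annotations

import numpy as np

A_CLIP = (-3.0, 2.5)  # log-shape bounds: k in [e^-3, e^2.5]
B_CLIP = (-4.0, 4.0)  # log-scale offset bounds around log(lam0)
EXP_CLAMP = 50.0  # clamp on Weibull exponents for numerical safety


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def init_params(rng: np.random.Generator, input_dim: int, hidden_dim: int,
                head_hidden_dim: int, head_input_dim: int = 0) -> dict:
    """Glorot-uniform initialization of GRU + head parameters."""
    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    D, H, M = input_dim, hidden_dim, head_hidden_dim
    p = {}
    for gate in ("z", "r", "c"):
        p[f"W{gate}"] = glorot((D, H))
        p[f"U{gate}"] = glorot((H, H))
        p[f"b{gate}"] = np.zeros(H)
    p["W1"] = glorot((head_input_dim or H, M))
    p["b1"] = np.zeros(M)
    p["W2"] = glorot((M, 2)) * 0.1  # start near (k, lam) = (1, lam0)
    p["b2"] = np.zeros(2)
    return p


def init_aux_head(rng: np.random.Generator, hidden_dim: int,
                  n_targets: int) -> dict:
    lim = np.sqrt(6.0 / (hidden_dim + n_targets))
    return {"Waux": rng.uniform(-lim, lim, size=(hidden_dim, n_targets)),
            "baux": np.zeros(n_targets)}


def stepahead_loss(p: dict, h_seq: np.ndarray, X: np.ndarray,
                   lengths: np.ndarray, target_idx) -> tuple:
    """Next-observation prediction loss (masked MSE) and its gradients.

    Predicts the next step's selected input channels from each hidden
    state; returns (loss, grads, dh_seq) where dh_seq injects the
    per-step hidden-state gradients.
    """
    B, T, _ = X.shape
    if T < 2:
        return 0.0, {"Waux": np.zeros_like(p["Waux"]),
                     "baux": np.zeros_like(p["baux"])}, np.zeros_like(h_seq[..., :p["Waux"].shape[0]])
    target = X[:, 1:, target_idx]
    pred = h_seq[:, :-1, :] @ p["Waux"] + p["baux"]
    steps = np.arange(T - 1)[None, :]
    valid = (steps + 1 < lengths[:, None]).astype(float)[:, :, None]
    denom = max(valid.sum() * len(target_idx), 1.0)
    resid = (pred - target) * valid
    loss = float((resid ** 2).sum() / denom)
    dpred = 2.0 * resid / denom
    g = {"Waux": np.einsum("bth,btk->hk", h_seq[:, :-1, :], dpred),
         "baux": dpred.sum(axis=(0, 1))}
    dh_seq = np.zeros((B, T, p["Waux"].shape[0]))
    dh_seq[:, :-1, :] = dpred @ p["Waux"].T
    return loss, g, dh_seq


# ---------------------------------------------------------------------------
# GRU

def gru_forward(p: dict, X: np.ndarray, lengths: np.ndarray,
                pool: str = "last"):
    """Run the GRU over a padded batch.

    X: [B, T, D]; lengths: [B] with 1 <= lengths <= T.  Steps at or past a
    sequence's length leave its hidden state unchanged, so padding has no
    effect on the output.  ``pool`` selects the sequence summary: the
    final hidden state ("last") or the mean over the active steps
    ("mean"), which preserves slow trend information in long histories.
    """
    B, T, _ = X.shape
    H = p["bz"].shape[0]
    h = np.zeros((B, H))
    cache = []
    h_sum = np.zeros((B, H))
    h_seq = np.zeros((B, T, H))
    for t in range(T):
        x = X[:, t, :]
        active = (t < lengths).astype(float)[:, None]
        z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        rh = r * h
        c = np.tanh(x @ p["Wc"] + rh @ p["Uc"] + p["bc"])
        h_new = (1.0 - z) * h + z * c
        cache.append((x, h, z, r, c, active))
        h = active * h_new + (1.0 - active) * h
        h_seq[:, t, :] = h
        h_sum = h_sum + active * h
    if pool == "mean":
        return h_sum / lengths[:, None], (cache, h_seq)
    if pool == "both":
        # responsive final state + slow-trend mean state
        return np.concatenate([h, h_sum / lengths[:, None]], axis=1), (cache, h_seq)
    return h, (cache, h_seq)


def gru_backward(p: dict, cache, dh: np.ndarray, lengths=None,
                 pool: str = "last", dh_seq=None) -> dict:
    """Backpropagate the summary gradient through time; returns param grads.

    ``dh_seq`` [B, T, H] optionally injects per-step gradients on h_t
    (auxiliary losses such as next-observation prediction).
    """
    cache, _ = cache if isinstance(cache, tuple) else (cache, None)
    g = {k: np.zeros_like(v) for k, v in p.items()
         if k[0] in ("W", "U", "b") and k[1] in ("z", "r", "c")}
    if pool == "mean":
        d_pool = dh / lengths[:, None]
        dh = np.zeros_like(dh)
    elif pool == "both":
        H = p["bz"].shape[0]
        d_pool = dh[:, H:] / lengths[:, None]
        dh = dh[:, :H].copy()
    else:
        dh = dh.copy()
    for t, (x, h_prev, z, r, c, active) in reversed(list(enumerate(cache))):
        if pool in ("mean", "both"):
            dh = dh + active * d_pool
        if dh_seq is not None:
            dh = dh + dh_seq[:, t, :]
        dh_step = active * dh
        dh_pass = (1.0 - active) * dh
        dz = dh_step * (c - h_prev)
        dc = dh_step * z
        dh_prev = dh_step * (1.0 - z)
        dcs = dc * (1.0 - c * c)
        dzs = dz * z * (1.0 - z)
        drh = dcs @ p["Uc"].T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        drs = dr * r * (1.0 - r)
        g["Wc"] += x.T @ dcs
        g["Uc"] += (r * h_prev).T @ dcs
        g["bc"] += dcs.sum(axis=0)
        g["Wz"] += x.T @ dzs
        g["Uz"] += h_prev.T @ dzs
        g["bz"] += dzs.sum(axis=0)
        g["Wr"] += x.T @ drs
        g["Ur"] += h_prev.T @ drs
        g["br"] += drs.sum(axis=0)
        dh_prev = dh_prev + dzs @ p["Uz"].T + drs @ p["Ur"].T
        dh = dh_prev + dh_pass
    return g


# ---------------------------------------------------------------------------
# head

def head_forward(p: dict, h: np.ndarray):
    """MLP head mapping hidden state to (a, b) = (log k, log-scale offset)."""
    u = np.tanh(h @ p["W1"] + p["b1"])
    out = u @ p["W2"] + p["b2"]
    return out[:, 0], out[:, 1], (h, u)


def head_backward(p: dict, cache, da: np.ndarray, db: np.ndarray):
    h, u = cache
    dout = np.stack([da, db], axis=1)
    g = {"W2": u.T @ dout, "b2": dout.sum(axis=0)}
    du = dout @ p["W2"].T
    dus = du * (1.0 - u * u)
    g["W1"] = h.T @ dus
    g["b1"] = dus.sum(axis=0)
    dh = dus @ p["W1"].T
    return g, dh


def params_to_weibull(a: np.ndarray, b: np.ndarray, log_lam0: float):
    """Map raw head outputs to positive (k, lam) with soft clipping."""
    a_c = np.clip(a, *A_CLIP)
    b_c = np.clip(b, *B_CLIP)
    k = np.exp(a_c)
    lam = np.exp(log_lam0 + b_c)
    return k, lam


# ---------------------------------------------------------------------------
# loss

def weibull_nll(a, b, T, delta, t_obs, log_lam0, weights=None):
    """Weighted mean conditional Weibull NLL and its gradients w.r.t. (a, b).

    a = log k (clipped), b = log lam - log_lam0 (clipped); the outcome
    (T, delta) is conditioned on survival to t_obs (left truncation).
    ``weights`` (default uniform) lets a patient's multiple as-of prefixes
    share one unit of weight.
    """
    if weights is None:
        weights = np.ones_like(np.asarray(a, dtype=float))
    wsum = float(weights.sum())
    ga = ((a > A_CLIP[0]) & (a < A_CLIP[1])).astype(float)
    gb = ((b > B_CLIP[0]) & (b < B_CLIP[1])).astype(float)
    a_c = np.clip(a, *A_CLIP)
    b_c = np.clip(b, *B_CLIP)
    k = np.exp(a_c)
    loglam = log_lam0 + b_c
    sT = np.log(T) - loglam
    w = np.exp(np.minimum(k * sT, EXP_CLAMP))
    pos = t_obs > 0
    so = np.where(pos, np.log(np.maximum(t_obs, 1.0)) - loglam, 0.0)
    v = np.where(pos, np.exp(np.minimum(k * so, EXP_CLAMP)), 0.0)
    ll = delta * (a_c + k * sT - np.log(T)) - w + v
    dll_da = ga * (delta * (1.0 + k * sT) - k * w * sT + k * v * so)
    dll_db = gb * (-delta * k + k * w - k * v)
    nll = -float((weights * ll).sum() / wsum)
    return nll, -weights * dll_da / wsum, -weights * dll_db / wsum


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 grad_clip: float = 5.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.grad_clip = grad_clip
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, self.grad_clip / (norm + 1e-12))
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for key, g in grads.items():
            g = g * scale
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
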