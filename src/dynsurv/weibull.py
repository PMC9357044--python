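"""Closed-form Weibull survival quantities.

The time-to-event process is modelled as Weibull with shape k and scale
lambda (days): S(t) = exp(-(t/lam)^k).  All model risk output is the
conditional probability of an event at or before a horizon, given
event-free survival to the time of the last observation:

    F(delta | t0) = 1 - S(t0 + delta) / S(t0)
"""

from __future__ import annotations

import numpy as np


def _check(k, lam):
    if np.any(np.asarray(k) <= 0) or np.any(np.asarray(lam) <= 0):
        raise ValueError("shape and scale must be strictly positive")


def weibull_survival(k, lam, t):
    """S(t) = exp(-(t/lam)^k)."""
    _check(k, lam)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-np.power(t / lam, k))
    return float(out) if out.ndim == 0 else out


def weibull_loglik(k, lam, T, delta, t_obs=0.0):
    """Log-likelihood of outcome (T, delta) conditional on survival to t_obs.

    delta = 1: event at T, density term; delta = 0: censored at T,
    survival term.  Conditioning adds +(t_obs/lam)^k (left truncation).
    """
    _check(k, lam)
    T = np.asarray(T, dtype=float)
    t_obs = np.asarray(t_obs, dtype=float)
    if np.any(T <= t_obs):
        raise ValueError("outcome precedes observation: T must exceed t_obs")
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    delta = np.asarray(delta, dtype=float)
    w = np.power(T / lam, k)
    v = np.where(t_obs > 0, np.power(np.maximum(t_obs, 1e-300) / lam, k), 0.0)
    event_term = np.log(k) - np.log(lam) + (k - 1.0) * np.log(T / lam)
    ll = delta * event_term - w + v
    return float(ll) if ll.ndim == 0 else ll


def conditional_risk(k, lam, t0, horizons):
    """F(delta | t0) = 1 - S(t0 + delta)/S(t0) for each horizon delta."""
    _check(k, lam)
    horizons = np.asarray(horizons, dtype=float)
    if np.any(horizons < 0):
        raise ValueError("horizons must be >= 0")
    t0 = float(t0)
    h0 = np.power(t0 / lam, k) if t0 > 0 else 0.0
    h1 = np.power((t0 + horizons) / lam, k)
    risk = 1.0 - np.exp(h0 - h1)
    return np.clip(risk, 0.0, 1.0 - 1e-15)


def weibull_median(k, lam):
    """Median event time: lam * (ln 2)^(1/k)."""
    _check(k, lam)
    return lam * np.log(2.0) ** (1.0 / k)
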