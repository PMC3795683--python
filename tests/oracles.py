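"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths (and the
libraries standing behind them): the Cox oracle maximizes the Efron partial
likelihood by dense grid search, the log-rank oracle accumulates the
hypergeometric O-E/V contributions per event time by hand, the Kaplan-Meier
oracle multiplies the product-limit factors directly, and the BH oracle runs
the step-up recursion explicitly.
"""
from __future__ import annotations

import numpy as np


def efron_log_partial_likelihood(beta, time, event, x):
    """Efron-tie log partial likelihood for a single covariate, vectorized
    over a grid of beta values."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = np.zeros_like(beta)
    ex = np.exp(np.outer(beta, x))  # grid x subjects
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        ll += beta * x[dead].sum()
        sum_risk = ex[:, at_risk].sum(axis=1)
        sum_dead = ex[:, dead].sum(axis=1)
        for tie in range(d):
            ll -= np.log(sum_risk - (tie / d) * sum_dead)
    return ll


def cox_beta_grid(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    """Grid-search maximizer of the Efron partial likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = efron_log_partial_likelihood(grid, time, event, x)
    return float(grid[np.argmax(ll)])


def logrank_oracle(time, event, in_group1):
    """Two-group log-rank chi-square from per-event-time hypergeometric
    contributions, accumulated by hand."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2


def km_oracle(time, event):
    """Product-limit estimate at each distinct event time, multiplied out
    directly. Returns (event_times, survival)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    times, surv = [], []
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        times.append(t)
        surv.append(s)
    return np.array(times), np.array(surv)


def bh_oracle(p):
    """Step-up BH: q_(i) = min_{j >= i} p_(j) * n / j, via the explicit
    backward recursion."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * n / (rank_from_top + 1))
        q[idx] = running
    return q
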