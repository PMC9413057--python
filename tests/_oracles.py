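"""Independent brute-force oracles used to validate the analysis code.

Everything here is deliberately naive -- full enumeration or direct
products at tiny n -- and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def km_survival_brute(times, events, t):
    """Product-limit S(t) computed directly from its definition.

    At each distinct event time u <= t, multiply by (n_u - d_u) / n_u
    where n_u counts subjects still at risk at u (events at equal times
    are processed before censorings, so a subject censored at u is still
    at risk for events at u).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        n_at_risk = int(np.sum(times >= u))
        d = int(np.sum((times == u) & events))
        s *= (n_at_risk - d) / n_at_risk
    return s


def km_median_brute(times, events):
    """Smallest event time with brute-force S(t) <= 0.5, else inf."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    for u in sorted(set(times[events])):
        if km_survival_brute(times, events, u) <= 0.5 + 1e-12:
            return float(u)
    return float("inf")


def wilcoxon_p_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    lower = np.mean(stats <= w_obs + 1e-9)
    upper = np.mean(stats >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney_p_enumeration(a, b):
    """Exact two-sided U-test p by enumerating all group-A rank subsets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(n1 + n2), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    lower = np.mean(us <= u_obs + 1e-9)
    upper = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def shannon_entropy_direct(counts):
    """Entropy from first principles, term by term."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        p = c / total
        h -= p * np.log(p)
    return h
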