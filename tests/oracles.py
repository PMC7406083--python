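"""Independent brute-force oracles for the nonparametric tests.

These enumerate the exact null distributions directly from definitions
(sign assignments for the signed-rank test, group assignments for the
rank-sum test) and are deliberately independent of scipy's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_oracle(a, b) -> tuple[float, float]:
    """U statistic for sample a and exact two-sided p by enumerating all
    assignments of pooled ranks to the first group."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n = len(a), len(a) + len(b)
    ranks = _midranks(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array([ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
                   for comb in itertools.combinations(range(n), n1)])
    p = min(1.0, 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return float(u_obs), float(p)


def wilcoxon_oracle(a, b) -> tuple[float, float]:
    """min(T+, T-) and exact two-sided p by enumerating all 2^n sign
    assignments of the absolute-difference ranks (zero differences dropped)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    r = _midranks(np.abs(d))
    t_plus = r[d > 0].sum()
    t_minus = r[d < 0].sum()
    dist = np.array([sum(ri for ri, s in zip(r, signs) if s)
                     for signs in itertools.product([0, 1], repeat=len(d))])
    p = min(1.0, 2.0 * min((dist <= t_plus).mean(), (dist >= t_plus).mean()))
    return float(min(t_plus, t_minus)), float(p)


def friedman_oracle(matrix) -> float:
    """Friedman chi-square from the rank-sum formula on within-row midranks
    (tie-free input assumed, where the classic formula is exact)."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    ranks = np.vstack([_midranks(row) for row in m])
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3.0 * n * (k + 1))


def bh_oracle(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, straight from the definition."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
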