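"""Nonparametric statistical battery and training-curve summaries.

Friedman, Wilcoxon signed-rank, and Mann-Whitney U tests (midranks for ties;
exact null distributions for small samples, normal approximation with
continuity correction otherwise), Benjamini-Hochberg step-up FDR adjustment,
seeded percentile-bootstrap confidence intervals of the mean, and the two
training-curve statistics: the convergence epoch (first epoch reaching 95% of
the curve's maximum) and the mean accuracy of the first n epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "friedman", "wilcoxon_signed_rank", "mann_whitney_u",
           "bh_fdr", "bootstrap_ci", "convergence_epoch", "early_mean_accuracy",
           "EXACT_N_MAX", "CONVERGENCE_FRACTION"]

EXACT_N_MAX = 25          # exact p-values up to this sample size
CONVERGENCE_FRACTION = 0.95


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: str
    adjusted_p: float | None = None
    degenerate: bool = False

    def row(self, groups: str = "") -> dict:
        return {"test": self.test_name, "groups": groups,
                "statistic": self.statistic, "p": self.p_value,
                "p_adj": self.adjusted_p, "n": self.n}


def _as_2d(block_matrix) -> np.ndarray:
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a subjects x conditions matrix, got shape {x.shape}")
    return x


def friedman(block_matrix) -> StatResult:
    """Friedman chi-square test on within-subject ranks.

    Rows are subjects (blocks), columns are repeated-measures conditions.
    A matrix whose rows are all constant is degenerate (all ranks tied);
    it is flagged and reported with statistic 0 and p = 1.
    """
    x = _as_2d(block_matrix)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {x.shape}")
    if np.all(x == x[:, :1]):
        return StatResult("friedman", 0.0, 1.0, f"n={n},k={k}", degenerate=True)
    stat, p = sps.friedmanchisquare(*(x[:, j] for j in range(k)))
    return StatResult("friedman", float(stat), float(p), f"n={n},k={k}")


def wilcoxon_signed_rank(paired_a, paired_b, exact_max: int = EXACT_N_MAX) -> StatResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped (Wilcoxon's convention); ties get midranks.
    The exact distribution is used for small samples without zeros or ties,
    otherwise the normal approximation with continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return StatResult("wilcoxon", 0.0, 1.0, f"n={len(a)}", degenerate=True)
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= exact_max and not has_ties) else "approx"
    with np.errstate(all="ignore"):
        stat, p = sps.wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"),
                               alternative="two-sided", method=method)
    return StatResult("wilcoxon", float(stat), float(min(p, 1.0)), f"n={len(nz)}")


def mann_whitney_u(a, b, exact_max: int = EXACT_N_MAX) -> StatResult:
    """Two-sample Mann-Whitney U test (two-sided); U is reported for sample a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= exact_max and not has_ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=True)
    return StatResult("mannwhitneyu", float(stat), float(min(p, 1.0)),
                      f"n1={len(a)},n2={len(b)}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_ci(values, n_boot: int = 10_000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap interval of the mean.

    Resamples the units passed in (whatever they are: subjects, subsets,
    seeds) with replacement.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 211))))
    idx = rng.integers(0, len(x), size=(int(n_boot), len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# training-curve summaries
# --------------------------------------------------------------------------

def _curve_values(curve) -> np.ndarray:
    vals = np.asarray(getattr(curve, "val_accuracy", curve), dtype=float)
    if vals.ndim != 1 or len(vals) == 0:
        raise ValueError("curve must be a non-empty 1-D accuracy sequence")
    return vals


def convergence_epoch(curve) -> int:
    """First epoch (1-based) reaching 95% of the curve's maximum accuracy.

    Undefined (flagged by ValueError) for an all-zero curve, whose maximum
    carries no information.
    """
    vals = _curve_values(curve)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("convergence undefined: curve never rises above zero")
    return int(np.argmax(vals >= CONVERGENCE_FRACTION * peak)) + 1


def early_mean_accuracy(curve, first_n: int = 10) -> float:
    """Arithmetic mean of the first ``first_n`` validation accuracies."""
    vals = _curve_values(curve)
    if first_n < 1:
        raise ValueError("first_n must be >= 1")
    return float(vals[: int(first_n)].mean())


def results_table(results: Sequence[tuple[str, StatResult]], adjust: bool = True) -> pd.DataFrame:
    """Uniform results CSV: test, groups, statistic, p, p_adj, n.

    When ``adjust`` is set, BH adjustment is applied across all rows.
    """
    rows = [res.row(groups) for groups, res in results]
    df = pd.DataFrame(rows, columns=["test", "groups", "statistic", "p", "p_adj", "n"])
    if adjust and len(df):
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df
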