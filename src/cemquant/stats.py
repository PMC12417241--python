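"""Nonparametric association and comparison tests, with Holm correction.

Thin, validated wrappers over the standard implementations: Mann-Whitney U
(exact enumeration for small tie-free samples, tie-corrected normal
approximation otherwise), Kruskal-Wallis H, Pearson chi-square without
continuity correction, Spearman's rho, Kendall's tau-b, and step-down Holm
adjustment.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "TestResult",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square",
    "spearman_rho",
    "kendall_tau_b",
    "holm_correct",
]


class StatsError(ValueError):
    """Raised for empty, degenerate or malformed test inputs."""


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    effect: Optional[float] = None
    df: Optional[float] = None


def _clean(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise StatsError(f"{name}: empty sample")
    if not np.all(np.isfinite(arr)):
        raise StatsError(f"{name}: non-finite values")
    return arr


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U; exact when n_x * n_y <= 400 and tie-free."""
    x = _clean(x, "x")
    y = _clean(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      n=x.size + y.size)


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square approximation, df = k-1."""
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    cleaned = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(cleaned)
    if np.unique(pooled).size == 1:
        raise StatsError("all observations identical; H degenerate")
    res = ss.kruskal(*cleaned)
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue),
                      n=pooled.size, df=float(len(cleaned) - 1))


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError("table must be 2-D with >= 2 rows and columns")
    if (table < 0).any():
        raise StatsError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("zero row/column margin")
    res = ss.chi2_contingency(table, correction=False)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue),
                      n=int(table.sum()), effect=float(res.statistic),
                      df=float(res.dof))


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = _clean(x, "x")
    y = _clean(y, "y")
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("need >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise StatsError("zero variance in a variable; correlation undefined")
    return x, y


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = _paired(x, y)
    res = ss.spearmanr(x, y)
    return TestResult("spearman_rho", float(res.statistic), float(res.pvalue),
                      n=x.size, effect=float(res.statistic))


def kendall_tau_b(x, y) -> TestResult:
    """Kendall's tau-b (tie-corrected)."""
    x, y = _paired(x, y)
    res = ss.kendalltau(x, y, variant="b")
    return TestResult("kendall_tau_b", float(res.statistic), float(res.pvalue),
                      n=x.size, effect=float(res.statistic))


def holm_correct(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm-adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="holm")[1]
    return [float(v) for v in adjusted]
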