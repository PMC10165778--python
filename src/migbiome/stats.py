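"""Shared statistical primitives.

All group contrasts in the pipeline reduce to the Mann-Whitney U test with
Benjamini-Hochberg correction across each family of comparisons, and all
monotone-association estimates to Spearman's rank correlation. Keeping these
three behind one surface guarantees every module applies identical
conventions (two-sided tests, average ranks for ties, per-family FDR).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "mann_whitney_u", "bh_adjust", "spearman_rho"]


@dataclass
class TestResult:
    """Outcome of a two-sample test.

    statistic is the Mann-Whitney U of the first sample; adjusted_p is filled
    in later by the caller once the whole family of tests is known.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int
    adjusted_p: float | None = None


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact enumeration is used for small samples (n1 + n2 <= 20) without ties;
    otherwise the normal approximation with tie correction and continuity
    correction. Two-sided by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), x.size, y.size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p) with p from the t approximation. A constant input vector
    makes rho undefined: (nan, nan) is returned with a warning rather than an
    exception so tabulated reports can carry missing cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_rho needs equal-length vectors, n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
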