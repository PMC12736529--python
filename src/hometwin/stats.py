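"""Paired-comparison statistics: paired t, BH-FDR, Cohen's d, KS normality.

Conventions: two-sided paired t on differences d = x - y with a Student-t 95%
confidence interval; Cohen's d for paired designs as mean(d)/SD(d) (a
pooled-SD variant is available behind a flag); Benjamini-Hochberg step-up
adjustment within each comparison table; normality via the one-sample
Kolmogorov-Smirnov statistic against a normal with estimated mean/SD, with
Lilliefors-corrected p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedComparison:
    n: int
    mean_difference: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    cohens_d: float
    degenerate: bool = False


def paired_t(x: np.ndarray, y: np.ndarray | None = None) -> PairedComparison:
    """Classical two-sided paired t-test on d = x - y (or on x if y omitted).

    Zero-variance differences are flagged degenerate: the mean difference and
    CI collapse to the constant, t and p are undefined (NaN).
    """
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    if y is not None and x.shape != np.shape(y):
        raise ValueError("paired samples must have equal length")
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(n, md, md, md, np.nan, np.nan, np.nan, degenerate=True)
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return PairedComparison(
        n=n,
        mean_difference=md,
        ci_low=md - tcrit * se,
        ci_high=md + tcrit * se,
        t=float(t),
        p=p,
        cohens_d=cohens_d_paired(d),
    )


def cohens_d_paired(d: np.ndarray, pooled_with: np.ndarray | None = None) -> float:
    """Effect size for paired data: mean(d) / SD(d).

    With ``pooled_with`` given, ``d`` is treated as the first condition and a
    pooled-SD (average-variance) denominator across the two conditions is
    used instead — the alternative convention some reports adopt.
    """
    d = np.asarray(d, float)
    if d.size < 2:
        raise ValueError("need at least 2 values")
    if pooled_with is not None:
        y = np.asarray(pooled_with, float)
        denom = np.sqrt((d.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2.0)
        if denom == 0:
            raise ValueError("zero pooled SD")
        return float((d.mean() - y.mean()) / denom)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD of differences")
    return float(d.mean() / sd)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_normality(x: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic against N(mean(x), sd(x)) with Lilliefors p.

    Returns (statistic, p). The statistic is sup |ECDF - Phi|.
    """
    x = np.asarray(x, float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("constant input")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)
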