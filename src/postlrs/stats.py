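"""Inferential layer: normality, bias screening, paired method comparison,
categorical comparison, and the repeated-measures power computation.

Implements the testing battery applied to the (eyes x methods) prediction
error matrix: exact one-sample Kolmogorov-Smirnov normality screen, one-sample
t against zero mean error, Friedman's test with Bonferroni-adjusted pairwise
rank comparisons on the absolute errors, Cochran's Q with pairwise McNemar on
the within-threshold indicators, and the noncentral-F sample size computation
for a one-group within-factor repeated-measures design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "one_sample_t",
    "friedman_with_bonferroni",
    "cochran_q",
    "mcnemar_uncorrected",
    "ks_normality",
    "cohen_f_from_eta2",
    "rm_power",
    "rm_sample_size",
    "PowerAnalysisSpec",
    "TestResult",
]

ALPHA = 0.05  # significance threshold used throughout the reports


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | None
    p: float
    pairwise: Mapping[tuple[str, str], float] | None = None


def one_sample_t(pes: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean PE against zero."""
    x = np.asarray(pes, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t requires n >= 2")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance sample")
    res = sps.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue)


def _column_mean_ranks(matrix: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
    return ranks.mean(axis=0)


def friedman_with_bonferroni(
    matrix, columns: Sequence[str] | None = None
) -> TestResult:
    """Friedman's rank test across methods with Bonferroni pairwise post hoc.

    ``matrix`` is eyes x methods (complete; listwise).  Ties within an eye
    receive average ranks (with the usual tie correction in the statistic).
    Pairwise comparisons are the standard rank-sum z-comparisons,
    p-values multiplied by k*(k-1)/2 and capped at 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 eyes and >= 2 methods")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells: Friedman requires listwise completeness")
    n, k = m.shape
    if columns is None:
        columns = [f"m{j}" for j in range(k)]

    # tie-corrected Friedman statistic (valid for any k >= 2):
    # chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2/4)
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    denom = (ranks ** 2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denom == 0:  # every row fully tied: no evidence of any difference
        chi2, p = 0.0, 1.0
    else:
        chi2 = float((k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum() / denom)
        p = float(sps.chi2.sf(chi2, k - 1))

    mean_ranks = _column_mean_ranks(m)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        praw = 2.0 * sps.norm.sf(z)
        pairwise[(columns[i], columns[j])] = min(1.0, praw * n_pairs)
    return TestResult("friedman", chi2, float(k - 1), p, pairwise)


def mcnemar_uncorrected(x: Sequence[int], y: Sequence[int]) -> tuple[float, float]:
    """McNemar chi-square without continuity correction (= 2-column Cochran Q)."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    if b + c == 0:
        return 0.0, 1.0
    stat = (b - c) ** 2 / (b + c)
    return float(stat), float(sps.chi2.sf(stat, 1))


def cochran_q(matrix, columns: Sequence[str] | None = None) -> TestResult:
    """Cochran's Q over paired binary outcomes with pairwise McNemar post hoc.

    Q = k(k-1) * sum_j (C_j - Cbar)^2 / (k*sum_i R_i - sum_i R_i^2), referred
    to chi-square with k-1 df.  Rows that are constant across all eyes make
    the denominator zero, in which case Q is undefined.
    """
    m = np.asarray(matrix, dtype=int)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 methods")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("Cochran Q requires binary entries")
    n, k = m.shape
    if columns is None:
        columns = [f"m{j}" for j in range(k)]
    col_sums = m.sum(axis=0)
    row_sums = m.sum(axis=1)
    denom = k * row_sums.sum() - (row_sums ** 2).sum()
    if denom == 0:
        raise ValueError("Q undefined: every eye is constant across methods")
    q = k * (k - 1) * ((col_sums - col_sums.mean()) ** 2).sum() / denom
    p = float(sps.chi2.sf(q, k - 1))
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        _, praw = mcnemar_uncorrected(m[:, i], m[:, j])
        pairwise[(columns[i], columns[j])] = min(1.0, praw * n_pairs)
    return TestResult("cochran_q", float(q), float(k - 1), p, pairwise)


def ks_normality(sample: Sequence[float], lilliefors: bool = False) -> float:
    """One-sample KS normality p-value with estimated mean/sd.

    Default is the exact-distribution p-value of the KS statistic against a
    normal with the sample mean and sd (the SPSS-style "exact" reading);
    ``lilliefors=True`` applies the Lilliefors correction for the estimated
    parameters instead.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("normality screen requires n >= 4")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
        return float(p)
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)), method="exact")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Power / sample size for the one-group repeated-measures within-factor design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerAnalysisSpec:
    partial_eta2: float
    cohen_f: float
    alpha: float
    target_power: float
    m: int              # number of repeated measurements (methods compared)
    epsilon: float      # Greenhouse-Geisser nonsphericity correction
    n: int | None = None

    def __post_init__(self):
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 2:
            raise ValueError("need m >= 2 repeated measurements")


def cohen_f_from_eta2(partial_eta2: float) -> float:
    """Cohen's f from partial eta-squared: f = sqrt(eta2 / (1 - eta2))."""
    if not (0 <= partial_eta2 < 1):
        raise ValueError("partial eta-squared must be in [0, 1)")
    return math.sqrt(partial_eta2 / (1.0 - partial_eta2))


def rm_power(n: int, f: float, alpha: float, m: int, epsilon: float,
             corr: float = 0.5) -> float:
    """Achieved power of the within-factor repeated-measures F test at size ``n``.

    Convention (SPSS-compatible effect size): the entered f derives from the
    partial eta-squared of the within-subject effect, which already embodies
    the correlation among the repeated measures, so ``corr`` (accepted for
    interface parity, default 0.5) does not enter the noncentrality.
    lambda = f^2 * n * m * epsilon, numerator df = m - 1 (nominal), error
    df = (n - 1)(m - 1) * epsilon (Greenhouse-Geisser corrected).
    """
    if not (0 <= corr < 1):
        raise ValueError("correlation among measures must be in [0, 1)")
    if n < 2:
        return 0.0
    df1 = m - 1
    df2 = (n - 1) * (m - 1) * epsilon
    lam = f * f * n * m * epsilon
    fcrit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def rm_sample_size(f: float, alpha: float, target_power: float, m: int,
                   epsilon: float, corr: float = 0.5, n_cap: int = 10 ** 5) -> int:
    """Smallest N whose achieved power reaches ``target_power``.

    Iterates N upward under the :func:`rm_power` convention; raises if the
    target is unreachable below ``n_cap``.
    """
    PowerAnalysisSpec(float("nan"), f, alpha, target_power, m, epsilon)
    for n in range(2, n_cap + 1):
        if rm_power(n, f, alpha, m, epsilon, corr) >= target_power:
            return n
    raise ValueError(f"target power {target_power} unreachable below N = {n_cap}")
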