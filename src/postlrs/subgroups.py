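"""Range stratification of prediction errors over K, AL and AL/K.

Cutoffs for the K and AL strata are data-driven: the quartiles of the
optimizable subset, rounded to the nearest 1.00 D (K) or 0.50 mm (AL).  The
AL/K ratio uses fixed cutoffs at 2/3 and 3/4.  Intervals are left-open,
right-closed, (a, b], with the outermost ranges unbounded.  Within each range
the full accuracy battery plus the paired comparison tests are computed, and
LOESS trend curves of PE against the stratifying variable summarise the
continuous relationship.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import GroupSummary, summarize
from .stats import TestResult, cochran_q, friedman_with_bonferroni

__all__ = [
    "RangeScheme",
    "derive_cutoffs",
    "alk_scheme",
    "partition",
    "RangeComparison",
    "per_range_comparison",
    "TrendCurve",
    "loess_trend",
]


@dataclass(frozen=True)
class RangeScheme:
    """Ordered breakpoints splitting a variable into (a, b] ranges."""

    variable: str                 # {"K", "AL", "ALK"}
    cutoffs: tuple[float, ...]    # strictly increasing

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")

    @property
    def n_ranges(self) -> int:
        return len(self.cutoffs) + 1

    def assign(self, value: float) -> int:
        """Range index of ``value``; boundary values fall in the lower range."""
        for i, c in enumerate(self.cutoffs):
            if value <= c:
                return i
        return len(self.cutoffs)

    def label(self, index: int) -> str:
        c = self.cutoffs
        if index == 0:
            return f"{self.variable} <= {c[0]:g}"
        if index == len(c):
            return f"{self.variable} > {c[-1]:g}"
        return f"{c[index - 1]:g} < {self.variable} <= {c[index]:g}"


def _round_to_step(x: float, step: float) -> float:
    """Nearest multiple of ``step``, halves away from zero."""
    return math.floor(abs(x) / step + 0.5) * step * (1 if x >= 0 else -1)


def derive_cutoffs(values: Sequence[float], step: float, n_ranges: int = 4,
                   variable: str = "X") -> RangeScheme:
    """Quartile-based cutoffs rounded to the nearest ``step``.

    Q1, Q2, Q3 are computed by linear interpolation and each rounded to the
    nearest multiple of ``step`` (0.50 mm for AL, 1.00 D for K).  Coincident
    rounded cutoffs are an error (the sample is too narrow for ``n_ranges``
    strata at this step).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < n_ranges:
        raise ValueError(f"need at least {n_ranges} values")
    probs = np.linspace(0, 1, n_ranges + 1)[1:-1]
    qs = np.quantile(vals, probs)
    cutoffs = tuple(_round_to_step(q, step) for q in qs)
    if len(set(cutoffs)) < len(cutoffs):
        raise ValueError(
            f"coincident rounded cutoffs {cutoffs}: use a larger sample or a "
            f"different step")
    return RangeScheme(variable, cutoffs)


def alk_scheme() -> RangeScheme:
    """Fixed AL/K stratification at 2/3 (0.67) and 3/4 (0.75)."""
    return RangeScheme("ALK", (0.67, 0.75))


def partition(records, scheme: RangeScheme,
              value_of=None) -> dict[int, list[str]]:
    """Disjoint, exhaustive assignment of eyes to ranges.

    ``value_of`` maps a record to the stratifying value; defaults per scheme
    variable (K -> .k, AL -> .al, ALK -> .al/.k).
    """
    if value_of is None:
        value_of = {
            "K": lambda r: r.k,
            "AL": lambda r: r.al,
            "ALK": lambda r: r.al / r.k,
        }[scheme.variable]
    out: dict[int, list[str]] = {i: [] for i in range(scheme.n_ranges)}
    for r in records:
        out[scheme.assign(value_of(r))].append(r.eye_id)
    return out


@dataclass
class RangeComparison:
    range_index: int
    label: str
    n: int
    summaries: Mapping[str, GroupSummary]
    friedman: TestResult | None = None
    cochran: Mapping[float, TestResult] = field(default_factory=dict)
    best_method: str | None = None          # lowest MedAE in the range


def per_range_comparison(
    pe_wide: pd.DataFrame,
    strat_values: pd.Series,
    scheme: RangeScheme,
    thresholds: Sequence[float] = (0.5, 1.0),
    min_n_for_tests: int = 5,
) -> list[RangeComparison]:
    """Accuracy battery + paired tests for every range of ``scheme``.

    ``pe_wide`` is the complete eyes x methods PE matrix (index eye_id);
    ``strat_values`` the stratifying variable per eye.  Ranges with fewer
    than ``min_n_for_tests`` eyes are summarized but their tests skipped.
    """
    if pe_wide.isna().any().any():
        raise ValueError("PE matrix must be complete")
    strat = strat_values.reindex(pe_wide.index)
    if strat.isna().any():
        raise ValueError("stratifying value missing for some eyes")
    results: list[RangeComparison] = []
    for i in range(scheme.n_ranges):
        mask = strat.map(scheme.assign) == i
        sub = pe_wide.loc[mask]
        rc = RangeComparison(i, scheme.label(i), int(mask.sum()), {})
        if rc.n == 0:
            results.append(rc)
            continue
        rc.summaries = {m: summarize(sub[m].to_numpy(), thresholds)
                        for m in sub.columns}
        rc.best_method = min(rc.summaries, key=lambda m: rc.summaries[m].medae)
        if rc.n >= min_n_for_tests:
            abs_err = sub.abs().to_numpy()
            rc.friedman = friedman_with_bonferroni(abs_err, list(sub.columns))
            for t in thresholds:
                binary = (sub.abs() <= t).astype(int).to_numpy()
                try:
                    rc.cochran[float(t)] = cochran_q(binary, list(sub.columns))
                except ValueError:
                    pass  # all eyes concordant at this threshold
        else:
            warnings.warn(
                f"range {rc.label!r}: n = {rc.n} < {min_n_for_tests}, "
                f"tests skipped", stacklevel=2)
        results.append(rc)
    return results


@dataclass
class TrendCurve:
    variable: str
    x: np.ndarray       # evaluation grid within the observed range
    fitted: np.ndarray
    span: float
    degree: int


def loess_trend(x: Sequence[float], y: Sequence[float], span: float = 0.75,
                degree: int = 1, grid_size: int = 100,
                variable: str = "X") -> TrendCurve:
    """Tricube-weighted local polynomial trend of PE against ``x``.

    Classical LOESS: at each grid point the ``span`` fraction of nearest
    observations is fit with a weighted polynomial of the given degree
    (tricube weights on distance scaled by the window radius) and evaluated
    at the point.  Grid spans the observed x-range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("LOESS trend requires n >= 10")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = x.size
    window = max(int(math.ceil(span * n)), degree + 2)
    if window > n:
        raise ValueError("span too small for local neighborhoods")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    grid = np.linspace(xs[0], xs[-1], grid_size)
    fitted = np.empty_like(grid)
    for gi, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        idx = np.argsort(d, kind="stable")[:window]
        h = d[idx].max()
        if h == 0:
            fitted[gi] = ys[idx].mean()
            continue
        u = d[idx] / h
        w = np.clip(1 - u ** 3, 0, None) ** 3
        w[w <= 0] = 1e-12  # boundary point of the window keeps a token weight
        xw = xs[idx] - x0  # center for conditioning
        design = np.vander(xw, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], ys[idx] * sw, rcond=None)
        fitted[gi] = beta[0]
    return TrendCurve(variable, grid, fitted, span, degree)
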