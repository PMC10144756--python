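"""Refractive prediction errors and the standard accuracy battery.

PE = postoperative SE minus predicted SE (positive = hyperopic surprise).
The battery computed per method/group is the field's usual one: signed mean
error (ME), median and mean absolute error (MedAE, MAE), standard error of
the absolute errors, min/max, interquartile range, a 95% CI around the MAE,
and counts/percentages of eyes within +-0.50 and +-1.00 D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["prediction_error", "GroupSummary", "summarize", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = (0.5, 1.0)


def prediction_error(se_post: float, se_pred: float) -> float:
    """PE (D) = observed postoperative SE - predicted SE."""
    return se_post - se_pred


@dataclass
class GroupSummary:
    n: int
    me: float                    # mean signed PE, D
    medae: float                 # median |PE|, D
    mae: float                   # mean |PE|, D
    se_mae: float                # standard error of |PE|, D
    min_abs: float
    max_abs: float
    iqr_abs: float               # IQR of |PE|, D (type-7 quartiles)
    ci95: tuple[float, float]    # mae +- 1.96*se_mae
    pct_within: Mapping[float, tuple[int, float]] = field(default_factory=dict)


def summarize(pes: Sequence[float],
              thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> GroupSummary:
    """Accuracy battery for one vector of prediction errors.

    All metrics except ME are computed on absolute PEs.  Threshold counts are
    inclusive (|PE| <= t); quartiles use linear interpolation.
    """
    pes = np.asarray(pes, dtype=float)
    if pes.size == 0:
        raise ValueError("summarize requires at least one prediction error")
    abs_pe = np.abs(pes)
    n = int(pes.size)
    mae = float(abs_pe.mean())
    se_mae = float(abs_pe.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q1, q3 = np.quantile(abs_pe, [0.25, 0.75])
    within = {
        float(t): (int((abs_pe <= t).sum()), 100.0 * float((abs_pe <= t).mean()))
        for t in thresholds
    }
    return GroupSummary(
        n=n,
        me=float(pes.mean()),
        medae=float(np.median(abs_pe)),
        mae=mae,
        se_mae=se_mae,
        min_abs=float(abs_pe.min()),
        max_abs=float(abs_pe.max()),
        iqr_abs=float(q3 - q1),
        ci95=(mae - 1.96 * se_mae, mae + 1.96 * se_mae),
        pct_within=within,
    )
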