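"""Lens-constant optimization by zeroing the mean prediction error.

Eyes are grouped by (IOL model x method); within each group the lens
constant is adjusted until the group's mean signed prediction error is zero,
removing the systematic offset so formulas become comparable.  Groups need at
least three eyes of a known model; eyes excluded from optimization (unknown
model or under-represented model) stay in the manufacturer-constant analysis.

Internal methods are continuous and monotone in the constant, so the zero is
found by bracketed scalar root-finding.  Barrett True-K predictions come from
a table: with several tabulated constants per eye the search interpolates and
scans a grid; with a single constant it degrades to a constant additive
refraction offset (flagged as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as spo

from .cohort import EyeRecord
from .formulas import (
    INTERNAL_METHODS,
    ExternalPredictions,
    Method,
    predict,
)
from .metrics import prediction_error

__all__ = [
    "OptimizationGroup",
    "ConstantEntry",
    "ConstantSet",
    "build_groups",
    "zero_mean_error",
    "optimize_all",
    "apply_constants",
    "ME_TOLERANCE",
]

MIN_GROUP_SIZE = 3
ME_TOLERANCE = 1e-3   # D; "closest to 0.000 D" at three printed decimals
BRACKET_HALFWIDTH = 6.0    # A-constant units; widened once to 12 on failure
EXTERNAL_GRID_STEP = 0.01  # grid granularity for table-based constants


@dataclass
class OptimizationGroup:
    iol_model: str
    method: Method
    eyes: list[EyeRecord]
    initial_constant: float
    optimized_constant: float | None = None
    achieved_me: float | None = None
    provenance: str = "manufacturer"   # {manufacturer, optimized, offset_optimized}
    offset: float = 0.0                # refraction offset (offset_optimized only)

    @property
    def n(self) -> int:
        return len(self.eyes)


@dataclass(frozen=True)
class ConstantEntry:
    value: float
    provenance: str            # {manufacturer, optimized, offset_optimized}
    n_eyes: int = 0
    achieved_me: float | None = None
    offset: float = 0.0


class ConstantSet:
    """Map (iol_model, method) -> lens constant with provenance."""

    def __init__(self):
        self._entries: dict[tuple[str, Method], ConstantEntry] = {}

    def set(self, iol_model: str, method: Method, entry: ConstantEntry) -> None:
        self._entries[(iol_model, Method(method))] = entry

    def get(self, iol_model: str, method: Method) -> ConstantEntry | None:
        return self._entries.get((iol_model, Method(method)))

    def items(self):
        return self._entries.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"iol_model": model, "method": method.value, "constant": e.value,
             "provenance": e.provenance, "n_eyes": e.n_eyes,
             "achieved_me_d": e.achieved_me}
            for (model, method), e in self._entries.items()
        ]
        return pd.DataFrame(rows, columns=["iol_model", "method", "constant",
                                           "provenance", "n_eyes", "achieved_me_d"])


def build_groups(
    records: Sequence[EyeRecord],
    methods: Iterable[Method] = INTERNAL_METHODS,
) -> tuple[list[OptimizationGroup], dict[str, str]]:
    """Form (model x method) optimization groups; tag excluded eyes.

    Exclusion reasons: ``unknown_model`` for eyes whose IOL model was not
    recorded, ``model_count_lt_3`` for models implanted in fewer than three
    eyes.  The eligible eyes constitute the optimizable subset (the
    constant-optimized analysis arm).
    """
    methods = [Method(m) for m in methods]
    by_model: dict[str, list[EyeRecord]] = {}
    exclusions: dict[str, str] = {}
    for r in records:
        if r.iol_model == "UNKNOWN":
            exclusions[r.eye_id] = "unknown_model"
        else:
            by_model.setdefault(r.iol_model, []).append(r)
    groups: list[OptimizationGroup] = []
    for model, eyes in by_model.items():
        if len(eyes) < MIN_GROUP_SIZE:
            for r in eyes:
                exclusions[r.eye_id] = "model_count_lt_3"
            continue
        # manufacturer A-constants should agree within a model; use the mode
        init = float(pd.Series([e.a_const for e in eyes]).mode().iloc[0])
        for method in methods:
            groups.append(OptimizationGroup(model, method, list(eyes), init))
    return groups, exclusions


def _group_me(group: OptimizationGroup, constant: float,
              external: ExternalPredictions | None = None) -> float:
    pes = [
        prediction_error(e.se_post, predict(group.method, e, constant, external).se_pred)
        for e in group.eyes
    ]
    return float(np.mean(pes))


def zero_mean_error(
    group: OptimizationGroup,
    external: ExternalPredictions | None = None,
) -> OptimizationGroup:
    """Adjust the group's lens constant until its mean PE is zero.

    Internal methods: bracketed root-finding on ME(c) over
    [A - 6, A + 6] (widened once to +-12).  External tables: grid search at
    0.01 steps over the tabulated constant range (ties toward the smaller
    constant); single-constant tables degrade to an additive refraction
    offset.  On failure the group keeps the manufacturer constant and is
    flagged.  The result is recorded in place and returned.
    """
    if group.n < MIN_GROUP_SIZE:
        raise ValueError(f"group {group.iol_model}/{group.method.value} has "
                         f"{group.n} eyes; optimization needs >= {MIN_GROUP_SIZE}")
    if group.method is Method.BARRETT_TK:
        return _zero_external(group, external)

    a0 = group.initial_constant
    me = lambda c: _group_me(group, c)
    me0 = me(a0)
    if abs(me0) <= ME_TOLERANCE:
        group.optimized_constant = a0
        group.achieved_me = me0
        group.provenance = "optimized"
        return group
    for half in (BRACKET_HALFWIDTH, 2 * BRACKET_HALFWIDTH):
        lo, hi = a0 - half, a0 + half
        flo, fhi = me(lo), me(hi)
        if flo == 0.0 or fhi == 0.0 or flo * fhi < 0:
            root = spo.brentq(me, lo, hi, xtol=1e-8)
            group.optimized_constant = float(root)
            group.achieved_me = me(root)
            group.provenance = "optimized"
            return group
    group.optimized_constant = None
    group.achieved_me = me0
    group.provenance = "manufacturer"
    return group


def _zero_external(group: OptimizationGroup,
                   external: ExternalPredictions | None) -> OptimizationGroup:
    if external is None:
        raise ValueError("external prediction table required to optimize Barrett True-K")
    n_constants = min(len(external.constants_for(e.eye_id)) for e in group.eyes)
    if n_constants >= 2:
        lo, hi = external.constant_range()
        grid = np.arange(lo, hi + EXTERNAL_GRID_STEP / 2, EXTERNAL_GRID_STEP)
        mes = np.array([_group_me(group, c, external) for c in grid])
        best = int(np.argmin(np.abs(mes)))  # argmin takes the first = smaller constant
        group.optimized_constant = float(grid[best])
        group.achieved_me = float(mes[best])
        group.provenance = "optimized"
    else:
        c0 = float(external.constants_for(group.eyes[0].eye_id)[0])
        me0 = _group_me(group, c0, external)
        group.optimized_constant = c0
        group.offset = me0          # se_pred_adjusted = se_pred + ME
        group.achieved_me = 0.0
        group.provenance = "offset_optimized"
    return group


def optimize_all(
    records: Sequence[EyeRecord],
    methods: Iterable[Method] = INTERNAL_METHODS,
    external: ExternalPredictions | None = None,
) -> tuple[ConstantSet, list[OptimizationGroup], dict[str, str]]:
    """Group the cohort and zero the mean error for every eligible group."""
    methods = [Method(m) for m in methods]
    groups, exclusions = build_groups(records, methods)
    constants = ConstantSet()
    for g in groups:
        zero_mean_error(g, external if g.method is Method.BARRETT_TK else None)
        value = g.optimized_constant if g.optimized_constant is not None else g.initial_constant
        constants.set(g.iol_model, g.method, ConstantEntry(
            value=value, provenance=g.provenance, n_eyes=g.n,
            achieved_me=g.achieved_me, offset=g.offset))
    return constants, groups, exclusions


def apply_constants(
    records: Sequence[EyeRecord],
    methods: Iterable[Method],
    constant_set: ConstantSet | None = None,
    external: ExternalPredictions | None = None,
    barrett_constant: float | None = None,
) -> pd.DataFrame:
    """Full eyes x methods prediction/PE matrix (long format).

    With ``constant_set=None`` every internal method uses the eye's
    manufacturer A-constant (the unoptimized analysis arm); otherwise
    optimized constants are looked up per (model, method) and the
    manufacturer constant is the fallback.  Returns columns
    eye_id, method, constant, provenance, predicted_se_d, pe_d.
    """
    methods = [Method(m) for m in methods]
    rows = []
    for r in records:
        for method in methods:
            entry = constant_set.get(r.iol_model, method) if constant_set else None
            offset = 0.0
            if entry is not None:
                constant, provenance, offset = entry.value, entry.provenance, entry.offset
            elif method is Method.BARRETT_TK:
                if external is None:
                    raise ValueError("Barrett True-K requires an external table")
                consts = external.constants_for(r.eye_id)
                constant = barrett_constant if barrett_constant is not None else float(consts[0])
                provenance = "manufacturer"
            else:
                constant, provenance = r.a_const, "manufacturer"
            cell = predict(method, r, constant,
                           external if method is Method.BARRETT_TK else None)
            se_pred = cell.se_pred + offset
            rows.append({
                "eye_id": r.eye_id, "method": method.value, "constant": constant,
                "provenance": provenance, "predicted_se_d": se_pred,
                "pe_d": prediction_error(r.se_post, se_pred),
            })
    return pd.DataFrame(rows, columns=["eye_id", "method", "constant",
                                       "provenance", "predicted_se_d", "pe_d"])
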