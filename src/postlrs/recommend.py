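"""Multi-formula recommender over K and AL ranges.

Encodes the decision table distilled from the range-partitioned accuracy
comparison: for each (K range x AL range) cell, the method (or unordered
pair of methods) with the best accuracy in that cell — one table for the
manufacturer-constant arm, one for the optimized-constant arm.  When a cell
names two methods, the eye's AL/K range acts as a tie-break; when that too is
inconclusive, the suggested IOL power is the arithmetic mean of the two
methods' powers for the surgeon's target refraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .formulas import Method
from .subgroups import RangeScheme

__all__ = [
    "K_SCHEME",
    "AL_SCHEME",
    "ALK_SCHEME",
    "RecommendationTable",
    "Recommendation",
    "builtin_tables",
    "recommend",
]

K_SCHEME = RangeScheme("K", (36.0, 38.0, 40.0))
AL_SCHEME = RangeScheme("AL", (26.5, 28.0, 29.5))
ALK_SCHEME = RangeScheme("ALK", (0.67, 0.75))

_A = (Method.ALMA,)
_B = (Method.BARRETT_TK,)
_AB = (Method.ALMA, Method.BARRETT_TK)


@dataclass(frozen=True)
class RecommendationTable:
    """Grid (K-range x AL-range) -> method(s), plus AL/K tie-break rows."""

    mode: str  # {"manufacturer_constants", "optimized_constants"}
    grid: Mapping[tuple[int, int], tuple[Method, ...]]
    alk_rows: tuple[Method | None, ...]  # None = inconclusive

    def __post_init__(self):
        expected = {(i, j) for i in range(K_SCHEME.n_ranges)
                    for j in range(AL_SCHEME.n_ranges)}
        if set(self.grid) != expected:
            raise ValueError("grid must cover all 4x4 (K, AL) cells")
        if len(self.alk_rows) != ALK_SCHEME.n_ranges:
            raise ValueError("need one AL/K row per AL/K range")

    def cell(self, k: float, al: float) -> tuple[Method, ...]:
        return self.grid[(K_SCHEME.assign(k), AL_SCHEME.assign(al))]


def builtin_tables() -> dict[str, RecommendationTable]:
    """The two built-in decision tables (manufacturer / optimized constants).

    Grid rows are K ranges (<=36, 36-38, 38-40, >40), columns AL ranges
    (<=26.5, 26.5-28, 28-29.5, >29.5).  In the optimized-constant table the
    flat-K long-AL cells resolve to ALMA because AL/K always exceeds 0.75
    there; the middle AL/K tie-break row of that table is inconclusive.
    """
    grid_a = {
        (0, 0): _B,  (0, 1): _B,  (0, 2): _B,  (0, 3): _B,
        (1, 0): _A,  (1, 1): _AB, (1, 2): _AB, (1, 3): _B,
        (2, 0): _A,  (2, 1): _A,  (2, 2): _A,  (2, 3): _AB,
        (3, 0): _A,  (3, 1): _A,  (3, 2): _A,  (3, 3): _AB,
    }
    grid_b = {
        (0, 0): _B,  (0, 1): _AB, (0, 2): _A,  (0, 3): _A,
        (1, 0): _B,  (1, 1): _AB, (1, 2): _A,  (1, 3): _A,
        (2, 0): _AB, (2, 1): _A,  (2, 2): _A,  (2, 3): _AB,
        (3, 0): _B,  (3, 1): _B,  (3, 2): _AB, (3, 3): _B,
    }
    return {
        "manufacturer_constants": RecommendationTable(
            "manufacturer_constants", grid_a,
            (Method.ALMA, Method.ALMA, Method.BARRETT_TK)),
        "optimized_constants": RecommendationTable(
            "optimized_constants", grid_b,
            (Method.BARRETT_TK, None, Method.ALMA)),
    }


@dataclass
class Recommendation:
    eye_id: str
    cell: tuple[Method, ...]
    tie_break_used: bool
    final: tuple[Method, ...]
    suggested_power: float
    rationale: str


def recommend(eye, mode: str, powers: Mapping[Method, float],
              tables: Mapping[str, RecommendationTable] | None = None) -> Recommendation:
    """Per-eye formula recommendation and suggested IOL power.

    ``powers`` maps each method that may be recommended to its IOL power for
    the surgeon's target refraction.  The (K, AL) cell is looked up; a pair
    cell consults the AL/K tie-break row, and an inconclusive row keeps the
    pair with the mean of the two powers.  AL/K rows never override a
    single-method cell.
    """
    tables = tables or builtin_tables()
    if mode not in tables:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(tables)}")
    table = tables[mode]
    cell = table.cell(eye.k, eye.al)
    tie_break_used = False
    if len(cell) == 1:
        final = cell
        rationale = (f"single-method cell for K={eye.k:.2f}, AL={eye.al:.2f}")
    else:
        alk = eye.al / eye.k
        row = table.alk_rows[ALK_SCHEME.assign(alk)]
        tie_break_used = True
        if row is not None and row in cell:
            final = (row,)
            rationale = (f"pair cell resolved by AL/K = {alk:.3f} "
                         f"({ALK_SCHEME.label(ALK_SCHEME.assign(alk))})")
        else:
            final = cell
            rationale = (f"pair cell, AL/K = {alk:.3f} inconclusive: "
                         f"averaging the two methods' powers")
    missing = [m for m in final if m not in powers]
    if missing:
        raise ValueError(
            f"eye {eye.eye_id!r}: no IOL power supplied for "
            f"{[m.value for m in missing]}")
    power = sum(powers[m] for m in final) / len(final)
    return Recommendation(eye.eye_id, cell, tie_break_used, final,
                          float(power), rationale)
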