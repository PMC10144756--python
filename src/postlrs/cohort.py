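"""Cohort table I/O and record-level validation.

One row per pseudophakic post-LRS eye: biometry measured before cataract
surgery (AL in mm, mean K in D), the implanted IOL (model label, labelled
A-constant, power) and the postoperative spectacle-plane spherical-equivalent
refraction.  Validation here enforces completeness and plausibility windows
only; clinical exclusions happen upstream of this package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .formulas import COEFFS

__all__ = [
    "EyeRecord",
    "ValidationResult",
    "COHORT_COLUMNS",
    "EXTERNAL_COLUMNS",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "write_rejection_log",
    "read_external_predictions",
    "convert_constant",
]

#: Canonical cohort CSV schema (comma-separated, UTF-8, dot decimals, one header).
COHORT_COLUMNS = ["eye_id", "al_mm", "k_d", "a_constant", "iol_model",
                  "iol_power_d", "postop_se_d", "source"]

#: External prediction CSV schema (Barrett True-K passthrough).
EXTERNAL_COLUMNS = ["eye_id", "method", "constant", "predicted_se_d"]

#: Default plausibility windows (validation guards, not clinical exclusions).
AL_WINDOW = (15.0, 40.0)   # mm
K_WINDOW = (25.0, 60.0)    # D
A_CONST_WINDOW = (100.0, 125.0)


@dataclass
class EyeRecord:
    """One post-LRS eye: biometry, implanted lens, observed refractive outcome."""

    eye_id: str
    al: float           # axial length, mm
    k: float            # mean keratometry, D
    a_const: float      # manufacturer A-constant
    iol_model: str      # "UNKNOWN" when the model was not recorded
    p_iol: float        # implanted IOL power, D
    se_post: float      # postoperative spherical equivalent, D (spectacle plane)
    source: str = "clinic"  # {"clinic", "literature"}


class ValidationResult(NamedTuple):
    ok: bool
    reason: str | None


def validate_record(r: EyeRecord,
                    al_window: tuple[float, float] = AL_WINDOW,
                    k_window: tuple[float, float] = K_WINDOW) -> ValidationResult:
    """Accept or reject one record with a single reason.

    A record is accepted when all four biometric/outcome fields are present
    and finite and AL, K, A-constant fall inside their plausibility windows.
    """
    for name, value in (("al", r.al), ("k", r.k), ("a_constant", r.a_const),
                        ("iol_power", r.p_iol)):
        if value is None or not math.isfinite(value):
            return ValidationResult(False, f"missing or non-numeric {name}")
    if r.se_post is None or not math.isfinite(r.se_post):
        return ValidationResult(False, "incomplete outcome")
    if not (al_window[0] <= r.al <= al_window[1]):
        return ValidationResult(False, "al out of plausibility window")
    if not (k_window[0] <= r.k <= k_window[1]):
        return ValidationResult(False, "k out of plausibility window")
    if not (A_CONST_WINDOW[0] < r.a_const < A_CONST_WINDOW[1]):
        return ValidationResult(False, "a_constant out of plausibility window")
    if r.source not in ("clinic", "literature"):
        return ValidationResult(False, f"unknown source {r.source!r}")
    return ValidationResult(True, None)


def _parse_float(text: str) -> float:
    text = (text or "").strip()
    if not text:
        return math.nan
    return float(text)


def read_cohort(path: str | Path) -> tuple[list[EyeRecord], list[tuple[int, str]]]:
    """Read and validate a cohort CSV.

    Returns (accepted records in row order, rejections as (row_number, reason)).
    Row numbers are 1-based over data rows.  A missing mandatory column is a
    schema error; an unparseable numeric in a row rejects that row only.
    """
    path = Path(path)
    records: list[EyeRecord] = []
    rejections: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames
                   and c != "source"]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                rec = EyeRecord(
                    eye_id=(row.get("eye_id") or f"row{i}").strip(),
                    al=_parse_float(row.get("al_mm", "")),
                    k=_parse_float(row.get("k_d", "")),
                    a_const=_parse_float(row.get("a_constant", "")),
                    iol_model=(row.get("iol_model") or "UNKNOWN").strip() or "UNKNOWN",
                    p_iol=_parse_float(row.get("iol_power_d", "")),
                    se_post=_parse_float(row.get("postop_se_d", "")),
                    source=(row.get("source") or "clinic").strip() or "clinic",
                )
            except ValueError:
                rejections.append((i, "unparseable numeric field"))
                continue
            ok, reason = validate_record(rec)
            if ok:
                records.append(rec)
            else:
                rejections.append((i, reason))
    return records, rejections


def write_cohort(records: Iterable[EyeRecord], path: str | Path) -> None:
    """Write records back to the canonical CSV schema."""
    frame = pd.DataFrame(
        [
            {
                "eye_id": r.eye_id, "al_mm": r.al, "k_d": r.k,
                "a_constant": r.a_const, "iol_model": r.iol_model,
                "iol_power_d": r.p_iol, "postop_se_d": r.se_post,
                "source": r.source,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_rejection_log(rejections: Iterable[tuple[int, str]], path: str | Path) -> None:
    """One line per rejected row: ``row_number<TAB>reason``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for row_number, reason in rejections:
            fh.write(f"{row_number}\t{reason}\n")


def read_external_predictions(path: str | Path) -> pd.DataFrame:
    """Read an external-prediction table (eye_id, method, constant, predicted_se_d)."""
    frame = pd.read_csv(path, dtype={"eye_id": str, "method": str})
    missing = [c for c in EXTERNAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return frame


_CONVERSIONS = {
    "srkt_acd": "convert.srkt_acd",
    "holladay_sf": "convert.holladay_sf",
    "shammas_pacd": "convert.shammas_pacd",
}


def convert_constant(a_const: float, target: str) -> float:
    """Convert a labelled A-constant to a base-formula native constant.

    Standard published linear relations: SRK/T ACD = 0.62467*A - 68.747,
    Holladay surgeon factor = 0.5663*A - 65.60, Shammas pACD = 0.5835*A - 64.40.
    """
    if target not in _CONVERSIONS:
        raise ValueError(f"unknown conversion target {target!r}; "
                         f"expected one of {sorted(_CONVERSIONS)}")
    slope, intercept = COEFFS[_CONVERSIONS[target]]
    return slope * a_const + intercept
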