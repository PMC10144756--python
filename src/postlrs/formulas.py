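"""Vergence-based IOL power formulas and no-history post-LRS corrections.

The back-calculation at the heart of the pipeline: given an eye's biometry
(axial length AL, mean keratometry K), a lens constant, and the power of the
IOL actually implanted, each method returns the spectacle-plane spherical
equivalent (SE) refraction it *predicts* for that eye.  Comparing this with
the measured postoperative SE gives the refractive prediction error.

Three base formulas are implemented in their published closed forms:

* SRK/T     -- theoretic vergence formula with regression-derived ELP
               (corrected axial length, corneal width, corneal height).
* Holladay 1 -- three-part vergence system with anatomical ACD + surgeon
               factor.
* Shammas-PL -- post-LASIK thin-lens formula with its own axial-length
               adjustment (0.9*AL + 2.3) and pACD constant.

The no-history corrections (ALMA, Ferrara, Jin, Kim, Latkany, Shammas c.d.)
transform the measured keratometry and/or add an IOL-power offset before the
base formula is evaluated; each method's coefficients live in the
:data:`COEFFS` registry.  Barrett True-K has no public algebra and is served
from an externally supplied prediction table (see :class:`ExternalPredictions`).

All refractions are spectacle-plane SE at a 12 mm vertex.  Every base formula
is linear-fractional in the IOL power, so both the predicted refraction at a
given power and the power achieving a given target refraction have closed
forms; the two are exact inverses of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Method",
    "BaseFormula",
    "MethodSpec",
    "METHOD_SPECS",
    "INTERNAL_METHODS",
    "OpticalConstants",
    "OPTICS",
    "COEFFS",
    "PredictionCell",
    "ExternalPredictions",
    "srkt_predict_refraction",
    "srkt_power",
    "holladay1_predict_refraction",
    "holladay1_power",
    "shammas_cd_correct_k",
    "shammas_pl_predict_refraction",
    "shammas_pl_power",
    "apply_correction",
    "predict",
    "emmetropic_power",
]


class Method(str, Enum):
    """No-history IOL power calculation methods under comparison."""

    ALMA = "ALMA"
    BARRETT_TK = "BARRETT_TK"
    FERRARA = "FERRARA"
    JIN = "JIN"
    KIM = "KIM"
    LATKANY = "LATKANY"
    SHAMMAS = "SHAMMAS"


class BaseFormula(str, Enum):
    SRKT = "SRKT"
    HOLLADAY1 = "HOLLADAY1"
    SHAMMAS_PL = "SHAMMAS_PL"
    EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class MethodSpec:
    method: Method
    base_formula: BaseFormula
    native_target: float = 0.0  # D; the refraction the method itself aims for


METHOD_SPECS: Mapping[Method, MethodSpec] = {
    Method.ALMA: MethodSpec(Method.ALMA, BaseFormula.SRKT),
    Method.BARRETT_TK: MethodSpec(Method.BARRETT_TK, BaseFormula.EXTERNAL),
    Method.FERRARA: MethodSpec(Method.FERRARA, BaseFormula.SRKT),
    Method.JIN: MethodSpec(Method.JIN, BaseFormula.HOLLADAY1, native_target=-0.75),
    Method.KIM: MethodSpec(Method.KIM, BaseFormula.SRKT),
    Method.LATKANY: MethodSpec(Method.LATKANY, BaseFormula.SRKT),
    Method.SHAMMAS: MethodSpec(Method.SHAMMAS, BaseFormula.SHAMMAS_PL),
}

#: Methods whose algebra is implemented here (everything except Barrett True-K).
INTERNAL_METHODS = tuple(m for m in Method if m is not Method.BARRETT_TK)


@dataclass(frozen=True)
class OpticalConstants:
    """Shared optical conventions of the SRK/T-family vergence chain."""

    n_aqueous: float = 1.336
    n_cornea_minus_1: float = 0.333  # SRK/T keratometric convention, r = 337.5/K
    vertex_mm: float = 12.0
    retinal_thickness_coeffs: tuple[float, float] = (0.65696, -0.02029)


OPTICS = OpticalConstants()

# ---------------------------------------------------------------------------
# Coefficient registry.  One entry per published regression/constant used by
# the engine.  Values for the base formulas and constant conversions follow
# the original formula publications; the no-history correction entries encode
# the functional form each method applies to the measured biometry (see
# docs/methods.md for the provenance discussion of each).
# ---------------------------------------------------------------------------
COEFFS: dict[str, tuple[float, ...]] = {
    # SRK/T chain
    "srkt.lcor": (-3.446, 1.716, -0.0237),       # corrected AL above 24.2 mm
    "srkt.cw": (-5.41, 0.58412, 0.098),          # corneal width regression
    "srkt.acd_offset": (-3.336,),                # ELP = H + ACDconst - 3.336
    "srkt.keratometric_radius": (337.5,),        # r (mm) = 337.5 / K
    # Holladay 1 chain
    "holladay.ag": (12.5 / 23.45, 13.5),         # AG = al*12.5/23.45, cap 13.5
    "holladay.acd": (0.56,),                     # anatomical ACD intercept
    "holladay.al_plus": (0.2,),                  # optical AL = AL + 0.2
    "holladay.n_cornea_minus_1": (1.0 / 3.0,),   # Holladay's 4/3 cornea
    # Shammas-PL chain
    "shammas.al_adjust": (0.9, 2.3),             # L* = 0.9*AL + 2.3
    "shammas.k_vergence": (1.0125,),             # 1/Pc = 1.0125/Kc
    "shammas.elp_plus": (0.05,),                 # optical ELP = pACD + 0.05
    "shammas.cd": (1.14, -6.8),                  # Kc = 1.14*K - 6.8
    # A-constant conversions to base-formula native constants
    "convert.srkt_acd": (0.62467, -68.747),
    "convert.holladay_sf": (0.5663, -65.60),
    "convert.shammas_pacd": (0.5835, -64.40),
    # No-history corrections
    "ferrara.index": (-0.0006, 0.0213, 1.1572),  # AL-dependent keratometric index
    "alma.rfactor": (-0.0276, 1.6512),           # AL-dependent radius scaling
    "kim.index_ratio": (0.3319 / 0.3375,),       # adjusted keratometric index 1.3319
    "jin.k": (1.114, -6.062),                    # linear corrected-K regression
    "latkany.offset": (0.47, 0.85),              # power offset from estimated ablation
    "latkany.se_from_k": (43.86, 0.8),           # SE_pre ~ (K - 43.86)/0.8
}


@dataclass
class PredictionCell:
    """Predicted refraction for one (eye, method) pair at a given constant."""

    eye_id: str
    method: Method
    constant: float
    se_pred: float
    pe: float | None = None


# ---------------------------------------------------------------------------
# Base formulas
# ---------------------------------------------------------------------------


def _srkt_geometry(al: float, k: float, acd_const: float):
    """ELP and optical axial length of the SRK/T chain.

    Returns (r, lopt, elp).  The corneal-height square root is clamped at
    zero when the corneal-width chord exceeds the corneal diameter implied by
    r (the formula's published domain guard).
    """
    r = COEFFS["srkt.keratometric_radius"][0] / k
    a0, a1, a2 = COEFFS["srkt.lcor"]
    lcor = al if al <= 24.2 else a0 + a1 * al + a2 * al * al
    c0, c1, c2 = COEFFS["srkt.cw"]
    cw = c0 + c1 * lcor + c2 * k
    h = r - math.sqrt(max(r * r - cw * cw / 4.0, 0.0))
    elp = h + acd_const + COEFFS["srkt.acd_offset"][0]
    t0, t1 = OPTICS.retinal_thickness_coeffs
    lopt = al + t0 + t1 * al
    return r, lopt, elp


def _vergence_terms(r: float, lopt: float, elp: float, na: float, ncm1: float):
    """Coefficients of the linear-fractional refraction/power relation.

    With A1 = 1000*na*(na*r - ncm1*L), B1 = (L-C)*(na*r - ncm1*C),
    C1 = na*(V*(na*r - ncm1*L) + L*r) and
    D1 = (L-C)*(V*(na*r - ncm1*C) + C*r), the predicted spectacle refraction
    at implanted power P is REF = (A1 - P*B1) / (C1 - 0.001*P*D1) and the
    power for target refraction R is P = (R*C1 - A1) / (0.001*R*D1 - B1).
    """
    v = OPTICS.vertex_mm
    a1 = 1000.0 * na * (na * r - ncm1 * lopt)
    b1 = (lopt - elp) * (na * r - ncm1 * elp)
    c1 = na * (v * (na * r - ncm1 * lopt) + lopt * r)
    d1 = (lopt - elp) * (v * (na * r - ncm1 * elp) + elp * r)
    return a1, b1, c1, d1


def srkt_predict_refraction(al: float, k: float, acd_const: float, p_iol: float) -> float:
    """SRK/T predicted spectacle SE (D) for implanted power ``p_iol``.

    ``acd_const`` is on the SRK/T ACD (mm) scale, i.e. 0.62467*A - 68.747.
    """
    r, lopt, elp = _srkt_geometry(al, k, acd_const)
    a1, b1, c1, d1 = _vergence_terms(r, lopt, elp, OPTICS.n_aqueous, OPTICS.n_cornea_minus_1)
    ref = (a1 - p_iol * b1) / (c1 - 0.001 * p_iol * d1)
    if not math.isfinite(ref):
        raise ArithmeticError("non-finite SRK/T refraction")
    return ref


def srkt_power(al: float, k: float, acd_const: float, target: float = 0.0) -> float:
    """SRK/T IOL power (D) achieving spectacle refraction ``target``."""
    r, lopt, elp = _srkt_geometry(al, k, acd_const)
    a1, b1, c1, d1 = _vergence_terms(r, lopt, elp, OPTICS.n_aqueous, OPTICS.n_cornea_minus_1)
    return (target * c1 - a1) / (0.001 * target * d1 - b1)


def _holladay_geometry(al: float, k: float, sf: float):
    r = COEFFS["srkt.keratometric_radius"][0] / k
    ag_slope, ag_cap = COEFFS["holladay.ag"]
    ag = min(al * ag_slope, ag_cap)
    acd = COEFFS["holladay.acd"][0] + r - math.sqrt(max(r * r - ag * ag / 4.0, 0.0))
    elp = acd + sf
    alm = al + COEFFS["holladay.al_plus"][0]
    return r, alm, elp


def holladay1_predict_refraction(al: float, k: float, sf: float, p_iol: float) -> float:
    """Holladay 1 predicted spectacle SE (D); ``sf`` is the surgeon factor (mm)."""
    r, alm, elp = _holladay_geometry(al, k, sf)
    ncm1 = COEFFS["holladay.n_cornea_minus_1"][0]
    a1, b1, c1, d1 = _vergence_terms(r, alm, elp, OPTICS.n_aqueous, ncm1)
    ref = (a1 - p_iol * b1) / (c1 - 0.001 * p_iol * d1)
    if not math.isfinite(ref):
        raise ArithmeticError("non-finite Holladay 1 refraction")
    return ref


def holladay1_power(al: float, k: float, sf: float, target: float = 0.0) -> float:
    r, alm, elp = _holladay_geometry(al, k, sf)
    ncm1 = COEFFS["holladay.n_cornea_minus_1"][0]
    a1, b1, c1, d1 = _vergence_terms(r, alm, elp, OPTICS.n_aqueous, ncm1)
    return (target * c1 - a1) / (0.001 * target * d1 - b1)


def shammas_cd_correct_k(k_measured: float) -> float:
    """Shammas clinically-derived post-LASIK K correction, Kc = 1.14*K - 6.8."""
    s, i = COEFFS["shammas.cd"]
    return s * k_measured + i


def _shammas_terms(al: float, pacd: float):
    s, i = COEFFS["shammas.al_adjust"]
    lstar = s * al + i
    elp = pacd + COEFFS["shammas.elp_plus"][0]
    dl = 1336.0 / (lstar - elp)           # dioptric demand at the lens plane
    d = elp / 1336.0                      # reduced cornea-to-lens distance (m)
    return dl, d


def shammas_pl_predict_refraction(al: float, kc: float, pacd: float, p_iol: float) -> float:
    """Shammas-PL predicted spectacle SE (D) at implanted power ``p_iol``.

    ``kc`` is the *corrected* keratometry (apply :func:`shammas_cd_correct_k`
    first); ``pacd`` the Shammas post-LASIK ELP constant (0.5835*A - 64.40).
    """
    dl, d = _shammas_terms(al, pacd)
    pc = kc / COEFFS["shammas.k_vergence"][0]
    rem = dl - p_iol
    if rem <= 0:
        raise ArithmeticError("IOL power exceeds the eye's dioptric demand")
    rc = 1.0 / (d + 1.0 / rem) - pc       # refraction at the corneal plane
    ref = rc / (1.0 + OPTICS.vertex_mm / 1000.0 * rc)
    if not math.isfinite(ref):
        raise ArithmeticError("non-finite Shammas-PL refraction")
    return ref


def shammas_pl_power(al: float, kc: float, pacd: float, target: float = 0.0) -> float:
    dl, d = _shammas_terms(al, pacd)
    pc = kc / COEFFS["shammas.k_vergence"][0]
    rc = target / (1.0 - OPTICS.vertex_mm / 1000.0 * target)  # spectacle -> cornea
    return dl - 1.0 / (1.0 / (pc + rc) - d)


# ---------------------------------------------------------------------------
# No-history corrections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Correction:
    """Modified biometry and power-offset rule produced by a method."""

    al: float
    k: float
    power_offset: float = 0.0  # D added to the base formula's required power


def apply_correction(method: Method, al: float, k: float) -> Correction:
    """Transform measured (AL, K) into the inputs the method feeds its base formula.

    Each correction is applied exactly once per prediction; composing them is
    not idempotent (they are affine in K), so callers must never chain them.
    """
    method = Method(method)
    if method is Method.BARRETT_TK:
        raise ValueError("Barrett True-K has no internal correction; use an external table")
    if method is Method.SHAMMAS:
        return Correction(al=al, k=shammas_cd_correct_k(k))
    if method is Method.FERRARA:
        q2, q1, q0 = COEFFS["ferrara.index"]
        n = q2 * al * al + q1 * al + q0
        return Correction(al=al, k=k * (n - 1.0) / 0.3375)
    if method is Method.ALMA:
        s, i = COEFFS["alma.rfactor"]
        rfactor = s * al + i
        if rfactor <= 0:
            raise ArithmeticError("radius scaling factor non-positive at this AL")
        return Correction(al=al, k=k * rfactor)
    if method is Method.KIM:
        return Correction(al=al, k=k * COEFFS["kim.index_ratio"][0])
    if method is Method.JIN:
        s, i = COEFFS["jin.k"]
        return Correction(al=al, k=s * k + i)
    if method is Method.LATKANY:
        k0, per_d = COEFFS["latkany.se_from_k"]
        se_pre = (k - k0) / per_d
        a, b = COEFFS["latkany.offset"]
        return Correction(al=al, k=k, power_offset=-(a * se_pre + b))
    raise ValueError(f"unknown method: {method}")


# ---------------------------------------------------------------------------
# External (Barrett True-K) prediction tables
# ---------------------------------------------------------------------------


class ExternalPredictions:
    """Per-eye predicted refractions computed outside this package.

    Holds rows (eye_id, constant, predicted_se_d) for one external method.
    When a table carries several constants per eye, :meth:`lookup` linearly
    interpolates between the two bracketing constants, which is what lets the
    constant-zeroing search treat the external method like a continuous one.
    """

    def __init__(self, frame: pd.DataFrame, method: Method = Method.BARRETT_TK):
        required = {"eye_id", "constant", "predicted_se_d"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"external prediction table missing columns: {sorted(missing)}")
        self.method = Method(method)
        self._by_eye: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for eye_id, grp in frame.groupby("eye_id", sort=False):
            g = grp.sort_values("constant")
            self._by_eye[str(eye_id)] = (
                g["constant"].to_numpy(dtype=float),
                g["predicted_se_d"].to_numpy(dtype=float),
            )

    @property
    def eye_ids(self) -> list[str]:
        return list(self._by_eye)

    def constants_for(self, eye_id: str) -> np.ndarray:
        return self._by_eye[str(eye_id)][0]

    def constant_range(self) -> tuple[float, float]:
        los = [c[0] for c, _ in self._by_eye.values()]
        his = [c[-1] for c, _ in self._by_eye.values()]
        return max(los), min(his)

    def lookup(self, eye_id: str, constant: float) -> float:
        key = str(eye_id)
        if key not in self._by_eye:
            raise KeyError(f"no external prediction registered for eye {eye_id!r}")
        consts, preds = self._by_eye[key]
        if len(consts) == 1:
            if not math.isclose(constant, consts[0], abs_tol=1e-9):
                raise KeyError(
                    f"eye {eye_id!r}: external table has a single constant "
                    f"{consts[0]:g}, requested {constant:g}"
                )
            return float(preds[0])
        if constant < consts[0] - 1e-9 or constant > consts[-1] + 1e-9:
            raise KeyError(
                f"eye {eye_id!r}: constant {constant:g} outside tabulated "
                f"range [{consts[0]:g}, {consts[-1]:g}]"
            )
        return float(np.interp(constant, consts, preds))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def _native_constant(method: Method, a_const: float) -> float:
    base = METHOD_SPECS[method].base_formula
    if base is BaseFormula.SRKT:
        s, i = COEFFS["convert.srkt_acd"]
    elif base is BaseFormula.HOLLADAY1:
        s, i = COEFFS["convert.holladay_sf"]
    elif base is BaseFormula.SHAMMAS_PL:
        s, i = COEFFS["convert.shammas_pacd"]
    else:
        raise ValueError(f"{method} has no native constant conversion")
    return s * a_const + i


def predict(method: Method, eye, constant: float,
            external: ExternalPredictions | None = None) -> PredictionCell:
    """Predicted spectacle SE for ``eye`` at its implanted power.

    ``constant`` is on the A-constant scale for every internal method (the
    conversion to the base formula's native constant happens here); for
    Barrett True-K it is whatever scale the external table was computed at.
    """
    method = Method(method)
    if method is Method.BARRETT_TK:
        if external is None:
            raise ValueError(f"Barrett True-K requested for eye {eye.eye_id!r} "
                             "but no external prediction table is registered")
        se = external.lookup(eye.eye_id, constant)
        return PredictionCell(eye.eye_id, method, constant, se)

    corr = apply_correction(method, eye.al, eye.k)
    native = _native_constant(method, constant)
    base = METHOD_SPECS[method].base_formula
    p_eff = eye.p_iol - corr.power_offset
    if base is BaseFormula.SRKT:
        se = srkt_predict_refraction(corr.al, corr.k, native, p_eff)
    elif base is BaseFormula.HOLLADAY1:
        se = holladay1_predict_refraction(corr.al, corr.k, native, p_eff)
    else:
        se = shammas_pl_predict_refraction(corr.al, corr.k, native, p_eff)
    return PredictionCell(eye.eye_id, method, constant, se)


def emmetropic_power(method: Method, eye, constant: float, target: float = 0.0) -> float:
    """IOL power (D) for which the method predicts refraction ``target``.

    Closed form: every base formula is linear-fractional in power, so the
    inverse is exact; power-offset methods add their offset afterwards.
    """
    method = Method(method)
    if method is Method.BARRETT_TK:
        raise ValueError("emmetropic power is only defined for internal methods")
    corr = apply_correction(method, eye.al, eye.k)
    native = _native_constant(method, constant)
    base = METHOD_SPECS[method].base_formula
    if base is BaseFormula.SRKT:
        p = srkt_power(corr.al, corr.k, native, target)
    elif base is BaseFormula.HOLLADAY1:
        p = holladay1_power(corr.al, corr.k, native, target)
    else:
        p = shammas_pl_power(corr.al, corr.k, native, target)
    return p + corr.power_offset
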