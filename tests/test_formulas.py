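"""Formula engine: inversion identity, monotonicity, golden values against an
independent vergence-propagation oracle, correction dispatch, Barrett passthrough."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from postlrs import (
    EyeRecord,
    ExternalPredictions,
    Method,
    apply_correction,
    convert_constant,
    emmetropic_power,
    predict,
)
from postlrs.formulas import (
    COEFFS,
    INTERNAL_METHODS,
    METHOD_SPECS,
    OPTICS,
    _holladay_geometry,
    _srkt_geometry,
    holladay1_power,
    holladay1_predict_refraction,
    shammas_cd_correct_k,
    shammas_pl_power,
    shammas_pl_predict_refraction,
    srkt_power,
    srkt_predict_refraction,
)

from conftest import make_eye


def refraction_by_propagation(r_mm, axial, elp, ncm1, p_iol, na=1.336, vertex=12.0):
    """Independent oracle: find the spectacle refraction R for which rays from
    a distant object, corrected by R at the vertex, refracted by the cornea
    (power n_c-1 over r) and the IOL at the ELP, focus on the retina.  Pure
    vergence propagation solved numerically — shares no algebra with the
    closed-form implementations."""
    pc = 1000.0 * ncm1 / r_mm

    def focus_error(R):
        v = R / (1 - vertex / 1000.0 * R) + pc
        v = v / (1 - elp / 1000.0 / na * v) + p_iol
        if v <= 0:
            return 1e9
        return na / v * 1000.0 - (axial - elp)

    return brentq(focus_error, -30, 30, xtol=1e-12)


class TestBaseFormulaOracle:
    """Closed forms vs the numerical propagation oracle."""

    @pytest.mark.parametrize("al,k", [(23.5, 43.0), (27.0, 38.0), (31.0, 34.5)])
    @pytest.mark.parametrize("dp", [-1.0, 0.0, 3.0])
    def test_srkt_matches_propagation(self, al, k, dp):
        acd = convert_constant(118.4, "srkt_acd")
        r, lopt, elp = _srkt_geometry(al, k, acd)
        p = srkt_power(al, k, acd) + dp
        closed = srkt_predict_refraction(al, k, acd, p)
        oracle = refraction_by_propagation(r, lopt, elp, OPTICS.n_cornea_minus_1, p)
        assert closed == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("dp", [-1.0, 0.0, 3.0])
    def test_holladay_matches_propagation(self, dp):
        sf = convert_constant(118.4, "holladay_sf")
        al, k = 23.5, 43.0
        r, alm, elp = _holladay_geometry(al, k, sf)
        p = holladay1_power(al, k, sf) + dp
        closed = holladay1_predict_refraction(al, k, sf, p)
        oracle = refraction_by_propagation(r, alm, elp, 1.0 / 3.0, p)
        assert closed == pytest.approx(oracle, abs=1e-9)

    def test_golden_values(self):
        """Frozen reference refractions (derived once from the propagation oracle)."""
        acd = convert_constant(118.4, "srkt_acd")
        assert srkt_power(23.5, 43.0, acd) == pytest.approx(21.083617, abs=1e-5)
        assert srkt_predict_refraction(23.5, 43.0, acd, 21.083617 - 1.0) == \
            pytest.approx(0.699541, abs=1e-5)
        sf = convert_constant(118.4, "holladay_sf")
        assert holladay1_power(23.5, 43.0, sf) == pytest.approx(21.196961, abs=1e-5)
        assert holladay1_predict_refraction(23.5, 43.0, sf, 21.196961 - 1.0) == \
            pytest.approx(0.692477, abs=1e-5)
        pacd = convert_constant(118.4, "shammas_pacd")
        kc = shammas_cd_correct_k(38.0)
        assert shammas_pl_power(27.0, kc, pacd) == pytest.approx(19.748483, abs=1e-5)
        assert shammas_pl_predict_refraction(27.0, kc, pacd, 19.748483 - 1.0) == \
            pytest.approx(0.751424, abs=1e-5)


class TestInversionAndMonotonicity:
    def test_inversion_identity_over_grid(self, biometry_grid):
        """predict at emmetropic_power(target) returns target, every method, 200 eyes."""
        for method in INTERNAL_METHODS:
            target = METHOD_SPECS[method].native_target
            for al, k in biometry_grid:
                eye = make_eye(al, k)
                p = emmetropic_power(method, eye, 118.4, target)
                eye.p_iol = p
                assert abs(predict(method, eye, 118.4).se_pred - target) < 1e-6

    @pytest.mark.parametrize("method", INTERNAL_METHODS)
    def test_se_strictly_decreasing_in_power(self, method):
        eye = make_eye(27.5, 37.0)
        base = emmetropic_power(method, eye, 118.4)
        powers = base + np.linspace(-4, 4, 9)
        ses = []
        for p in powers:
            eye.p_iol = p
            ses.append(predict(method, eye, 118.4).se_pred)
        assert all(a > b for a, b in zip(ses, ses[1:]))

    @pytest.mark.parametrize("method", INTERNAL_METHODS)
    def test_se_strictly_increasing_in_a_constant(self, method):
        # A deeper effective lens position (larger A) demands more power, so
        # at fixed implanted power the predicted refraction is more hyperopic.
        eye = make_eye(27.5, 37.0, p_iol=22.0)
        ses = [predict(method, eye, a).se_pred for a in (117.0, 118.4, 120.0)]
        assert ses[0] < ses[1] < ses[2]

    def test_more_myopic_target_needs_more_power(self):
        eye = make_eye(27.0, 38.0)
        for method in INTERNAL_METHODS:
            assert emmetropic_power(method, eye, 118.4, -0.75) > \
                emmetropic_power(method, eye, 118.4, 0.0)

    def test_closed_form_power_agrees_with_root_finding(self, biometry_grid):
        """Self-consistency: invert predict() numerically on 100 eyes, SRK/T path."""
        acd = convert_constant(118.4, "srkt_acd")
        for al, k in biometry_grid[::2]:
            closed = srkt_power(al, k, acd, 0.0)
            rooted = brentq(lambda p: srkt_predict_refraction(al, k, acd, p),
                            -10, 60, xtol=1e-9)
            assert abs(closed - rooted) < 1e-6


class TestContinuityAtClamps:
    def test_lcor_join_at_24_2(self):
        # the published regression joins AL = 24.2 only to ~1.5e-3 mm, so a
        # sub-millidiopter step is inherited from the formula itself
        acd = convert_constant(118.4, "srkt_acd")
        left = srkt_predict_refraction(24.2 - 1e-9, 42.0, acd, 20.0)
        right = srkt_predict_refraction(24.2 + 1e-9, 42.0, acd, 20.0)
        assert abs(left - right) < 1e-3

    def test_holladay_ag_cap_join(self):
        sf = convert_constant(118.4, "holladay_sf")
        al_cap = 13.5 * 23.45 / 12.5
        left = holladay1_predict_refraction(al_cap - 1e-9, 36.0, sf, 18.0)
        right = holladay1_predict_refraction(al_cap + 1e-9, 36.0, sf, 18.0)
        assert abs(left - right) < 1e-6

    def test_corneal_height_domain_guard(self):
        # absurdly steep K makes r small; the sqrt clamp must not produce NaN
        acd = convert_constant(118.4, "srkt_acd")
        assert math.isfinite(srkt_predict_refraction(33.0, 58.0, acd, 10.0))


class TestCorrections:
    def test_shammas_cd_regression(self):
        assert shammas_cd_correct_k(38.0) == pytest.approx(36.52, abs=1e-9)
        assert shammas_cd_correct_k(40.0) == pytest.approx(38.80, abs=1e-9)
        fixed = 6.8 / 0.14
        assert shammas_cd_correct_k(fixed) == pytest.approx(fixed, abs=1e-9)
        assert shammas_cd_correct_k(fixed - 5) < fixed - 5

    def test_shammas_delegates(self):
        corr = apply_correction(Method.SHAMMAS, 27.0, 38.0)
        assert corr.k == pytest.approx(36.52) and corr.al == 27.0

    def test_ferrara_lowers_corneal_power_in_long_eyes(self):
        assert apply_correction(Method.FERRARA, 30.0, 38.0).k < 38.0

    def test_jin_aims_minus_075(self):
        assert METHOD_SPECS[Method.JIN].native_target == -0.75

    def test_latkany_adds_power_for_flat_corneas(self):
        corr = apply_correction(Method.LATKANY, 28.0, 38.0)
        assert corr.power_offset > 0 and corr.k == 38.0

    def test_corrections_are_affine_not_idempotent(self):
        # applying a K-correction twice must differ from applying it once,
        # so the engine's single-application dispatch is load-bearing
        once = apply_correction(Method.SHAMMAS, 27.0, 38.0).k
        twice = apply_correction(Method.SHAMMAS, 27.0, once).k
        assert abs(twice - once) > 1e-6
        eye = make_eye(27.0, 38.0, p_iol=20.0)
        via_predict = predict(Method.SHAMMAS, eye, 118.4).se_pred
        direct = shammas_pl_predict_refraction(
            27.0, once, convert_constant(118.4, "shammas_pacd"), 20.0)
        assert via_predict == pytest.approx(direct, abs=1e-12)

    def test_barrett_has_no_internal_correction(self):
        with pytest.raises(ValueError):
            apply_correction(Method.BARRETT_TK, 27.0, 38.0)


class TestDispatch:
    def test_barrett_passthrough(self):
        table = ExternalPredictions(pd.DataFrame(
            {"eye_id": ["X"], "constant": [119.0], "predicted_se_d": [-0.42]}))
        eye = make_eye(27.0, 38.0, eye_id="X")
        assert predict(Method.BARRETT_TK, eye, 119.0, table).se_pred == -0.42

    def test_barrett_missing_eye_names_it(self):
        table = ExternalPredictions(pd.DataFrame(
            {"eye_id": ["X"], "constant": [119.0], "predicted_se_d": [-0.42]}))
        eye = make_eye(27.0, 38.0, eye_id="Y")
        with pytest.raises(KeyError, match="Y"):
            predict(Method.BARRETT_TK, eye, 119.0, table)

    def test_barrett_without_table_errors(self):
        with pytest.raises(ValueError, match="external"):
            predict(Method.BARRETT_TK, make_eye(27.0, 38.0), 119.0)

    def test_full_seven_method_sweep_cardinality(self):
        eyes = [make_eye(26 + i, 38 - i, eye_id=f"e{i}", p_iol=20.0)
                for i in range(3)]
        table = ExternalPredictions(pd.DataFrame({
            "eye_id": [e.eye_id for e in eyes],
            "constant": [119.0] * 3,
            "predicted_se_d": [-0.1, -0.2, -0.3]}))
        cells = [
            predict(m, e, 119.0 if m is Method.BARRETT_TK else 118.4,
                    table if m is Method.BARRETT_TK else None)
            for e in eyes for m in Method
        ]
        assert len(cells) == 21
        assert all(math.isfinite(c.se_pred) for c in cells)

    def test_external_interpolation_between_constants(self):
        table = ExternalPredictions(pd.DataFrame({
            "eye_id": ["X", "X"], "constant": [118.0, 120.0],
            "predicted_se_d": [-1.0, 1.0]}))
        assert table.lookup("X", 119.0) == pytest.approx(0.0)
        with pytest.raises(KeyError):
            table.lookup("X", 121.0)
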