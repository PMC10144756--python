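"""Constant zeroing: grouping rules, root-finding, offset removal, fallbacks."""

import numpy as np
import pandas as pd
import pytest

from postlrs import (
    ExternalPredictions,
    Method,
    SimulationConfig,
    apply_constants,
    build_groups,
    optimize_all,
    predict,
    simulate_cohort,
    synthetic_barrett_table,
    zero_mean_error,
)
from postlrs.optimize import ME_TOLERANCE, OptimizationGroup

from conftest import make_eye


def _eyes(n, model, start=0, **kw):
    return [make_eye(26.0 + 0.3 * i, 39.0 - 0.2 * i, model=model,
                     eye_id=f"{model}{start + i}", **kw) for i in range(n)]


class TestBuildGroups:
    def test_sub3_models_excluded(self):
        cohort = _eyes(5, "X") + _eyes(2, "Y")
        groups, excl = build_groups(cohort, [Method.SHAMMAS])
        assert [(g.iol_model, g.n) for g in groups] == [("X", 5)]
        assert set(excl.values()) == {"model_count_lt_3"} and len(excl) == 2

    def test_unknown_model_excluded(self):
        groups, excl = build_groups(_eyes(3, "UNKNOWN"), [Method.SHAMMAS])
        assert groups == []
        assert set(excl.values()) == {"unknown_model"} and len(excl) == 3

    def test_cohort_split_132_to_90(self):
        """25 unknown-model + 17 eyes in sub-3 models leave 90 optimizable."""
        cohort = (
            _eyes(25, "UNKNOWN")
            + [e for j in range(8) for e in _eyes(2, f"RARE{j}", start=10 * j)]
            + _eyes(1, "RARE9")
            + _eyes(50, "BIG1") + _eyes(40, "BIG2")
        )
        assert len(cohort) == 132
        groups, excl = build_groups(cohort, [Method.SHAMMAS])
        optimizable = {e.eye_id for g in groups for e in g.eyes}
        assert len(optimizable) == 90
        assert len(excl) == 42
        assert sum(v == "unknown_model" for v in excl.values()) == 25
        assert sum(v == "model_count_lt_3" for v in excl.values()) == 17

    def test_two_eye_group_never_constructed(self):
        groups, _ = build_groups(_eyes(2, "X"), [Method.SHAMMAS])
        assert groups == []
        with pytest.raises(ValueError, match="needs >= 3"):
            zero_mean_error(OptimizationGroup("X", Method.SHAMMAS,
                                              _eyes(2, "X"), 118.4))


class TestZeroMeanError:
    def _noiseless_group(self, method=Method.SHAMMAS, true_a=118.4, n=6):
        eyes = _eyes(n, "M", a_const=118.4)
        for e in eyes:
            e.p_iol = 18.5
            e.se_post = predict(method, e, true_a).se_pred
        return OptimizationGroup("M", method, eyes, 118.4)

    def test_fixed_point_constant_unchanged(self):
        g = self._noiseless_group(true_a=118.4)
        zero_mean_error(g)
        assert g.optimized_constant == pytest.approx(118.4, abs=1e-6)
        assert g.provenance == "optimized"

    @pytest.mark.parametrize("method", [Method.SHAMMAS, Method.ALMA, Method.JIN])
    @pytest.mark.parametrize("true_a", [116.4, 118.4, 120.4])
    def test_recovers_generating_constant(self, method, true_a):
        """Noise-free construction guarantees the root; initialized 2 units off."""
        g = self._noiseless_group(method=method, true_a=true_a)
        g.initial_constant = true_a - 2.0
        zero_mean_error(g)
        assert g.optimized_constant == pytest.approx(true_a, abs=1e-3)
        assert abs(g.achieved_me) <= ME_TOLERANCE

    def test_me_after_never_worse_than_before(self, seeded_cohort):
        records, _ = seeded_cohort
        _, groups, _ = optimize_all(records, [Method.KIM])
        for g in groups:
            before = np.mean([e.se_post - predict(g.method, e, g.initial_constant).se_pred
                              for e in g.eyes])
            assert abs(g.achieved_me) <= abs(before) + 1e-12

    def test_zeroing_is_locally_affine_per_eye(self, seeded_cohort):
        """Each eye's PE moves by its own local sensitivity dSE/dA times the
        constant shift (the prediction is locally affine in the constant);
        the shift is not uniform across eyes because the sensitivity varies
        with biometry, but the group mean lands on zero."""
        records, _ = seeded_cohort
        _, groups, _ = optimize_all(records, [Method.SHAMMAS])
        g = max(groups, key=lambda g: g.n)
        da = g.optimized_constant - g.initial_constant
        pre = np.array([e.se_post - predict(g.method, e, g.initial_constant).se_pred
                        for e in g.eyes])
        post = np.array([e.se_post - predict(g.method, e, g.optimized_constant).se_pred
                         for e in g.eyes])
        eps = 1e-4
        mid = (g.initial_constant + g.optimized_constant) / 2
        slope = np.array([
            (predict(g.method, e, mid + eps).se_pred
             - predict(g.method, e, mid - eps).se_pred) / (2 * eps)
            for e in g.eyes])
        assert np.allclose(post, pre - slope * da, atol=2e-3)
        assert abs(post.mean()) <= ME_TOLERANCE

    def test_determinism(self, seeded_cohort):
        records, _ = seeded_cohort
        c1, _, _ = optimize_all(records, [Method.ALMA])
        c2, _, _ = optimize_all(records, [Method.ALMA])
        assert c1.to_frame().equals(c2.to_frame())


class TestExternalOptimization:
    def test_grid_search_zeroes_me(self):
        eyes = _eyes(5, "M", p_iol=19.0)
        table = synthetic_barrett_table(eyes, np.arange(116.0, 122.01, 0.5))
        ext = ExternalPredictions(table)
        for e in eyes:  # truth: the surrogate itself at A = 119.3
            e.se_post = ext.lookup(e.eye_id, 119.3)
        g = OptimizationGroup("M", Method.BARRETT_TK, eyes, 118.4)
        zero_mean_error(g, ext)
        assert g.provenance == "optimized"
        assert g.optimized_constant == pytest.approx(119.3, abs=0.011)
        assert abs(g.achieved_me) < 0.01

    def test_single_constant_degrades_to_offset(self):
        eyes = _eyes(4, "M", p_iol=19.0)
        table = synthetic_barrett_table(eyes, [119.0])
        ext = ExternalPredictions(table)
        for e in eyes:
            e.se_post = ext.lookup(e.eye_id, 119.0) + 0.4
        g = OptimizationGroup("M", Method.BARRETT_TK, eyes, 119.0)
        zero_mean_error(g, ext)
        assert g.provenance == "offset_optimized"
        assert g.offset == pytest.approx(0.4, abs=1e-12)
        assert g.achieved_me == 0.0


class TestApplyConstants:
    def test_manufacturer_mode_equals_raw_sweep(self, seeded_cohort):
        records, _ = seeded_cohort
        frame = apply_constants(records, [Method.KIM], constant_set=None)
        for row, r in zip(frame.itertuples(), records):
            assert row.predicted_se_d == predict(Method.KIM, r, r.a_const).se_pred
            assert row.provenance == "manufacturer"

    def test_optimized_groups_have_zero_me(self, seeded_cohort):
        records, _ = seeded_cohort
        constants, groups, excl = optimize_all(records)
        eligible = [r for r in records if r.eye_id not in excl]
        frame = apply_constants(eligible, [g.method for g in groups[:1]] and
                                [Method.SHAMMAS, Method.ALMA], constants)
        by = frame.merge(
            pd.DataFrame({"eye_id": [r.eye_id for r in eligible],
                          "iol_model": [r.iol_model for r in eligible]}),
            on="eye_id")
        for (_, _), grp in by.groupby(["iol_model", "method"]):
            assert abs(grp["pe_d"].mean()) <= ME_TOLERANCE + 1e-9

    def test_unknown_model_falls_back_to_manufacturer(self, seeded_cohort):
        records, _ = seeded_cohort
        constants, _, _ = optimize_all(records)
        unknown = [r for r in records if r.iol_model == "UNKNOWN"]
        frame = apply_constants(unknown, [Method.KIM], constants)
        assert (frame["provenance"] == "manufacturer").all()
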