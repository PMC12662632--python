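"""Sensitivity profiles, shape closed forms, information criteria, and
model comparison."""

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, strategies as st

from expectprofile.shapes import (PROFILE_DISTANCES, SensitivityProfile,
                                  eval_gaussian, eval_mexican, aicc, bic,
                                  lr_bf, fit_shape, compare_shapes,
                                  compute_ds, ds_table, ShapeFit)


class TestClosedForms:
    def test_gaussian_peak_value(self):
        assert eval_gaussian(0.0, 0.0, 1.0, 2.0) == pytest.approx(
            2.0 / (2.0 * np.sqrt(2 * np.pi)))

    def test_mexican_zero_crossings_at_width(self):
        for m in (1.0, 7.0, 15.0):
            assert eval_mexican(m, 0.0, 3.0, m) == pytest.approx(0.0, abs=1e-12)
            assert eval_mexican(-m, 0.0, 3.0, m) == pytest.approx(0.0, abs=1e-12)

    def test_mexican_peak_against_sympy(self):
        # 2H / (sqrt(3m) pi^(1/4)) at x = 0, H = m = 1
        exact = float(2 / (sympy.sqrt(3) * sympy.pi ** sympy.Rational(1, 4)))
        assert eval_mexican(0.0, 0.0, 1.0, 1.0) == pytest.approx(exact, abs=1e-12)

    @given(x=st.floats(-50, 50), y0=st.floats(-2, 2), a=st.floats(-30, 30),
           w=st.floats(0.5, 60))
    def test_gaussian_matches_arbitrary_precision(self, x, y0, a, w):
        xs, y0s, as_, ws = (sympy.Float(v, 30) for v in (x, y0, a, w))
        exact = y0s + 2 * as_ / (ws * sympy.sqrt(2 * sympy.pi)) \
            * sympy.exp(-2 * (xs / ws) ** 2)
        assert eval_gaussian(x, y0, a, w) == pytest.approx(float(exact), abs=1e-8)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            eval_gaussian(0.0, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            eval_mexican(0.0, 0.0, 1.0, -1.0)


class TestInformationCriteria:
    def test_hand_computable_point(self):
        # rss = n makes the log term vanish
        assert aicc(5.0, 5, 3) == pytest.approx(30.0)
        assert bic(5.0, 5, 3) == pytest.approx(3 * np.log(5.0))

    @given(rss=st.floats(1e-3, 1e3), n=st.integers(5, 100),
           k=st.integers(1, 3))
    def test_match_arbitrary_precision_oracle(self, rss, n, k):
        rs = sympy.Float(rss, 30)
        exact_aicc = n * sympy.log(rs / n) + 2 * k + sympy.Rational(
            2 * k * (k + 1), n - k - 1)
        exact_bic = n * sympy.log(rs / n) + k * sympy.log(n)
        assert aicc(rss, n, k) == pytest.approx(float(exact_aicc), abs=1e-8)
        assert bic(rss, n, k) == pytest.approx(float(exact_bic), abs=1e-8)

    @given(n=st.integers(5, 50), k=st.integers(1, 3),
           rss=st.floats(0.01, 10), factor=st.floats(1.01, 10))
    def test_monotone_decreasing_in_rss(self, n, k, rss, factor):
        assert aicc(rss, n, k) < aicc(rss * factor, n, k)
        assert bic(rss, n, k) < bic(rss * factor, n, k)

    def test_undefined_correction_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 4, 3)


def _fit(values, model="mexican", **kw):
    prof = SensitivityProfile(PROFILE_DISTANCES, np.asarray(values), "OD")
    return fit_shape(prof, model, **kw)


class TestEvidenceRatios:
    def mk(self, aicc_v, bic_v, n=5):
        return ShapeFit("gaussian", {}, 1.0, n, 3, aicc_v, bic_v, 0.5)

    def test_equal_criteria_give_unit_ratio(self):
        lr, bf = lr_bf(self.mk(10.0, 12.0), self.mk(10.0, 12.0))
        assert lr == pytest.approx(1.0) and bf == pytest.approx(1.0)

    def test_two_point_gap_gives_e(self):
        lr, _ = lr_bf(self.mk(12.0, 0.0), self.mk(10.0, 0.0))
        assert lr == pytest.approx(np.e)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            lr_bf(self.mk(1.0, 1.0, n=5), self.mk(1.0, 1.0, n=6))


class TestShapeFitting:
    def test_recovers_exact_mexican_data(self):
        truth = dict(y1=0.1, big_h=1.5, m=15.0)
        y = eval_mexican(PROFILE_DISTANCES, **truth)
        fit = _fit(y, "mexican")
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.params["m"] == pytest.approx(15.0, rel=1e-3)
        assert fit.params["big_h"] == pytest.approx(1.5, rel=1e-3)

    def test_constant_profile_fit_by_flat_gaussian(self):
        fit = _fit(np.full(5, 0.37), "gaussian")
        assert fit.rss == pytest.approx(0.0, abs=1e-10)
        assert fit.params["a"] == pytest.approx(0.0, abs=1e-4)

    def test_invariant_to_point_order(self):
        y = eval_mexican(PROFILE_DISTANCES, 0.0, 1.0, 12.0) \
            + np.array([0.05, -0.02, 0.01, 0.03, -0.04])
        f1 = _fit(y)
        perm = np.array([3, 0, 4, 2, 1])
        prof = SensitivityProfile(PROFILE_DISTANCES[perm], y[perm], "OD")
        f2 = fit_shape(prof, "mexican")
        assert f1.rss == pytest.approx(f2.rss, rel=1e-6)

    def test_offset_shifts_only_the_offset_parameter(self):
        y = eval_mexican(PROFILE_DISTANCES, 0.0, 1.0, 12.0)
        f1 = _fit(y)
        f2 = _fit(y + 2.5)
        assert f2.params["y1"] - f1.params["y1"] == pytest.approx(2.5, abs=1e-4)
        assert f2.params["m"] == pytest.approx(f1.params["m"], rel=1e-4)

    def test_center_surround_data_favor_mexican(self):
        y = np.array([0.8, 0.14, -0.36, -0.16, -0.02])
        prof = SensitivityProfile(PROFILE_DISTANCES, y, "OD")
        comp = compare_shapes(prof)
        assert comp["lr"] > 1.0 and comp["bf"] > 1.0
        assert comp["favored"] == "mexican"


class TestComputeDS:
    def test_subtraction_and_pooling(self, fast_cohort):
        prof = compute_ds(fast_cohort, "OD")
        assert list(prof.distances) == list(PROFILE_DISTANCES)
        tidy = ds_table(fast_cohort, "OD")
        manual = tidy.groupby("distance").ds.mean()
        assert np.allclose(prof.ds, manual.loc[PROFILE_DISTANCES])

    def test_identical_phases_give_zero_ds(self):
        rows = []
        for pid in ("P0", "P1"):
            for cond, phase in (("B20", "baseline"), ("E20", "main"),
                                ("B70", "baseline"), ("E70", "main")):
                anchor = 20.0 if "20" in cond else 70.0
                orients = np.arange(20.0, 71.0, 10.0)
                for o in orients:
                    d = abs(o - anchor)
                    if phase == "main" and d > 40:
                        continue
                    rows.append({"participant": pid, "task": "OD",
                                 "phase": phase, "condition": cond,
                                 "orientation": o, "distance": d, "dt": 3.0})
        table = pd.DataFrame(rows)
        prof = compute_ds(table, "OD")
        assert np.allclose(prof.ds, 0.0)

    def test_missing_condition_error_names_the_hole(self, fast_cohort):
        broken = fast_cohort[~((fast_cohort.phase == "main")
                               & (fast_cohort.distance == 30.0)
                               & (fast_cohort.participant == "P01"))]
        with pytest.raises(ValueError, match="P01"):
            compute_ds(broken, "OD")
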