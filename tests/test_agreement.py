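"""Regression and Bland-Altman statistics against hand-computed values and
the arithmetic identities of the limits-of-agreement construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qctstiff import (bland_altman, cohort_agreement, fit_regression,
                      limits_from_bias_and_upper)
from qctstiff.errors import AgreementError, IncompleteCohortError


class TestFitRegression:
    def test_identity_series(self):
        x = np.arange(1.0, 8.0)
        r = fit_regression(x, x)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope_vs_unity_p == pytest.approx(1.0)

    def test_exact_affine_series(self):
        x = np.arange(1.0, 8.0)
        r = fit_regression(x, 2 * x + 3)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(3.0)
        np.testing.assert_allclose(r.residuals, 0.0, atol=1e-10)

    def test_three_point_hand_ols(self):
        # x=(1,2,3), y=(2,2,4): slope 1, intercept 2/3, r^2 = 0.75
        r = fit_regression([1, 2, 3], [2, 2, 4])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(2.0 / 3.0)
        assert r.r_squared == pytest.approx(0.75)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 25)
        y = 1.5 * x + rng.normal(0, 2, 25)
        r = fit_regression(x, y)
        scale = np.abs(r.residuals).sum()
        assert abs(r.residuals.sum()) <= 1e-9 * max(scale, 1.0)
        assert 0.0 <= r.shapiro_p <= 1.0
        assert r.max_cooks_d >= 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(AgreementError):
            fit_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(AgreementError):
            fit_regression([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0.0
        assert r.upper_limit == 0.0 and r.lower_limit == 0.0
        assert r.percent_error == 0.0

    def test_hand_arithmetic(self):
        # d = (10, 14): bias 12, sd = 2*sqrt(2), limits 12 -+ 1.96*sd
        r = bland_altman([100.0, 120.0], [110.0, 134.0])
        assert r.mean_difference == pytest.approx(12.0)
        assert r.sd_difference == pytest.approx(2.0 * np.sqrt(2.0))
        assert r.upper_limit == pytest.approx(12.0 + 5.543717, abs=1e-5)
        assert r.lower_limit == pytest.approx(12.0 - 5.543717, abs=1e-5)

    def test_limits_identity_from_reported_pairs(self):
        """bias and upper limit determine the lower limit: lower = 2b - u."""
        sd, lower = limits_from_bias_and_upper(13.08, 37.60)
        assert lower == pytest.approx(-11.44, abs=5e-3)
        sd, lower = limits_from_bias_and_upper(65.90, 296.81)
        assert lower == pytest.approx(-165.01, abs=5e-3)

    def test_constant_offset_percent_error(self):
        ref = np.array([100.0, 200.0, 300.0])
        r = bland_altman(ref, ref + 20.0)
        assert r.mean_difference == pytest.approx(20.0)
        assert r.sd_difference == pytest.approx(0.0, abs=1e-12)
        assert r.percent_error == pytest.approx(100.0 * 20.0 / 200.0)

    def test_zero_reference_mean_signaled(self):
        with pytest.raises(AgreementError):
            bland_altman([-1.0, 1.0], [0.0, 2.0])

    def test_heteroscedasticity_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(100, 300, 30)
        test = ref + rng.normal(0, 5, 30) * (ref / 200)
        r = bland_altman(ref, test)
        assert 0.0 <= r.heteroscedasticity_p <= 1.0


@settings(deadline=None, max_examples=25)
@given(st.lists(st.tuples(st.floats(50, 500), st.floats(50, 500)),
                min_size=3, max_size=12))
def test_bland_altman_antisymmetry(pairs):
    ref = np.array([p[0] for p in pairs])
    tst = np.array([p[1] for p in pairs])
    a = bland_altman(ref, tst)
    b = bland_altman(tst, ref)
    assert a.mean_difference == pytest.approx(-b.mean_difference, abs=1e-9)
    assert a.upper_limit == pytest.approx(-b.lower_limit, abs=1e-9)
    assert a.lower_limit == pytest.approx(-b.upper_limit, abs=1e-9)
    # limits identity holds exactly by construction
    assert a.upper_limit == pytest.approx(
        a.mean_difference + 1.96 * a.sd_difference)


class TestCohortAgreement:
    @staticmethod
    def _tables(n=8, offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(100, 300, n)
        rows_v, rows_s = [], []
        for i, v in enumerate(base):
            sid = f"S{i:03d}"
            for m in ("PHANTOM", "AAdC", "AAdCM", "ACM"):
                shift = 0.0 if m == "PHANTOM" else offset
                rows_v.append({"specimen_id": sid, "method": m,
                               "vbmd": v + shift})
                rows_s.append({"specimen_id": sid, "method": m,
                               "stiffness_mpa": 8.0 * (v + shift)})
        return pd.DataFrame(rows_v), pd.DataFrame(rows_s)

    def test_identical_methods_zero_bias_unit_r2(self):
        vb, st_ = self._tables()
        agr = cohort_agreement(vb, st_)
        for rep in agr.reports:
            assert rep.bland_altman.mean_difference == pytest.approx(0.0)
            assert rep.regression.r_squared == pytest.approx(1.0)

    def test_report_and_regression_counts(self):
        vb, st_ = self._tables()
        agr = cohort_agreement(vb, st_)
        assert len(agr.reports) == 6           # 3 methods x 2 measures
        assert len(agr.vbmd_stiffness) == 4    # 3 internal + phantom

    def test_injected_offset_recovered_as_bias(self):
        vb, st_ = self._tables(offset=10.0)
        agr = cohort_agreement(vb, st_)
        for rep in agr.reports:
            if rep.measure == "vbmd":
                assert rep.bland_altman.mean_difference == pytest.approx(10.0)

    def test_missing_cell_rejected(self):
        vb, st_ = self._tables()
        with pytest.raises(IncompleteCohortError):
            cohort_agreement(vb.iloc[:-1], st_)


def test_plots_write_files(tmp_path):
    from qctstiff.agreement import plot_bland_altman, plot_regression

    ref = np.linspace(100, 300, 10)
    tst = ref * 1.05 + 3
    ba = bland_altman(ref, tst)
    reg = fit_regression(ref, tst)
    plot_bland_altman(ba, ref, tst, tmp_path / "ba.png", "vbmd")
    plot_regression(ref, tst, reg, tmp_path / "reg.png", "vbmd")
    assert (tmp_path / "ba.png").stat().st_size > 0
    assert (tmp_path / "reg.png").stat().st_size > 0
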