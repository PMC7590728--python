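import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epiclock.evaluate import (
    PredictionResult,
    accuracy_mad,
    bootstrap_r_ci,
    compare_groups_eaa,
    compute_eaa,
    evaluate_predictions,
    fisher_z,
    fisher_z_inverse,
    precision_r,
    predict_age,
)
from epiclock.io import ClockModel
from .conftest import make_beta_matrix


def _pred(dnam, chron, ids=None):
    return PredictionResult.from_ages(dnam, chron, ids)


class TestPredictAge:
    def test_one_term_arithmetic(self):
        model = ClockModel(30.0, {"cg000": 10.0})
        bm = make_beta_matrix([[0.5], [0.1]])
        pred = predict_age(model, bm)
        assert pred.dnam_age.tolist() == [35.0, 31.0]

    def test_intercept_only_clock(self):
        model = ClockModel(47.5, {})
        bm = make_beta_matrix([[0.5, 0.2], [0.1, 0.9]])
        assert predict_age(model, bm).dnam_age.tolist() == [47.5, 47.5]

    def test_extra_probes_and_order_are_irrelevant(self):
        model = ClockModel(10.0, {"cg001": 5.0})
        a = make_beta_matrix([[0.3, 0.4, 0.8]])
        b = a.select_probes(["cg002", "cg001", "cg000"])
        assert predict_age(model, a).dnam_age.tolist() == predict_age(model, b).dnam_age.tolist()

    def test_linearity_in_model_terms(self):
        model = ClockModel(10.0, {"cg000": 8.0, "cg001": -4.0})
        lo = make_beta_matrix([[0.2, 0.3]])
        hi = make_beta_matrix([[0.4, 0.6]])  # doubled betas
        contrib_lo = predict_age(model, lo).dnam_age.iloc[0] - 10.0
        contrib_hi = predict_age(model, hi).dnam_age.iloc[0] - 10.0
        assert contrib_hi == pytest.approx(2 * contrib_lo)

    def test_missing_probe_policies(self):
        model = ClockModel(
            0.0, {"cg000": 10.0, "cgZZZ": 2.0},
            provenance={"probe_means": {"cg000": 0.5, "cgZZZ": 0.25}},
        )
        bm = make_beta_matrix([[0.5, 0.1]])
        with pytest.raises(ValueError, match="cgZZZ"):
            predict_age(model, bm, missing_policy="error")
        by_mean = predict_age(model, bm, missing_policy="impute_stored_means")
        assert by_mean.dnam_age.iloc[0] == pytest.approx(0.5 * 10 + 0.25 * 2)
        by_half = predict_age(model, bm, missing_policy="impute_half")
        assert by_half.dnam_age.iloc[0] == pytest.approx(0.5 * 10 + 0.5 * 2)

    def test_residual_sign_convention(self):
        pred = _pred([50.0, 30.0], [40.0, 40.0])
        assert pred.residual.tolist() == [10.0, -10.0]


class TestAccuracyMad:
    @pytest.mark.parametrize("residuals,expected", [
        ([1.0, -1.0, 3.0], 1.0),
        ([0.0, 0.0], 0.0),
        ([2.0, -4.0], 3.0),  # even n: midpoint of order statistics
    ])
    def test_hand_fixtures(self, residuals, expected):
        chron = np.full(len(residuals), 40.0)
        pred = _pred(chron + np.asarray(residuals), chron)
        assert accuracy_mad(pred) == expected

    def test_permutation_invariance(self):
        chron = np.array([20.0, 30, 40, 50])
        res = np.array([1.0, -2, 0.5, 4])
        a = accuracy_mad(_pred(chron + res, chron))
        b = accuracy_mad(_pred((chron + res)[::-1], chron[::-1]))
        assert a == b


class TestPrecisionR:
    def test_perfect_and_offset_prediction(self):
        chron = np.array([20.0, 30, 40, 55])
        assert precision_r(_pred(chron, chron)) == pytest.approx(1.0)
        assert precision_r(_pred(chron + 2, chron)) == pytest.approx(1.0)

    def test_four_point_textbook_formula(self):
        x = np.array([1.0, 2, 3, 5])
        y = np.array([2.0, 2.5, 4, 4.5])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert precision_r(_pred(y, x)) == pytest.approx(num / den, abs=1e-12)

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(20, 60, 30)
        y = x + rng.normal(0, 3, 30)
        r = precision_r(_pred(y, x))
        assert precision_r(_pred(3 * y + 7, x)) == pytest.approx(r, abs=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError):
            precision_r(_pred([40.0, 40, 40], [20.0, 30, 40]))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_known_value(self):
        assert fisher_z(0.95) == pytest.approx(np.arctanh(0.95), abs=1e-4)
        assert fisher_z(0.95) == pytest.approx(1.8318, abs=1e-4)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(deadline=None)
    def test_round_trip(self, r):
        assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestBootstrapCI:
    def test_collinear_data_collapses_to_one(self):
        chron = np.linspace(20, 60, 20)
        lo, hi = bootstrap_r_ci(_pred(chron * 1.1 + 2, chron), n_boot=50, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_interval_contains_resample_median_and_is_tight_at_high_r(self):
        rng = np.random.default_rng(42)
        n = 200
        chron = rng.uniform(20, 70, n)
        dnam = chron + rng.normal(0, chron.std() * 0.33, n)  # true r ~ 0.95
        pred = _pred(dnam, chron)
        lo, hi = bootstrap_r_ci(pred, n_boot=1000, seed=7)
        r = precision_r(pred)
        assert lo < r < hi
        assert hi - lo < 0.04

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        chron = rng.uniform(20, 60, 30)
        pred = _pred(chron + rng.normal(0, 2, 30), chron)
        assert bootstrap_r_ci(pred, n_boot=100, seed=5) == bootstrap_r_ci(pred, n_boot=100, seed=5)


class TestComputeEAA:
    def test_perfect_prediction_gives_zero_eaa_under_every_method(self):
        chron = np.linspace(20, 80, 40)
        pred = _pred(chron, chron)
        for method in ("linear", "smoothing_spline", "piecewise_cubic"):
            eaa = compute_eaa(pred, method)
            assert np.allclose(eaa.eaa, 0.0, atol=1e-8)

    def test_linear_eaa_orthogonality(self):
        rng = np.random.default_rng(1)
        chron = rng.uniform(20, 70, 100)
        pred = _pred(chron + rng.normal(0, 3, 100), chron)
        eaa = compute_eaa(pred, "linear")
        assert abs(eaa.eaa.mean()) < 1e-10
        assert abs(eaa.diagnostic_cor) < 1e-10

    def test_linear_eaa_equals_normal_equations_residuals(self):
        rng = np.random.default_rng(2)
        chron = rng.uniform(20, 70, 50)
        dnam = chron + rng.normal(0, 2, 50)
        pred = _pred(dnam, chron)
        eaa = compute_eaa(pred, "linear")
        A = np.column_stack([np.ones(50), chron])
        coef = np.linalg.solve(A.T @ A, A.T @ dnam)
        assert np.allclose(eaa.eaa, dnam - A @ coef, atol=1e-10)

    def test_spline_removes_old_age_flattening_bias(self):
        rng = np.random.default_rng(8)
        chron = np.sort(rng.uniform(20, 88, 300))
        dnam = np.where(chron < 65, chron, 65 + 0.3 * (chron - 65))
        dnam = dnam + rng.normal(0, 1.0, 300)
        pred = _pred(dnam, chron)
        lin = compute_eaa(pred, "linear")
        spl = compute_eaa(pred, "smoothing_spline")
        # whole-sample Pearson cor is ~0 for the linear method by OLS
        # orthogonality; the bias shows as residual age dependence in the
        # old stratum, which the spline calibration removes
        old = chron > 65
        lin_old = np.corrcoef(lin.eaa[old], chron[old])[0, 1]
        spl_old = np.corrcoef(spl.eaa[old], chron[old])[0, 1]
        assert abs(lin_old) > 0.5
        assert abs(spl_old) < abs(lin_old)

    def test_piecewise_cubic_keeps_knot_and_absorbs_kink(self):
        rng = np.random.default_rng(9)
        chron = np.sort(rng.uniform(20, 88, 300))
        dnam = np.where(chron < 70, chron, 70 + 0.4 * (chron - 70))
        pred = _pred(dnam + rng.normal(0, 0.5, 300), chron)
        pc = compute_eaa(pred, "piecewise_cubic", knot=70.0)
        lin = compute_eaa(pred, "linear")
        assert pc.knot == 70.0
        old = chron > 70
        pc_old = np.corrcoef(pc.eaa[old], chron[old])[0, 1]
        lin_old = np.corrcoef(lin.eaa[old], chron[old])[0, 1]
        assert abs(pc_old) < abs(lin_old)

    def test_knot_outside_range_warns_but_fits(self):
        chron = np.linspace(20, 40, 30)
        pred = _pred(chron + 1, chron)
        with pytest.warns(UserWarning, match="knot"):
            compute_eaa(pred, "piecewise_cubic", knot=70.0)

    def test_reverse_direction_swaps_regression(self):
        rng = np.random.default_rng(4)
        chron = rng.uniform(20, 70, 60)
        pred = _pred(chron + rng.normal(0, 4, 60), chron)
        fwd = compute_eaa(pred, "linear")
        rev = compute_eaa(pred, "linear", direction="reverse")
        assert not np.allclose(fwd.eaa, rev.eaa)


class TestCompareGroups:
    def test_identical_multisets_give_zero_difference(self):
        from epiclock.evaluate import EAAResult

        vals = [1.0, -1.0, 4.0, -4.0] * 2  # same multiset in both groups
        eaa = EAAResult(eaa=pd.Series(vals, index=list("abcdefgh")),
                        method="linear", knot=None, diagnostic_cor=0.0)
        groups = pd.Series(["x"] * 4 + ["y"] * 4, index=eaa.eaa.index)
        comp = compare_groups_eaa(eaa, groups, reference="x")
        assert comp.mean_difference == pytest.approx(0.0, abs=1e-12)

    def test_welch_statistic_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        vals = np.concatenate([a, b])
        from epiclock.evaluate import EAAResult

        eaa = EAAResult(
            eaa=pd.Series(vals, index=list("abcdef")),
            method="linear", knot=None, diagnostic_cor=0.0,
        )
        groups = pd.Series(["ref"] * 3 + ["cmp"] * 3, index=list("abcdef"))
        comp = compare_groups_eaa(eaa, groups, reference="ref")
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (b.mean() - a.mean()) / se
        df = se ** 4 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert comp.mean_difference == pytest.approx(b.mean() - a.mean(), abs=1e-10)
        assert comp.p_value == pytest.approx(p, abs=1e-10)
        assert comp.ci[0] <= comp.mean_difference <= comp.ci[1]

    def test_more_than_two_groups_rejected(self):
        from epiclock.evaluate import EAAResult

        eaa = EAAResult(eaa=pd.Series([1.0, 2, 3], index=list("abc")),
                        method="linear", knot=None, diagnostic_cor=0.0)
        with pytest.raises(ValueError, match="two"):
            compare_groups_eaa(eaa, pd.Series(["x", "y", "z"], index=list("abc")), "x")


class TestEvaluationReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(0)
        chron = rng.uniform(20, 70, 50)
        pred = _pred(chron + rng.normal(0, 2, 50), chron)
        rep = evaluate_predictions(pred, n_boot=200, seed=1)
        assert rep.r_ci[0] <= rep.r <= rep.r_ci[1]
        assert rep.mad >= 0 and rep.n == 50
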