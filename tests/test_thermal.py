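import numpy as np
import pytest
from scipy import stats

from thermomri import synth
from thermomri.thermal import (
    LinearTempModel,
    compare_fit_variants,
    correct_to_temperature,
    delta_double_star,
    delta_star,
    fit_all_models,
    fit_linear_model,
    model_from_coefficients,
    predict_at,
)


def closed_form_ols(y, x):
    """Normal-equation OLS with t-based 95% CIs, adjusted R^2 and slope p."""
    n = len(y)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    b = np.sum((x - xbar) * (y - ybar)) / sxx
    a = ybar - b * xbar
    resid = y - (a + b * x)
    s2 = np.sum(resid ** 2) / (n - 2)
    se_b = np.sqrt(s2 / sxx)
    se_a = np.sqrt(s2 * (1 / n + xbar ** 2 / sxx))
    tcrit = stats.t.ppf(0.975, n - 2)
    ss_tot = np.sum((y - ybar) ** 2)
    r2 = 1 - np.sum(resid ** 2) / ss_tot
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    tstat = b / se_b
    p = 2 * stats.t.sf(abs(tstat), n - 2)
    return a, b, tcrit * se_a, tcrit * se_b, r2_adj, p


def _model(a, b, region="white_matter", parameter="T2", invivo=False):
    return LinearTempModel(a, b, 0.0, 0.0, 1.0, 0.01, 16, invivo, region, parameter)


class TestFitLinearModel:
    def test_exact_line(self):
        x = np.linspace(5, 30, 16)
        y = 100.0 - 0.5 * x
        m = fit_linear_model(y, x, includes_invivo=False)
        assert m.intercept_a == pytest.approx(100.0, abs=1e-9)
        assert m.slope_b == pytest.approx(-0.5, abs=1e-12)
        assert m.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert m.ci_a == pytest.approx(0.0, abs=1e-6)
        assert m.ci_b == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_normal_equations(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            x = rng.uniform(4, 37, n)
            y = rng.normal(100, 10, n) + rng.uniform(-2, 2) * x
            m = fit_linear_model(y, x, includes_invivo=False)
            a, b, ci_a, ci_b, r2_adj, p = closed_form_ols(y, x)
            assert m.intercept_a == pytest.approx(a, abs=1e-10)
            assert m.slope_b == pytest.approx(b, abs=1e-10)
            assert m.ci_a == pytest.approx(ci_a, abs=1e-10)
            assert m.ci_b == pytest.approx(ci_b, abs=1e-10)
            assert m.r2_adj == pytest.approx(r2_adj, abs=1e-10)
            assert m.p_value == pytest.approx(p, abs=1e-10)

    def test_pure_noise_gives_negative_adjusted_r2_in_expectation(self):
        rng = np.random.default_rng(77)
        r2s = []
        for _ in range(200):
            x = rng.uniform(5, 28, 16)
            y = rng.normal(0, 1, 16)
            r2s.append(fit_linear_model(y, x, False).r2_adj)
        assert np.mean(r2s) < 0.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_model(np.array([1.0, 2.0, 3.0]), np.full(3, 10.0), False)


class TestPredictAndDeltas:
    def test_predict_at_zero_is_intercept(self):
        assert predict_at(_model(123.4, -0.7), 0.0) == 123.4

    def test_putamen_t1_prediction_at_invivo(self, table):
        m = model_from_coefficients("putamen", "T1", "without_invivo", table)
        assert predict_at(m, 36.5) == pytest.approx(500.6 + 6.5 * 36.5, rel=1e-12)

    def test_zero_slope_constant_prediction(self):
        m = _model(50.0, 0.0)
        assert predict_at(m, 4.0) == predict_at(m, 36.5) == 50.0

    def test_delta_star_zero_when_prediction_matches(self):
        m = _model(100.0, 0.0)
        assert delta_star(m, 100.0) == 0.0

    def test_delta_star_arithmetic(self):
        # prediction 610.7 vs in vivo mean 600 -> +1.78%
        m = _model(610.7, 0.0)
        assert delta_star(m, 600.0) == pytest.approx(100 * (610.7 - 600) / 600, rel=1e-12)
        assert delta_star(m, 600.0) == pytest.approx(1.78, abs=0.005)

    def test_delta_star_half_prediction(self):
        m = _model(50.0, 0.0)
        assert delta_star(m, 100.0) == -50.0

    def test_delta_star_requires_post_mortem_fit(self):
        with pytest.raises(ValueError):
            delta_star(_model(100, 0, invivo=True), 100.0)

    def test_delta_double_star_zero_slope(self):
        assert delta_double_star(_model(80.0, 0.0)) == 0.0

    @pytest.mark.parametrize("region,parameter,a,b,printed", [
        ("putamen", "T1", 500.6, 6.5, -28.6),
        ("putamen", "MD", 1.2e-4, 5.1e-6, -54.1),
    ])
    def test_delta_double_star_published_rows(self, region, parameter, a, b, printed):
        m = _model(a, b, region, parameter)
        assert delta_double_star(m) == pytest.approx(printed, abs=0.1)

    def test_delta_double_star_scale_invariant(self):
        m1 = _model(1.2e-4, 5.1e-6)
        m2 = _model(1.2e-4 * 1e6, 5.1e-6 * 1e6)  # mm^2/s -> um^2/s
        assert delta_double_star(m1) == pytest.approx(delta_double_star(m2), rel=1e-12)


class TestCorrection:
    def test_no_op_at_same_temperature(self):
        m = _model(105.4, -0.6)
        assert correct_to_temperature(90.0, 20.0, 20.0, m) == 90.0

    def test_wm_t2_worked_example(self):
        m = _model(105.4, -0.6)
        got = correct_to_temperature(100.0, 10.0, 36.5, m)
        assert got == pytest.approx(100.0 + (-0.6) * 26.5, rel=1e-12)
        assert got == pytest.approx(84.1, abs=1e-9)

    def test_exact_round_trip(self):
        m = _model(105.4, -0.6)
        v = 97.3
        there = correct_to_temperature(v, 8.0, 36.5, m)
        back = correct_to_temperature(there, 36.5, 8.0, m)
        assert back == pytest.approx(v, rel=1e-15)

    def test_additive_composition(self):
        m = _model(105.4, -0.6)
        via = correct_to_temperature(correct_to_temperature(90.0, 5.0, 20.0, m), 20.0, 36.5, m)
        direct = correct_to_temperature(90.0, 5.0, 36.5, m)
        assert via == pytest.approx(direct, rel=1e-15)

    def test_reference_out_of_range_warns(self):
        m = _model(105.4, -0.6)
        with pytest.warns(UserWarning):
            correct_to_temperature(90.0, 10.0, 50.0, m)


class TestCompareFitVariants:
    def test_identical_models_zero_discrepancy(self):
        mw = _model(100.0, -0.5, invivo=True)
        mo = _model(100.0, -0.5)
        rep = compare_fit_variants(mw, mo)
        assert rep["difference"] == 0.0
        assert rep["slope_cis_overlap"]

    def test_nonoverlapping_slope_cis_flagged(self):
        mw = LinearTempModel(100, 1.0, 0.1, 0.1, 0.9, 0.01, 20, True, "putamen", "T1")
        mo = LinearTempModel(100, 2.0, 0.1, 0.1, 0.9, 0.01, 16, False, "putamen", "T1")
        assert not compare_fit_variants(mw, mo)["slope_cis_overlap"]

    def test_mismatched_models_rejected(self):
        mw = _model(1, 0, region="putamen", invivo=True)
        mo = _model(1, 0, region="thalamus")
        with pytest.raises(ValueError):
            compare_fit_variants(mw, mo)

    def test_injected_invivo_md_offset_detected(self, table):
        # post mortem MD is ~50% below the in vivo level: the without-invivo
        # extrapolation should sit ~50% under the measured in vivo mean
        _, df = synth.generate_cohort(invivo_scale={"MD": 2.0}, seed=31, coefficient_table=table)
        models = fit_all_models(df)
        md = models[(models.parameter == "MD") & (models.variant == "without_invivo")]
        mean_delta_star = md["delta_star_pct"].mean()
        assert mean_delta_star == pytest.approx(-50.0, abs=5.0)


class TestSlopeRecovery:
    def test_ci_coverage_near_nominal(self, table):
        # cohorts generated from the WM T2 post-mortem row: the generating
        # slope must fall inside the fitted 95% CI at ~95% rate
        a, b_true = 105.4, -0.6
        rng = np.random.default_rng(55)
        n, n_rep = 16, 500
        covered = 0
        for _ in range(n_rep):
            x = synth.sample_post_mortem_temperatures(n, rng=rng)
            sxx = np.sum((x - x.mean()) ** 2)
            sd = synth.residual_sd_from_ci(0.4, n, sxx)
            y = a + b_true * x + rng.normal(0, sd, n)
            m = fit_linear_model(y, x, False)
            covered += (m.slope_b - m.ci_b) <= b_true <= (m.slope_b + m.ci_b)
        assert 0.90 <= covered / n_rep <= 0.98

    def test_fitted_slope_unbiased(self, table):
        # Monte-Carlo unbiasedness of OLS on generator output (WM MD row)
        rng = np.random.default_rng(200)
        slopes = []
        for rep in range(200):
            _, df = synth.generate_cohort(n_in_vivo=0, seed=10_000 + rep,
                                          coefficient_table=table)
            sub = df[(df.region == "white_matter") & (df.parameter == "MD")]
            slopes.append(fit_linear_model(sub["mean"], sub["temperature_C"], False).slope_b)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 4.3e-6) < 3 * se
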