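"""Response-effect statistics: CWM, path models, mediation, chi-square tests."""
import numpy as np
import pandas as pd
import pytest

from traitforest.fixtures import RefDatasetParams, make_ref_dataset
from traitforest.refstats import (
    MEDIATION_PARTIAL,
    MEDIATION_SATURATED,
    chi2_difference_test,
    chi2_sf,
    cwm,
    fit_path_model,
    mediation_effects,
)

from sem_oracle import fit_sem_numeric


def mediation_data(n=200, a=0.5, b=0.5, c=0.0, seed=0):
    df = make_ref_dataset(RefDatasetParams(n=n, a=a, b=b, c=c), seed=seed)
    return df.rename(columns={"mat_c": "x", "trait": "m", "response": "y"})[["x", "m", "y"]]


class TestCwm:
    def test_equal_weights(self):
        assert cwm([1, 1], [10, 20]) == pytest.approx(15.0)

    def test_unequal_weights_hand_arithmetic(self):
        assert cwm([3, 1], [10, 20]) == pytest.approx(12.5)

    def test_against_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 5, 100)
        t = rng.normal(size=100)
        assert cwm(w, t) == pytest.approx(float(np.sum(w * t) / np.sum(w)), abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            cwm([0.0, 0.0], [1.0, 2.0])


class TestChi2Sf:
    def test_printed_worked_examples(self):
        assert chi2_sf(5.25, 2) == pytest.approx(0.072, abs=5e-4)
        assert chi2_sf(5.99, 2) == pytest.approx(0.050, abs=5e-4)

    @pytest.mark.parametrize("df", [1, 2, 5, 10])
    def test_zero_statistic_full_mass(self, df):
        assert chi2_sf(0.0, df) == 1.0

    def test_df2_closed_form_identity(self):
        for x in np.linspace(0, 30, 61):
            assert chi2_sf(x, 2) == pytest.approx(np.exp(-x / 2), abs=1e-12)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 2)


class TestFitPathModel:
    def test_saturated_model_is_just_identified(self):
        fit = fit_path_model(mediation_data(seed=3), MEDIATION_SATURATED)
        assert fit.chi_square == 0.0
        assert fit.df == 0

    def test_parameter_recovery_large_n(self):
        fit = fit_path_model(mediation_data(n=5000, seed=5), MEDIATION_SATURATED)
        for edge, truth in {("x", "m"): 0.5, ("m", "y"): 0.5, ("x", "y"): 0.0}.items():
            est, se = fit.coefficients[edge], fit.standard_errors[edge]
            assert abs(est - truth) < 2 * se

    def test_matches_per_equation_ols(self):
        """Saturated ML fit reproduces OLS of m~x and y~x+m to 1e-8."""
        d = mediation_data(n=300, c=0.3, seed=7)
        fit = fit_path_model(d, MEDIATION_SATURATED)
        z = (d - d.mean()) / d.std(ddof=1)
        bm = np.linalg.lstsq(
            np.column_stack([np.ones(len(z)), z["x"]]), z["m"], rcond=None
        )[0][1]
        by = np.linalg.lstsq(
            np.column_stack([np.ones(len(z)), z["x"], z["m"]]), z["y"], rcond=None
        )[0][1:]
        assert fit.coefficients[("x", "m")] == pytest.approx(bm, abs=1e-8)
        assert fit.coefficients[("x", "y")] == pytest.approx(by[0], abs=1e-8)
        assert fit.coefficients[("m", "y")] == pytest.approx(by[1], abs=1e-8)

    def test_restricted_chi2_positive_when_direct_path_real(self):
        d = mediation_data(n=2000, c=0.4, seed=9)
        fit = fit_path_model(d, MEDIATION_PARTIAL)
        assert fit.df == 1
        assert fit.chi_square > 10.0

    def test_singular_covariance_rejected(self):
        n = 50
        x = np.random.default_rng(0).normal(size=n)
        with pytest.raises(ValueError, match="singular|constant"):
            fit_path_model({"x": x, "m": 2 * x, "y": x}, MEDIATION_SATURATED)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            fit_path_model(mediation_data(), (("x", "m"), ("m", "x")))

    def test_agreement_with_numeric_sem_oracle(self):
        """Closed-form fits match a brute-force numerical ML fitter."""
        rng = np.random.default_rng(23)
        for rep in range(20):
            a, b, c = rng.uniform(-0.6, 0.6, size=3)
            d = mediation_data(n=150, a=a, b=b, c=c, seed=1000 + rep)
            edges = MEDIATION_SATURATED if rep % 2 == 0 else MEDIATION_PARTIAL
            fit = fit_path_model(d, edges)
            coeffs, chi2, df = fit_sem_numeric(d, edges, variables=["x", "m", "y"])
            assert df == fit.df
            for e, v in coeffs.items():
                assert fit.coefficients[e] == pytest.approx(v, abs=1e-4)
            assert fit.chi_square == pytest.approx(chi2, abs=1e-3)


class TestMediationEffects:
    def test_no_first_path_no_indirect_effect(self):
        d = mediation_data(n=500, a=0.0, b=0.5, c=0.0, seed=11)
        fit = fit_path_model(d, MEDIATION_SATURATED)
        fit.coefficients[("x", "m")] = 0.0  # exact-zero topology
        direct, indirect, total = mediation_effects(fit)
        assert indirect == 0.0

    def test_product_rule(self):
        d = mediation_data(n=4000, a=0.5, b=0.5, c=0.0, seed=13)
        fit = fit_path_model(d, MEDIATION_SATURATED)
        direct, indirect, total = mediation_effects(fit)
        assert indirect == pytest.approx(
            fit.coefficients[("x", "m")] * fit.coefficients[("m", "y")], abs=1e-12
        )
        assert total == pytest.approx(direct + indirect, abs=1e-12)
        assert indirect == pytest.approx(0.25, abs=0.06)

    def test_total_effect_equals_marginal_regression_slope(self):
        """Wright's path tracing: total effect = slope of y ~ x (standardized)."""
        d = mediation_data(n=400, a=0.4, b=0.5, c=0.2, seed=17)
        fit = fit_path_model(d, MEDIATION_SATURATED)
        _, _, total = mediation_effects(fit)
        z = (d - d.mean()) / d.std(ddof=1)
        marginal = float(np.cov(z["x"], z["y"], ddof=1)[0, 1] / np.var(z["x"], ddof=1))
        assert total == pytest.approx(marginal, abs=1e-10)


class TestChi2DifferenceTest:
    def test_identical_models_give_zero_and_p_one(self):
        d = mediation_data(seed=19)
        fit = fit_path_model(d, MEDIATION_SATURATED)
        res = chi2_difference_test(fit, fit)
        assert res.delta_chi2 == 0.0 and res.p_value == 1.0

    def test_paper_style_worked_comparison(self):
        # a restricted model at chi2=5.25 on 2 df against a saturated fit
        d = mediation_data(seed=21)
        sat = fit_path_model(d, MEDIATION_SATURATED)
        part = fit_path_model(d, MEDIATION_PARTIAL)
        res = chi2_difference_test(part, sat)
        assert res.delta_df == 1
        assert res.p_value == pytest.approx(chi2_sf(res.delta_chi2, 1), abs=1e-12)

    def test_non_nested_rejected(self):
        d = mediation_data(seed=25)
        sat = fit_path_model(d, MEDIATION_SATURATED)
        # reversed x->m edge: not a subset of the saturated edge set
        weird = fit_path_model(d, (("m", "x"), ("m", "y")))
        with pytest.raises(ValueError, match="nested"):
            chi2_difference_test(weird, sat)

    def test_type_i_error_calibration_small(self):
        """Null-true difference test rejects at ~5% (light version, 400 reps)."""
        rejections = 0
        reps = 400
        for i in range(reps):
            d = mediation_data(n=200, a=0.5, b=0.5, c=0.0, seed=50_000 + i)
            sat = fit_path_model(d, MEDIATION_SATURATED)
            part = fit_path_model(d, MEDIATION_PARTIAL)
            if chi2_difference_test(part, sat).p_value < 0.05 :
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.03  # 400-rep band; the full audit runs 2000
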