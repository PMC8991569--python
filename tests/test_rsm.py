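"""Quadratic response-surface fit, exact box maximization, surfaces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize as sciopt

from fermopt import (
    Factor,
    QuadraticModel,
    fit_quadratic,
    make_bb_design,
    maximize_over_box,
    predict,
    surface_grid,
    verification_report,
)
from fermopt.design import DesignMatrix
from fermopt.rsm import expand_model_matrix

from conftest import grid_max

PRINTED = {
    "Intercept": 0.64,
    "CaCl2": 0.13625,
    "TraceElement": 0.015,
    "Volume": 0.22875,
    "CaCl2:TraceElement": -0.045,
    "CaCl2:Volume": -0.0825,
    "TraceElement:Volume": 0.015,
    "CaCl2^2": 0.09125,
    "TraceElement^2": 0.02375,
    "Volume^2": -0.05875,
}


def _random_model(seed, k=3, scale=1.0):
    rng = np.random.default_rng(seed)
    factors = [Factor(f"X{j+1}", "coded", -1, 1) for j in range(k)]
    return QuadraticModel.from_coefficients(
        factors,
        beta0=rng.normal(0, scale),
        linear=rng.normal(0, scale, k),
        interaction_upper=rng.normal(0, scale, k * (k - 1) // 2),
        squared=rng.normal(0, scale, k),
    )


class TestFit:
    def test_intercept_and_cacl2_trace_interaction_exact(self, bb_fixture):
        model = fit_quadratic(*bb_fixture)
        assert model.beta0 == pytest.approx(0.64, abs=1e-12)
        assert model.interaction[0, 1] == pytest.approx(-0.045, abs=1e-12)
        # the interaction is a simple contrast on a Box-Behnken design
        assert model.interaction[0, 1] == pytest.approx(
            (0.44 + 0.98 - 0.59 - 1.01) / 4, abs=1e-12
        )

    def test_remaining_coefficients_near_published_model(self, bb_fixture):
        # responses are printed to 2 dp, so only +/-0.03 agreement is expected
        coef = fit_quadratic(*bb_fixture).coefficients()
        for term, ref in PRINTED.items():
            assert coef[term] == pytest.approx(ref, abs=0.03), term

    def test_r_squared_near_published_value(self, bb_fixture):
        assert fit_quadratic(*bb_fixture).r_squared == pytest.approx(0.853, abs=0.03)

    def test_matches_statsmodels_ols(self, bb_fixture):
        import statsmodels.api as sm

        design, y = bb_fixture
        res = sm.OLS(y, expand_model_matrix(design.coded)).fit()
        model = fit_quadratic(design, y)
        coef = list(model.coefficients().values())
        assert coef == pytest.approx(list(res.params), abs=1e-10)
        assert model.r_squared == pytest.approx(res.rsquared, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_noiseless_synthetic_recovery(self, seed):
        truth = _random_model(seed)
        design = make_bb_design(3, 3, factors=truth.factors)
        raw = predict(truth, design.coded.astype(float))
        shift = 0.1 - raw.min()  # yields must be positive; only the intercept moves
        recovered = fit_quadratic(design, raw + shift).coefficients()
        expected = truth.coefficients()
        expected["Intercept"] += shift
        for term in expected:
            assert recovered[term] == pytest.approx(expected[term], abs=1e-10), term

    def test_residuals_orthogonal_to_model_columns(self, bb_fixture):
        design, y = bb_fixture
        model = fit_quadratic(design, y)
        M = expand_model_matrix(design.coded)
        assert np.abs(M.T @ model.residuals).max() < 1e-10

    def test_fit_idempotent_on_own_predictions(self, bb_fixture):
        design, y = bb_fixture
        model = fit_quadratic(design, y)
        refit = fit_quadratic(design, predict(model, design.coded.astype(float)))
        a = np.array(list(model.coefficients().values()))
        b = np.array(list(refit.coefficients().values()))
        assert np.abs(a - b).max() <= 1e-10

    def test_too_few_runs_rejected(self):
        design = make_bb_design(3, 3)
        sub = DesignMatrix(design.factors, design.coded[:9])
        with pytest.raises(ValueError, match="runs"):
            fit_quadratic(sub, np.ones(9))

    def test_rank_deficiency_names_collinear_columns(self):
        design = make_bb_design(3, 3)
        coded = design.coded.copy()
        coded[:, 1] = coded[:, 0]  # duplicate factor column
        dup = DesignMatrix(design.factors, coded)
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(dup, np.ones(15))

    @given(st.integers(0, 100))
    def test_bb_contrast_identities_on_random_responses(self, seed):
        """On a Box-Behnken design, LS linear/interaction coefficients equal
        their closed-form contrasts (checked internally by fit_quadratic)."""
        design = make_bb_design(3, 3)
        y = np.random.default_rng(seed).uniform(0.1, 1.0, 15)
        model = fit_quadratic(design, y)  # raises if a contrast identity fails
        X = design.coded.astype(float)
        assert model.linear[2] == pytest.approx((X[:, 2] * y).sum() / 8, abs=1e-10)


class TestPredict:
    def test_published_model_at_its_optimum_corner(self, ref_model):
        assert predict(ref_model, [1, -1, 1]) == pytest.approx(0.99375, abs=1e-12)

    def test_origin_returns_intercept(self, ref_model):
        assert predict(ref_model, [0, 0, 0]) == pytest.approx(0.64, abs=1e-12)

    def test_term_by_term_summation(self, ref_model):
        x = np.array([0.3, -0.7, 0.5])
        expected = (
            0.64 + 0.13625 * x[0] + 0.015 * x[1] + 0.22875 * x[2]
            - 0.045 * x[0] * x[1] - 0.0825 * x[0] * x[2] + 0.015 * x[1] * x[2]
            + 0.09125 * x[0] ** 2 + 0.02375 * x[1] ** 2 - 0.05875 * x[2] ** 2
        )
        assert predict(ref_model, x) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, ref_model):
        with pytest.raises(ValueError):
            predict(ref_model, [0, 0])


class TestMaximizeOverBox:
    def test_published_model_optimum(self, ref_model):
        opt = maximize_over_box(ref_model)
        assert tuple(opt.coded_optimum) == (1, -1, 1)
        assert opt.natural_optimum == pytest.approx([1.125, 0.25, 225])
        assert round(opt.predicted_response, 3) == 0.994
        assert opt.boundary_flags.all()

    def test_concave_bowl_maximized_at_origin(self):
        factors = [Factor(f"X{j}", "", -1, 1) for j in range(3)]
        bowl = QuadraticModel.from_coefficients(
            factors, 0.0, np.zeros(3), np.zeros(3), -np.ones(3)
        )
        opt = maximize_over_box(bowl)
        assert opt.coded_optimum == pytest.approx(np.zeros(3), abs=1e-12)
        assert opt.predicted_response == pytest.approx(0.0, abs=1e-12)
        assert not opt.boundary_flags.any()

    def test_linear_model_hits_boundary(self):
        factors = [Factor(f"X{j}", "", -1, 1) for j in range(3)]
        lin = QuadraticModel.from_coefficients(
            factors, 0.0, [1.0, 0, 0], np.zeros(3), np.zeros(3)
        )
        opt = maximize_over_box(lin)
        assert opt.coded_optimum[0] == 1.0
        assert opt.predicted_response == pytest.approx(1.0)
        assert opt.boundary_flags[0]

    @pytest.mark.parametrize("seed", range(100))
    def test_dominates_fine_grid_in_two_variables(self, seed):
        model = _random_model(seed, k=2)
        exact = maximize_over_box(model).predicted_response
        approx = grid_max(model, step=0.01)
        assert exact >= approx - 1e-12
        assert exact - approx <= 1e-3  # grid resolution bound

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_multistart_numerical_solver(self, seed):
        model = _random_model(seed, k=3)
        exact = maximize_over_box(model).predicted_response
        best = -np.inf
        rng = np.random.default_rng(seed + 1)
        for trial in range(12):
            x0 = rng.uniform(-1, 1, 3)
            res = sciopt.minimize(
                lambda x: -predict(model, x),
                x0,
                bounds=[(-1, 1)] * 3,
                method="L-BFGS-B",
            )
            best = max(best, -res.fun)
        assert exact == pytest.approx(best, abs=1e-6)
        assert exact >= best - 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_dominates_random_points(self, seed):
        model = _random_model(seed + 200, k=3)
        opt = maximize_over_box(model)
        pts = np.random.default_rng(seed).uniform(-1, 1, (1000, 3))
        assert (predict(model, pts) <= opt.predicted_response + 1e-12).all()

    def test_degenerate_hessian_handled_by_face_enumeration(self):
        # flat in X2: singular quadratic part, maximum on a face boundary
        factors = [Factor(f"X{j}", "", -1, 1) for j in range(2)]
        model = QuadraticModel.from_coefficients(
            factors, 0.0, [0.0, 0.5], np.zeros(1), [-1.0, 0.0]
        )
        opt = maximize_over_box(model)
        assert opt.predicted_response == pytest.approx(0.5, abs=1e-12)
        assert opt.coded_optimum == pytest.approx([0.0, 1.0], abs=1e-9)


class TestSurfaceGrid:
    def test_published_model_peaks_at_high_cacl2_high_volume(self, ref_model):
        grid = surface_grid(ref_model, "CaCl2", "Volume")
        best = grid.loc[grid["predicted"].idxmax()]
        assert best["CaCl2_coded"] == 1.0 and best["Volume_coded"] == 1.0

    def test_constant_model_gives_flat_grid(self):
        factors = [Factor(f"X{j}", "", -1, 1) for j in range(3)]
        const = QuadraticModel.from_coefficients(
            factors, 0.42, np.zeros(3), np.zeros(3), np.zeros(3)
        )
        grid = surface_grid(const, 0, 1)
        assert (grid["predicted"] == 0.42).all()

    def test_grid_max_bounded_by_slice_maximum(self, ref_model):
        grid = surface_grid(ref_model, "CaCl2", "TraceElement")
        # restricted 2-variable quadratic with Volume fixed at 0
        sub = QuadraticModel.from_coefficients(
            ref_model.factors[:2],
            ref_model.beta0,
            ref_model.linear[:2],
            [ref_model.interaction[0, 1]],
            ref_model.squared[:2],
        )
        assert grid["predicted"].max() <= maximize_over_box(sub).predicted_response + 1e-9

    def test_natural_units_included(self, ref_model):
        grid = surface_grid(ref_model, "CaCl2", "Volume", n=5)
        assert grid["CaCl2_g/L"].max() == pytest.approx(1.125)
        assert grid["Volume_mL/500mL"].min() == pytest.approx(75)

    def test_same_factor_twice_rejected(self, ref_model):
        with pytest.raises(ValueError):
            surface_grid(ref_model, "CaCl2", "CaCl2")


class TestVerificationReport:
    def test_published_verification_numbers(self, ref_model):
        opt = maximize_over_box(ref_model)
        report = verification_report(ref_model, opt, 0.938, 0.646)
        assert report["absolute_deviation_g_per_L"] == pytest.approx(0.056, abs=5e-4)
        assert report["relative_deviation_pct"] == pytest.approx(5.6, abs=0.1)
        assert round(report["fold_change_vs_basal"], 2) == 1.45

    def test_perfect_prediction_gives_zero_deviation(self, ref_model):
        opt = maximize_over_box(ref_model)
        report = verification_report(ref_model, opt, opt.predicted_response, 0.5)
        assert report["absolute_deviation_g_per_L"] == 0.0

    def test_nonpositive_yields_rejected(self, ref_model):
        opt = maximize_over_box(ref_model)
        with pytest.raises(ValueError):
            verification_report(ref_model, opt, 0.9, 0.0)
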