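import numpy as np
import pandas as pd
import pytest

import gardenclim as gc
from gardenclim.gam import (CrsBasis, OverfitError, SmoothTermSpec,
                            build_crs_basis, select_model)


@pytest.fixture()
def x12():
    rng = np.random.default_rng(2)
    return np.sort(rng.uniform(0, 1, 12))


class TestCrsBasis:
    def test_penalty_null_space_is_linear(self, x12):
        basis = CrsBasis(np.array([0.0, 0.5, 1.0]))
        # a linear function has knot values on a line -> zero penalty
        beta = 2.0 + 3.0 * basis.knots
        assert beta @ basis.penalty @ beta == pytest.approx(0.0, abs=1e-12)
        # a kinked function is penalized
        beta = np.array([0.0, 1.0, 0.0])
        assert beta @ basis.penalty @ beta > 0

    def test_interpolates_knot_values(self):
        knots = np.array([0.0, 0.4, 1.0])
        basis = CrsBasis(knots)
        B = basis.matrix(knots)
        np.testing.assert_allclose(B, np.eye(3), atol=1e-12)

    def test_matches_scipy_natural_spline_between_knots(self):
        """The basis row times knot values reproduces the natural cubic
        interpolant of those values."""
        from scipy.interpolate import CubicSpline

        knots = np.array([0.0, 0.35, 1.0])
        vals = np.array([1.0, -0.5, 2.0])
        cs = CubicSpline(knots, vals, bc_type="natural")
        xs = np.linspace(0, 1, 33)
        B = CrsBasis(knots).matrix(xs)
        np.testing.assert_allclose(B @ vals, cs(xs), atol=1e-10)

    def test_linear_extrapolation_outside_knots(self):
        knots = np.array([0.0, 0.5, 1.0])
        basis = CrsBasis(knots)
        vals = np.array([0.0, 1.0, 0.5])
        xs = np.array([-0.5, -0.2, 1.2, 1.5])
        f = basis.matrix(xs) @ vals
        # second differences vanish on each side: linear extension
        assert (f[1] - f[0]) / 0.3 == pytest.approx(
            (basis.matrix(np.array([-0.01])) @ vals -
             basis.matrix(np.array([-0.02])) @ vals).item() / 0.01, abs=1e-6)

    def test_constrained_columns_sum_to_zero(self, x12):
        spec = SmoothTermSpec("v")
        Bz, Sz = build_crs_basis(x12, spec)
        np.testing.assert_allclose(Bz.sum(axis=0), 0.0, atol=1e-10)
        # penalty stays symmetric PSD
        np.testing.assert_allclose(Sz, Sz.T, atol=1e-12)
        assert np.linalg.eigvalsh(Sz).min() > -1e-12

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            build_crs_basis(np.array([1.0, 1.0, 2.0]), SmoothTermSpec("v"))


class TestFitGam:
    def test_noiseless_linear_is_exact_and_matches_ols(self, climate12):
        y = 1.5 + 0.25 * climate12["T_MAX"].to_numpy()
        fit = gc.fit_gam(y, climate12, ["T_MAX"])
        assert fit.deviance_explained == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(fit.predict(climate12), y, atol=1e-6)

    def test_lambda_zero_equals_direct_least_squares(self, climate12):
        rng = np.random.default_rng(5)
        y = np.sin(climate12["T_MAX"].to_numpy() / 3.0) + 0.1 * rng.standard_normal(12)
        fit = gc.fit_gam(y, climate12, ["T_MAX", "P_MA"], lambdas={"default": 0.0})
        # oracle: assemble the same design and solve unpenalized
        from gardenclim.gam import _assemble
        _, Xd, _, _, _ = _assemble(y, climate12, ["T_MAX", "P_MA"], 3)
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        np.testing.assert_allclose(Xd @ fit.coefficients, Xd @ beta, atol=1e-8)

    def test_affine_rescaling_of_covariates_is_invariant(self, climate12):
        """Knots are quantiles on an internal [0, 1] scale, so the
        constructed fit does not depend on affine reparameterisation of
        the inputs.  With fixed smoothing the predictions agree to
        floating-point accuracy; with GCV-chosen smoothing they agree
        to the flatness of the GCV ridge (the objective moves by
        < 1e-6 relative while lambda wanders, so fitted values are only
        pinned to ~1e-4)."""
        rng = np.random.default_rng(6)
        y = np.cos(climate12["P_MA"].to_numpy() / 200.0) + 0.05 * rng.standard_normal(12)
        scaled = climate12.copy()
        scaled["P_MA"] = scaled["P_MA"] * 0.001 - 3.0
        scaled["T_MAX"] = scaled["T_MAX"] * 10.0 + 7.0
        lam = {"P_MA": 0.006, "T_MAX": 2.5}
        fit = gc.fit_gam(y, climate12, ["P_MA", "T_MAX"], lambdas=lam)
        fit2 = gc.fit_gam(y, scaled, ["P_MA", "T_MAX"], lambdas=lam)
        np.testing.assert_allclose(fit2.predict(scaled), fit.predict(climate12),
                                   atol=1e-8)
        g1 = gc.fit_gam(y, climate12, ["P_MA", "T_MAX"])
        g2 = gc.fit_gam(y, scaled, ["P_MA", "T_MAX"])
        np.testing.assert_allclose(g2.predict(scaled), g1.predict(climate12),
                                   atol=1e-3)

    def test_rss_nondecreasing_in_lambda(self, climate12):
        rng = np.random.default_rng(7)
        y = np.sin(climate12["T_MAX"].to_numpy()) + 0.3 * rng.standard_normal(12)
        rss = []
        for lam in (0.0, 1e-3, 1e-1, 10.0, 1e4):
            fit = gc.fit_gam(y, climate12, ["T_MAX"], lambdas={"default": lam})
            rss.append((1 - fit.deviance_explained / 100))
        assert all(a <= b + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_edf_structurally_below_n(self, climate12):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(12)
        fit = gc.fit_gam(y, climate12, ["T_MAX", "P_MA", "P_DM"],
                         lambdas={"default": 0.0})
        assert fit.edf_total <= 7 + 1e-9  # 1 + 3 terms x 2 coefficients
        assert fit.edf_total < fit.n

    def test_gcv_beats_straight_line_on_curved_truth(self, climate12):
        """A sin-shaped response over 12 design points: the GCV spline
        should beat the straight-line fit out of sample on average."""
        p_ma = climate12["P_MA"].to_numpy()
        z = (p_ma - p_ma.mean()) / p_ma.std()
        truth = np.sin(1.8 * z)
        rng = np.random.default_rng(9)
        wins = 0
        reps = 100
        for _ in range(reps):
            y = truth + 0.15 * rng.standard_normal(12)
            fit = gc.fit_gam(y, climate12, ["P_MA"])
            slope, intercept = np.polyfit(p_ma, y, 1)
            rmse_gam = np.sqrt(np.mean((fit.predict(climate12) - truth) ** 2))
            rmse_line = np.sqrt(np.mean((slope * p_ma + intercept - truth) ** 2))
            wins += rmse_gam < rmse_line
        assert wins / reps > 0.5

    def test_duplicate_variables_rejected(self, climate12):
        with pytest.raises(ValueError):
            gc.fit_gam(np.zeros(12), climate12, ["T_MAX", "T_MAX"])


class TestSelection:
    def test_single_candidate_wins(self, climate12):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(12)
        sel = select_model(y, climate12, ["T_MAX"], max_vars=3)
        assert sel.winner_variables == ("T_MAX",)

    def test_candidates_enumerate_subsets(self, climate12):
        rng = np.random.default_rng(12)
        y = climate12["T_MAX"].to_numpy() + rng.standard_normal(12)
        sel = select_model(y, climate12, list(gc.CLIMATE_VARIABLES), max_vars=3)
        assert len(sel.table) == 7 + 21 + 35
        assert sel.table.loc[0, "r2_adj"] == sel.table["r2_adj"].max()

    def test_pure_noise_never_trips_overfit_guard(self, climate12):
        rng = np.random.default_rng(13)
        for _ in range(10):
            y = rng.standard_normal(12)
            sel = select_model(y, climate12, list(gc.CLIMATE_VARIABLES))
            assert sel.winner.edf_total < sel.winner.n
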