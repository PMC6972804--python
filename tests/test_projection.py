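import numpy as np
import pandas as pd
import pytest

import gardenclim as gc
from gardenclim.projection import _slope_equality_f
from gardenclim.simulate import gradients_spanning


@pytest.fixture(scope="module")
def fitted_surfaces(request):
    """A GAM fitted on the 12-population climate, projected on current
    and offset future stacks."""
    clim = gc.default_population_climate(12)
    y = 5.0 + 0.08 * clim["T_MAX"].to_numpy() - 0.001 * clim["P_MA"].to_numpy()
    fit = gc.fit_gam(y, clim, ["T_MAX", "P_MA"])
    grads = gradients_spanning(clim, ["T_MAX", "P_MA"], 10, 12)
    cur, fut, mask = gc.simulate_climate_rasters(
        10, 12, grads, future_offsets={"T_MAX": 1.0, "P_MA": -60.0})
    s_cur = gc.predict_surface(fit, cur, "current", trait="y",
                               distribution_mask=mask)
    s_fut = gc.predict_surface(fit, fut, "future", trait="y",
                               distribution_mask=mask)
    return fit, cur, fut, mask, s_cur, s_fut


class TestPredictSurface:
    def test_constant_raster_predicts_point_value(self):
        clim = gc.default_population_climate(12)
        y = clim["T_MAX"].to_numpy() * 0.1
        fit = gc.fit_gam(y, clim, ["T_MAX"])
        tmax0 = float(clim["T_MAX"].iloc[0])
        stack = {"T_MAX": gc.RasterGrid(np.full((4, 4), tmax0))}
        surf = gc.predict_surface(fit, stack, "current", trait="y")
        expected = fit.predict(pd.DataFrame({"T_MAX": [tmax0]}))[0]
        np.testing.assert_allclose(surf.grid.values, expected, atol=1e-10)
        assert not surf.extrapolated.any()

    def test_extrapolation_flagged_outside_training_range(self, fitted_surfaces):
        fit, cur, *_ = fitted_surfaces
        hot = {v: g.with_values(g.values + (50.0 if v == "T_MAX" else 0.0))
               for v, g in cur.items()}
        surf = gc.predict_surface(fit, hot, "hot", trait="y")
        assert surf.extrapolated.all()
        assert np.isfinite(surf.grid.values).all()  # still predicted

    def test_two_point_gradient_matches_direct_evaluation(self, fitted_surfaces):
        fit, *_ = fitted_surfaces
        lo = {v: r[0] for v, r in fit.training_range.items()}
        hi = {v: r[1] for v, r in fit.training_range.items()}
        stack = {v: gc.RasterGrid(np.array([[lo[v], hi[v]]])) for v in lo}
        surf = gc.predict_surface(fit, stack, "current", trait="y")
        direct = fit.predict(pd.DataFrame([lo, hi]))
        np.testing.assert_allclose(surf.grid.values[0], direct, atol=1e-10)

    def test_missing_layer_rejected(self, fitted_surfaces):
        fit, cur, *_ = fitted_surfaces
        with pytest.raises(ValueError, match="P_MA"):
            gc.predict_surface(fit, {"T_MAX": cur["T_MAX"]}, "x")

    def test_commutes_with_cropping(self, fitted_surfaces):
        fit, cur, *_ = fitted_surfaces
        full = gc.predict_surface(fit, cur, "current", trait="y")
        window = {v: gc.RasterGrid(g.values[2:6, 3:9],
                                   x_origin=g.x_origin + 3 * g.cell_size,
                                   y_origin=g.y_origin - 2 * g.cell_size)
                  for v, g in cur.items()}
        cropped = gc.predict_surface(fit, window, "current", trait="y")
        np.testing.assert_allclose(cropped.grid.values,
                                   full.grid.values[2:6, 3:9], atol=1e-12)


class TestChangeMap:
    def test_identical_scenarios_give_zero(self, fitted_surfaces):
        *_, s_cur, _ = fitted_surfaces
        cm = gc.change_map(s_cur, s_cur)
        assert np.nanmax(np.abs(cm.grid.values)) == 0.0

    def test_arithmetic(self):
        a = gc.TraitSurface(gc.RasterGrid(np.full((2, 2), 2.0)),
                            np.zeros((2, 2), bool), "current", "y")
        b = gc.TraitSurface(gc.RasterGrid(np.full((2, 2), 3.0)),
                            np.zeros((2, 2), bool), "future", "y")
        cm = gc.change_map(a, b)
        np.testing.assert_allclose(cm.grid.values, 0.5)

    def test_near_zero_current_guarded(self):
        vals = np.array([[1e-12, 1.0], [2.0, -1.0]])
        a = gc.TraitSurface(gc.RasterGrid(vals), np.zeros((2, 2), bool),
                            "current", "PRI")
        b = gc.TraitSurface(gc.RasterGrid(vals + 0.5), np.zeros((2, 2), bool),
                            "future", "PRI")
        cm = gc.change_map(a, b)
        assert cm.undefined[0, 0]
        assert np.isnan(cm.grid.values[0, 0])
        assert np.isfinite(cm.grid.values[0, 1])

    def test_not_antisymmetric_in_general(self, fitted_surfaces):
        *_, s_cur, s_fut = fitted_surfaces
        ab = gc.change_map(s_cur, s_fut).grid.values
        ba = gc.change_map(s_fut, s_cur).grid.values
        assert not np.allclose(np.nan_to_num(ab), np.nan_to_num(-ba))


class TestSummarizeChange:
    def test_all_zero_map(self, fitted_surfaces):
        *_, s_cur, _ = fitted_surfaces
        summ = gc.summarize_change(gc.change_map(s_cur, s_cur))
        assert summ["mean"] == 0.0 and summ["min"] == 0.0 and summ["max"] == 0.0

    def test_half_up_half_down(self):
        vals = np.ones((2, 4))
        fut = np.ones((2, 4))
        fut[:, :2] = 1.1
        fut[:, 2:] = 0.9
        a = gc.TraitSurface(gc.RasterGrid(vals), np.zeros((2, 4), bool), "c", "y")
        b = gc.TraitSurface(gc.RasterGrid(fut), np.zeros((2, 4), bool), "f", "y")
        summ = gc.summarize_change(gc.change_map(a, b))
        assert summ["mean"] == pytest.approx(0.0, abs=1e-12)
        assert summ["share_increasing"] == 0.5

    def test_masked_cells_excluded(self):
        vals = np.ones((3, 3))
        fut = np.full((3, 3), 1.2)
        extrap = np.zeros((3, 3), bool)
        extrap[0, 0] = True
        fut[0, 0] = 99.0  # sentinel under the mask
        a = gc.TraitSurface(gc.RasterGrid(vals), extrap, "c", "y")
        b = gc.TraitSurface(gc.RasterGrid(fut), extrap, "f", "y")
        summ = gc.summarize_change(gc.change_map(a, b))
        assert summ["n_cells"] == 8
        assert summ["max"] == pytest.approx(0.2)

    def test_empty_summary_raises(self):
        a = gc.TraitSurface(gc.RasterGrid(np.full((2, 2), np.nan)),
                            np.zeros((2, 2), bool), "c", "y")
        with pytest.raises(ValueError):
            gc.summarize_change(gc.change_map(a, a))


def _surface(vals, scenario, trait):
    return gc.TraitSurface(gc.RasterGrid(np.asarray(vals, float)),
                           np.zeros(np.shape(vals), bool), scenario, trait)


class TestDecoupling:
    def test_identical_scenarios_f_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 10))
        y = 2 * x + 0.1 * rng.normal(size=(10, 10))
        t = gc.decoupling_test(_surface(x, "c", "A"), _surface(y, "c", "B"),
                               _surface(x, "f", "A"), _surface(y, "f", "B"))
        assert t.f_stat == pytest.approx(0.0, abs=1e-9)
        assert t.p_value > 0.99

    def test_stacked_f_equals_two_sample_slope_test(self):
        """Algebraic identity: the interaction F equals the squared
        two-sample slope z with pooled residual variance."""
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=200), rng.normal(size=200)
        y1 = 1.0 * x1 + 0.3 * rng.normal(size=200)
        y2 = 1.3 * x2 + 0.3 * rng.normal(size=200)
        f, p = _slope_equality_f(x1, y1, x2, y2)

        def ols(x, y):
            sxx = np.sum((x - x.mean()) ** 2)
            b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            a = y.mean() - b * x.mean()
            rss = np.sum((y - a - b * x) ** 2)
            return b, rss, sxx

        b1, rss1, sxx1 = ols(x1, y1)
        b2, rss2, sxx2 = ols(x2, y2)
        s2 = (rss1 + rss2) / (len(x1) + len(x2) - 4)
        z2 = (b1 - b2) ** 2 / (s2 * (1 / sxx1 + 1 / sxx2))
        assert f == pytest.approx(z2, abs=1e-9 * max(1.0, z2))

    def test_power_at_slopes_one_vs_two(self):
        """Slopes 1 vs 2 with small noise over 1,000 cells should be
        detected essentially always."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=1000)
            y1 = x + 0.2 * rng.normal(size=1000)
            y2 = 2 * x + 0.2 * rng.normal(size=1000)
            t = gc.decoupling_test(
                _surface(x.reshape(25, 40), "c", "A"),
                _surface(y1.reshape(25, 40), "c", "B"),
                _surface(x.reshape(25, 40), "f", "A"),
                _surface(y2.reshape(25, 40), "f", "B"))
            hits += t.p_value < 0.05
        assert hits == 20

    def test_observed_means_comparison(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 1.5 * x + 0.1 * rng.normal(size=100)
        obs = pd.DataFrame({"A": rng.normal(size=12),
                            "B": rng.normal(size=12)})
        t = gc.decoupling_test(_surface(x.reshape(10, 10), "c", "A"),
                               _surface(y.reshape(10, 10), "c", "B"),
                               _surface(x.reshape(10, 10), "f", "A"),
                               _surface(y.reshape(10, 10), "f", "B"),
                               observed_means=obs)
        assert t.slope_observed is not None
        assert 0.0 <= t.p_observed_vs_current <= 1.0

    def test_degenerate_x_rejected(self):
        x = np.ones((3, 3))
        y = np.arange(9, dtype=float).reshape(3, 3)
        with pytest.raises(ValueError):
            gc.decoupling_test(_surface(x, "c", "A"), _surface(y, "c", "B"),
                               _surface(x, "f", "A"), _surface(y, "f", "B"))
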