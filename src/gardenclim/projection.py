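"""Landscape projection of fitted trait-climate models.

A fitted GAM is evaluated on co-registered climate raster stacks to
produce a trait surface per scenario; cells whose climate leaves the
model's training range are flagged as extrapolated (still predicted,
but masked in summaries by default).  Future-minus-current change is
expressed proportionally, (future - current) / current, and the
stability of trait-trait correlations under climate change is tested by
comparing regression slopes across pixels between scenarios.

Pixels are treated as independent observations in the slope tests (no
spatial-autocorrelation correction); this caveat is recorded in the
test metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GamFit
from .io import RasterGrid, align_stack


@dataclass
class TraitSurface:
    """Predicted trait values per raster cell for one scenario."""

    grid: RasterGrid
    extrapolated: np.ndarray
    scenario: str
    trait: str = ""

    def defined(self, include_extrapolated: bool = False) -> np.ndarray:
        """Boolean mask of usable cells."""
        ok = ~self.grid.mask
        if not include_extrapolated:
            ok &= ~self.extrapolated
        return ok


@dataclass
class ProportionalChangeMap:
    """(future - current) / current per cell, with an undefined-cell
    mask where |current| falls below the division guard."""

    grid: RasterGrid
    undefined: np.ndarray
    extrapolated: np.ndarray
    trait: str = ""


@dataclass
class SlopeEquivalenceTest:
    """Slope-equality (decoupling) test between two scenarios.

    ``f_stat``/``p_value`` test equal slopes via the scenario x
    covariate interaction in the stacked pixel regression.  When
    observed population or family means are supplied, the current
    spatial slope is also compared against the slope over those means.
    """

    pair: tuple[str, str]
    slope_current: float
    slope_future: float
    r2_current: float
    r2_future: float
    f_stat: float
    p_value: float
    n_pixels: int
    slope_observed: float | None = None
    p_observed_vs_current: float | None = None
    metadata: dict | None = None


def predict_surface(fit: GamFit, stack: dict[str, RasterGrid],
                    scenario: str, trait: str = "",
                    distribution_mask: RasterGrid | None = None) -> TraitSurface:
    """Evaluate a fitted GAM on a climate raster stack.

    Every selected covariate must be present in the stack and all
    layers co-registered.  Cells with any covariate outside the fit's
    training range are predicted anyway but flagged extrapolated.  An
    optional species-distribution mask (nonzero/non-nan = inside)
    restricts the surface to distribution cells.
    """
    missing = [v for v in fit.variables if v not in stack]
    if missing:
        raise ValueError(f"stack is missing layers {missing}")
    layers = {v: stack[v] for v in fit.variables}
    align_stack(dict(layers))
    first = next(iter(layers.values()))
    valid = ~first.mask
    if distribution_mask is not None:
        if not first.same_grid(distribution_mask):
            raise ValueError("distribution mask is not co-registered")
        inside = (~distribution_mask.mask) & (distribution_mask.values != 0)
        valid &= inside
    frame = pd.DataFrame({v: g.values[valid] for v, g in layers.items()})
    values = np.full(first.shape, np.nan)
    extrap = np.zeros(first.shape, dtype=bool)
    if len(frame):
        values[valid] = fit.predict(frame)
        extrap[valid] = fit.extrapolation_mask(frame)
    grid = first.with_values(values, scenario=scenario)
    return TraitSurface(grid=grid, extrapolated=extrap, scenario=scenario,
                        trait=trait)


def change_map(current: TraitSurface, future: TraitSurface,
               guard_quantile: float = 0.95,
               guard_factor: float = 1e-6) -> ProportionalChangeMap:
    """Proportional change (future - current) / current per cell.

    Cells where |current| is below ``guard_factor`` times the
    ``guard_quantile`` quantile of |current| are marked undefined
    rather than allowed to blow up (PRI crosses zero).
    """
    if not current.grid.same_grid(future.grid):
        raise ValueError("surfaces are not co-registered")
    if current.scenario == future.scenario:
        import logging
        logging.getLogger("gardenclim").warning(
            "change_map: both surfaces tagged %r", current.scenario)
    cur, fut = current.grid.values, future.grid.values
    both = ~(np.isnan(cur) | np.isnan(fut))
    scale = np.nanquantile(np.abs(cur[both]), guard_quantile) if both.any() else 0.0
    guard = guard_factor * scale
    undefined = ~both | (np.abs(np.where(both, cur, np.inf)) < guard)
    values = np.full(cur.shape, np.nan)
    ok = ~undefined
    values[ok] = (fut[ok] - cur[ok]) / cur[ok]
    grid = current.grid.with_values(
        values, scenario=f"{current.scenario}->{future.scenario}")
    return ProportionalChangeMap(grid=grid, undefined=undefined,
                                 extrapolated=current.extrapolated | future.extrapolated,
                                 trait=current.trait)


def summarize_change(cmap: ProportionalChangeMap,
                     include_extrapolated: bool = False) -> dict[str, float]:
    """Range, mean and direction shares of a proportional-change map
    over defined (and by default non-extrapolated) cells."""
    ok = ~cmap.undefined
    if not include_extrapolated:
        ok &= ~cmap.extrapolated
    vals = cmap.grid.values[ok]
    if vals.size == 0:
        raise ValueError("no defined cells to summarise")
    return {"n_cells": int(vals.size),
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "max_abs": float(np.abs(vals).max()),
            "share_increasing": float((vals > 0).mean()),
            "share_decreasing": float((vals < 0).mean())}


def _pixel_regression(x: np.ndarray, y: np.ndarray):
    if np.var(x) == 0:
        raise ValueError("degenerate covariate: zero variance across pixels")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def _slope_equality_f(x1, y1, x2, y2) -> tuple[float, float]:
    """F test of equal slopes from the scenario x covariate interaction
    in the stacked regression y ~ x * scenario."""
    n1, n2 = len(x1), len(x2)
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(n1), np.ones(n2)])
    X = np.column_stack([np.ones(n1 + n2), x, g, x * g])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_int = np.sqrt(sigma2 * XtX_inv[3, 3])
    t = beta[3] / se_int
    f = float(t ** 2)
    p = float(stats.f.sf(f, 1, df))
    return f, p


def decoupling_test(x_current: TraitSurface, y_current: TraitSurface,
                    x_future: TraitSurface, y_future: TraitSurface,
                    observed_means: pd.DataFrame | None = None,
                    include_extrapolated: bool = False) -> SlopeEquivalenceTest:
    """Test whether a trait-pair regression slope differs between the
    current and future predicted surfaces.

    The slope of y on x is estimated over defined pixels within each
    scenario; equality is tested by the F statistic on the scenario x x
    interaction of the stacked regression.  ``observed_means`` (columns
    named after the two traits, rows = populations or families) adds a
    comparison of the current spatial slope against the slope over the
    observed means.
    """
    for a, b in ((x_current, y_current), (x_future, y_future)):
        if not a.grid.same_grid(b.grid):
            raise ValueError("surfaces are not co-registered")
    ok_cur = x_current.defined(include_extrapolated) & y_current.defined(include_extrapolated)
    ok_fut = x_future.defined(include_extrapolated) & y_future.defined(include_extrapolated)
    if ok_cur.sum() < 3 or ok_fut.sum() < 3:
        raise ValueError("need >= 3 defined cells per scenario")
    xc, yc = x_current.grid.values[ok_cur], y_current.grid.values[ok_cur]
    xf, yf = x_future.grid.values[ok_fut], y_future.grid.values[ok_fut]
    slope_c, r2_c = _pixel_regression(xc, yc)
    slope_f, r2_f = _pixel_regression(xf, yf)
    f, p = _slope_equality_f(xc, yc, xf, yf)
    slope_obs = p_obs = None
    if observed_means is not None:
        xo = observed_means[x_current.trait].to_numpy(dtype=float)
        yo = observed_means[y_current.trait].to_numpy(dtype=float)
        keep = ~(np.isnan(xo) | np.isnan(yo))
        slope_obs, _ = _pixel_regression(xo[keep], yo[keep])
        _, p_obs = _slope_equality_f(xc, yc, xo[keep], yo[keep])
    return SlopeEquivalenceTest(
        pair=(x_current.trait, y_current.trait),
        slope_current=slope_c, slope_future=slope_f,
        r2_current=r2_c, r2_future=r2_f,
        f_stat=f, p_value=p,
        n_pixels=int(ok_cur.sum() + ok_fut.sum()),
        slope_observed=slope_obs, p_observed_vs_current=p_obs,
        metadata={"pixels_treated_independent": True,
                  "include_extrapolated": include_extrapolated})
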