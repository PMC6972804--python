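"""Desk-scale validation experiments with known ground truth.

Each function simulates data from :mod:`gardenclim.simulate` at the
study's design dimensions, runs the corresponding analysis stage, and
returns the summary quantity a reviewer would check: estimator
agreement with closed-form oracles, parameter-recovery bias, test
calibration (type-I error) and power.  The same functions back the
test suite and the reproduction script, so every reported number is
recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gam as gam_mod
from . import projection as proj_mod
from .io import CLIMATE_VARIABLES
from .multivar import family_means
from .simulate import (SimulationConfig, TraitModel, dataset1_config,
                       gradients_spanning, simulate_climate_rasters,
                       simulate_plantation, simulate_spectra,
                       synthetic_population_climate, trait_model_for_h2)
from .spectra import average_spectra, ndvi_mnd705, pri
from .varcomp import (RandomModelSpec, _RemlProblem, fit_random_model,
                      heritability, lrt_family)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


# ---------------------------------------------------------------------------
# REML estimator checks
# ---------------------------------------------------------------------------


def reml_anova_agreement(seed: int = 0, n_designs: int = 5) -> float:
    """Max |REML - closed-form ANOVA| over balanced one-way designs.

    For a balanced family design the REML estimates coincide with the
    method-of-moments estimators s2_fam = (MS_between - MS_within)/n
    whenever the estimate is interior.
    """
    worst = 0.0
    for child in _spawn_seeds(seed, n_designs):
        rng = np.random.default_rng(child)
        n_fam, n_rep = 25, 8
        s2f, s2e = rng.uniform(1.0, 4.0), rng.uniform(3.0, 8.0)
        fam = np.repeat(np.arange(n_fam), n_rep)
        y = (np.repeat(rng.normal(0, np.sqrt(s2f), n_fam), n_rep)
             + rng.normal(0, np.sqrt(s2e), n_fam * n_rep))
        res = _RemlProblem(y, [fam]).fit()
        if res["boundary"].any():
            continue
        fam_means_ = np.bincount(fam, y) / n_rep
        ms_between = n_rep * np.sum((fam_means_ - y.mean()) ** 2) / (n_fam - 1)
        ms_within = np.sum((y - fam_means_[fam]) ** 2) / (n_fam * (n_rep - 1))
        anova = np.array([(ms_between - ms_within) / n_rep, ms_within])
        worst = max(worst, float(np.abs(res["theta"] - anova).max()))
    return worst


def heritability_recovery(n_rep: int = 200, true_h2: float = 0.20,
                          seed: int = 0) -> dict[str, float]:
    """Simulate at the heritability data set's dimensions and refit.

    Returns the mean estimate, its empirical SD across replicates, and
    the mean delta-method SE (which should track that SD).
    """
    cfg = dataset1_config(traits={"y": trait_model_for_h2(true_h2)})
    h2s, ses = [], []
    for child in _spawn_seeds(seed, n_rep):
        ds = simulate_plantation(cfg, seed=int(child))
        est = heritability(fit_random_model(ds.table, "y"))
        h2s.append(est.h2)
        ses.append(est.se_h2)
    h2s = np.asarray(h2s)
    return {"true_h2": true_h2,
            "mean_h2": float(np.mean(h2s)),
            "empirical_sd": float(np.std(h2s, ddof=1)),
            "mean_delta_se": float(np.mean(ses)),
            "n_rep": n_rep}


def lrt_null_calibration(n_rep: int = 500, alpha: float = 0.05,
                         seed: int = 0) -> dict[str, float]:
    """Rejection rate of the family LRT when s2_fam is truly zero.

    Under the boundary mixture 0.5*chi2_0 + 0.5*chi2_1 the test should
    hold its nominal level.
    """
    cfg = dataset1_config(traits={"y": TraitModel(
        sigma2_fam=0.0, sigma2_famblock=0.5, sigma2_err=9.5)})
    rejections = 0
    for child in _spawn_seeds(seed, n_rep):
        ds = simulate_plantation(cfg, seed=int(child))
        vc = fit_random_model(ds.table, "y")
        _, p = lrt_family(vc, ds.table, "y")
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "alpha": alpha,
            "n_rep": n_rep}


def lrt_power(n_rep: int = 100, true_h2: float = 0.20, alpha: float = 0.05,
              seed: int = 0) -> dict[str, float]:
    """Rejection rate of the family LRT at a heritable signal."""
    cfg = dataset1_config(traits={"y": trait_model_for_h2(true_h2)})
    rejections = 0
    for child in _spawn_seeds(seed, n_rep):
        ds = simulate_plantation(cfg, seed=int(child))
        vc = fit_random_model(ds.table, "y")
        _, p = lrt_family(vc, ds.table, "y")
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "alpha": alpha,
            "n_rep": n_rep}


# ---------------------------------------------------------------------------
# spectral identities
# ---------------------------------------------------------------------------


def spectral_identity_error(seed: int = 0) -> float:
    """Max |recovered - target| index error over constructed spectra,
    including a uniform-rescaling check (both indices are ratios)."""
    worst = 0.0
    for target_p, target_m in ((0.2, 0.5), (-0.15, 0.35), (0.05, 0.72)):
        leaves = simulate_spectra(target_p, target_m, n_leaves=3,
                                  noise_sd=0.0, seed=seed,
                                  wavelength_range=(400, 800))
        mean = average_spectra(leaves)
        worst = max(worst, abs(pri(mean) - target_p),
                    abs(ndvi_mnd705(mean) - target_m))
        scaled = type(mean)(mean.wavelengths, mean.reflectance * 0.01)
        worst = max(worst, abs(pri(scaled) - target_p),
                    abs(ndvi_mnd705(scaled) - target_m))
    return worst


# ---------------------------------------------------------------------------
# GAM checks
# ---------------------------------------------------------------------------


def gam_linear_limit(seed: int = 0) -> dict[str, float]:
    """Noiseless linear trait-climate response: the penalized spline
    must reproduce the OLS line with 100% deviance explained."""
    clim = synthetic_population_climate(12, seed=seed)
    x = clim["T_MAX"].to_numpy()
    y = 1.0 + 0.2 * x
    fit = gam_mod.fit_gam(y, clim, ["T_MAX"])
    slope, intercept = np.polyfit(x, y, 1)
    ols_gap = float(np.abs(fit.predict(clim) - (intercept + slope * x)).max())
    return {"deviance_explained": fit.deviance_explained,
            "max_abs_gap_to_ols": ols_gap}


def gam_lambda0_agreement(seed: int = 0) -> float:
    """Max |penalized fit at lambda=0 - direct least squares| over the
    training points."""
    clim = synthetic_population_climate(12, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y = np.sin(clim["T_MAX"].to_numpy() / 2.0) + 0.1 * rng.standard_normal(12)
    variables = ["T_MAX", "P_MA"]
    fit = gam_mod.fit_gam(y, clim, variables, lambdas={"default": 0.0})
    _, Xd, _, _, _ = gam_mod._assemble(y, clim, variables, 3)
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return float(np.abs(Xd @ fit.coefficients - Xd @ beta).max())


def gam_selection_recovery(n_rep: int = 100, snr: float = 5.0,
                           seed: int = 0) -> dict[str, float]:
    """How often exhaustive subset selection includes the true driver.

    Twelve populations, trait means a linear function of T_MAX with
    noise at the requested signal-to-noise ratio; the candidate pool is
    all seven climate variables with controlled moderate correlation.
    """
    hits = 0
    seeds = _spawn_seeds(seed, n_rep)
    rng = np.random.default_rng(seed)
    for child in seeds:
        clim = synthetic_population_climate(12, seed=int(child))
        z = clim["T_MAX"].to_numpy()
        z = (z - z.mean()) / z.std()
        signal = 2.0 * z
        noise_sd = float(np.sqrt(np.var(signal) / snr))
        y = signal + noise_sd * rng.standard_normal(12)
        sel = gam_mod.select_model(y, clim, list(CLIMATE_VARIABLES))
        hits += "T_MAX" in sel.winner_variables
    return {"recovery_rate": hits / n_rep, "snr": snr, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# projection checks
# ---------------------------------------------------------------------------


def projection_zero_offset_identity(seed: int = 0) -> float:
    """Max |proportional change| when the future equals the current
    climate: must be exactly zero."""
    clim = synthetic_population_climate(12, seed=seed)
    y = 3.0 + 0.15 * clim["T_MAX"].to_numpy()
    fit = gam_mod.fit_gam(y, clim, ["T_MAX"])
    grads = gradients_spanning(clim, ["T_MAX"], 12, 15)
    cur, fut, mask = simulate_climate_rasters(12, 15, grads, future_offsets={})
    s_cur = proj_mod.predict_surface(fit, cur, "current", "y", mask)
    s_fut = proj_mod.predict_surface(fit, fut, "future", "y", mask)
    summ = proj_mod.summarize_change(proj_mod.change_map(s_cur, s_fut))
    return summ["max_abs"]


def _pixel_pair(rng, n_pixels, slope, noise_sd):
    x = rng.normal(size=n_pixels)
    y = slope * x + noise_sd * rng.normal(size=n_pixels)
    return x, y


def slope_test_type1(n_rep: int = 500, n_pixels: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Type-I error of the slope-equality (decoupling) F test when the
    two scenarios share the same true slope."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        x1, y1 = _pixel_pair(rng, n_pixels, 1.0, 1.0)
        x2, y2 = _pixel_pair(rng, n_pixels, 1.0, 1.0)
        _, p = proj_mod._slope_equality_f(x1, y1, x2, y2)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "alpha": alpha,
            "n_rep": n_rep}


def slope_test_power(n_rep: int = 100, n_pixels: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Power of the decoupling test at slopes 1 vs 2 with small noise."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        x1, y1 = _pixel_pair(rng, n_pixels, 1.0, 0.5)
        x2, y2 = _pixel_pair(rng, n_pixels, 2.0, 0.5)
        _, p = proj_mod._slope_equality_f(x1, y1, x2, y2)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "alpha": alpha,
            "n_rep": n_rep}


# ---------------------------------------------------------------------------
# end-to-end pipeline demonstration
# ---------------------------------------------------------------------------


def end_to_end_summary(seed: int = 0) -> dict[str, float]:
    """One full pipeline pass on a simulated modelling data set:
    simulate -> family means -> trait-pair regression -> GAM selection
    -> projection -> proportional change under a hotter, drier future.

    Returns the realised trait-pair slope sign, the winning model's
    deviance explained, the correlation of the predicted surface with
    the true mean field, and the mean proportional change.
    """
    from .multivar import fit_trait_pair
    from .simulate import dataset2_config

    clim = synthetic_population_climate(12, seed=seed)
    traits = {
        "WD": trait_model_for_h2(0.12, phenotypic_var=0.002,
                                 mu=0.52, sigma2_pop=2e-5,
                                 climate_slopes={"T_MAX": -0.02}),
        "N_CONC": trait_model_for_h2(0.22, phenotypic_var=0.02,
                                     mu=1.1, sigma2_pop=2e-4,
                                     climate_slopes={"T_MAX": 0.06}),
    }
    corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
    cfg = dataset2_config(traits=traits, genetic_corr=corr,
                          population_climate=clim)
    ds = simulate_plantation(cfg, seed=seed)
    fm = family_means(ds.table)
    pair = fit_trait_pair(fm, "WD", "N_CONC")
    pm = ds.table.data.groupby("population", observed=True)["N_CONC"].mean()
    sel = gam_mod.select_model(pm.to_numpy(), clim.loc[pm.index],
                               list(CLIMATE_VARIABLES))
    grads = gradients_spanning(clim, sel.winner.variables, 15, 20)
    cur, fut, mask = simulate_climate_rasters(
        15, 20, grads,
        future_offsets={v: (1.5 if v.startswith("T") else -0.1 * clim[v].std())
                        for v in sel.winner.variables})
    s_cur = proj_mod.predict_surface(sel.winner, cur, "current", "N_CONC", mask)
    s_fut = proj_mod.predict_surface(sel.winner, fut, "future", "N_CONC", mask)
    summ = proj_mod.summarize_change(proj_mod.change_map(s_cur, s_fut),
                                     include_extrapolated=False)
    return {"wd_nconc_slope": pair.slope,
            "winner_deviance_explained": sel.winner.deviance_explained,
            "mean_proportional_change": summ["mean"],
            "share_decreasing": summ["share_decreasing"]}
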