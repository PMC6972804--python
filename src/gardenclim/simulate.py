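"""Synthetic plantation, spectra and climate rasters with known truth.

The generator mirrors the structure of the fitted models so parameter
recovery is well-posed: a tree's trait value is

    value = mu + pop(climate) + pop_random + block + family
            + block x family + residual

with independent Gaussian effects at the configured variances.  The
population term has a deterministic part driven by the population's
climate-of-origin (linear in standardised climate by default, or any
smooth callable) plus an optional random component.  Family effects
carry the additive genetic signal: their variance is sigma2_A / 2.5 for
the mixed-mating coefficient of relationship rho = 1/2.5, so the
heritability estimator 2.5 * s2_fam / (s2_fam + s2_famblock + s2_err)
targets sigma2_A over the within-population phenotypic variance.

Default dimensions mirror the trial's two data sets (480 trees each):
data set 1 is 4 populations x 10 families x 12 replicates and data set
2 is 12 populations x 10 families x 4 replicates, both over 6 blocks.
Multi-trait draws use a genetic correlation matrix for family effects
and a residual correlation matrix for the error term.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import (CLIMATE_VARIABLES, ClimateVariableSet, RasterGrid,
                 TraitTable, load_population_climate)
from .spectra import ReflectanceSpectrum


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class TraitModel:
    """Ground-truth generative model for one trait."""

    mu: float = 0.0
    sigma2_block: float = 0.5
    sigma2_pop: float = 1.0
    sigma2_fam: float = 0.8
    sigma2_famblock: float = 0.5
    sigma2_err: float = 8.7
    #: linear response of the population mean to standardised climate
    climate_slopes: dict[str, float] = field(default_factory=dict)
    #: optional smooth response applied to the raw climate values
    climate_response: Callable[[ClimateVariableSet], float] | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_block", "sigma2_pop", "sigma2_fam",
                     "sigma2_famblock", "sigma2_err"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def implied_h2(self) -> float:
        denom = self.sigma2_fam + self.sigma2_famblock + self.sigma2_err
        return 2.5 * self.sigma2_fam / denom if denom > 0 else 0.0


def trait_model_for_h2(h2: float, phenotypic_var: float = 10.0,
                       famblock_share: float = 0.05, **kwargs) -> TraitModel:
    """Variance components hitting a target within-population h^2.

    ``phenotypic_var`` is s2_fam + s2_famblock + s2_err; the family
    component is h2 * P / 2.5 and ``famblock_share`` fixes the block x
    family share of what remains.
    """
    if not 0 <= h2 <= 2.5:
        raise ConfigError("implied h2 must lie in [0, 2.5]")
    s_fam = h2 * phenotypic_var / 2.5
    rest = phenotypic_var - s_fam
    if rest < 0:
        raise ConfigError("family variance exceeds phenotypic variance")
    return TraitModel(sigma2_fam=s_fam,
                      sigma2_famblock=famblock_share * rest,
                      sigma2_err=(1 - famblock_share) * rest, **kwargs)


@dataclass
class SimulationConfig:
    """Design dimensions, per-trait models and cross-trait correlations."""

    n_blocks: int = 6
    n_populations: int = 4
    families_per_population: int = 10
    replicates_per_family: int = 12
    traits: dict[str, TraitModel] = field(
        default_factory=lambda: {"trait": TraitModel()})
    genetic_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    population_climate: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.n_populations,
               self.families_per_population, self.replicates_per_family) < 1:
            raise ConfigError("design dimensions must be positive")
        k = len(self.traits)
        for name in ("genetic_corr", "residual_corr"):
            C = getattr(self, name)
            if C is None:
                continue
            C = np.asarray(C, dtype=float)
            if C.shape != (k, k) or not np.allclose(C, C.T) \
                    or not np.allclose(np.diag(C), 1.0):
                raise ConfigError(f"{name} must be a {k}x{k} correlation matrix")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ConfigError(f"{name} is not positive semi-definite")
            setattr(self, name, C)


@dataclass
class SyntheticDataset:
    """A simulated plantation with its ground truth."""

    table: TraitTable
    true_population_means: pd.DataFrame
    true_family_effects: pd.DataFrame
    true_block_effects: pd.DataFrame
    config: SimulationConfig
    seed: int


def default_population_climate(n_populations: int) -> pd.DataFrame:
    """Climate-of-origin for up to 12 populations, from the trial's
    published station extractions; the three untabulated variables are
    derived deterministically on plausible regional scales."""
    pub = load_population_climate()
    if n_populations <= 4:
        pub = pub[pub["ds1_families"].notna()].reset_index(drop=True)
    if n_populations > len(pub):
        raise ConfigError(f"at most {len(pub)} populations available")
    pub = pub.iloc[:n_populations]
    # T_MA cools toward the south coast and warms inland; T_RANGE grows
    # with continentality and aridity; P_RANGE reflects the region's
    # strong winter-rainfall seasonality.  These keep the derived
    # variables correlated with the tabulated ones, as real bioclim
    # layers are, without being collinear.
    t_ma = 0.75 * pub["T_MAX"] - 5.0 - 0.6 * (pub["longitude"] - 116.5)
    t_range = 1.1 * (pub["T_MAX"] - t_ma) + 0.5 * pub["AI_inv"]
    p_range = (0.12 * pub["P_MA"] + 40.0 - 1.5 * pub["P_DM"]
               - 5.0 * (pub["latitude"] + 32.5))
    out = pd.DataFrame({
        "population": pub["population"],
        "T_MAX": pub["T_MAX"],
        "P_MA": pub["P_MA"],
        "P_DM": pub["P_DM"],
        "AI_inv": pub["AI_inv"],
        "T_MA": t_ma,
        "T_RANGE": t_range,
        "P_RANGE": p_range,
    }).set_index("population")
    return out[list(CLIMATE_VARIABLES)]


def _corr_chol(C: np.ndarray | None, k: int) -> np.ndarray:
    if C is None:
        return np.eye(k)
    # tolerate PSD-but-singular matrices via eigen square root
    w, v = np.linalg.eigh(C)
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def _correlated_normal(rng: np.random.Generator, n: int,
                       sds: np.ndarray, L: np.ndarray) -> np.ndarray:
    """n draws of a k-vector with unit-marginal correlation L L^T,
    scaled by per-trait sds."""
    return (rng.standard_normal((n, len(sds))) @ L.T) * sds


def simulate_plantation(config: SimulationConfig, seed: int = 0) -> SyntheticDataset:
    """Draw a complete plantation data set from the configured model.

    Replicates of each family are assigned to blocks cyclically, so a
    family with 12 replicates over 6 blocks contributes 2 trees per
    block and one with 4 replicates appears in 4 of the 6 blocks.
    """
    rng = np.random.default_rng(seed)
    traits = list(config.traits)
    k = len(traits)
    models = list(config.traits.values())
    climate = config.population_climate
    if climate is None:
        climate = default_population_climate(config.n_populations)
    pops = list(climate.index.astype(str))[:config.n_populations]

    # deterministic climate-driven population means
    z = (climate - climate.mean()) / climate.std(ddof=0).replace(0, 1.0)
    pop_means = np.zeros((config.n_populations, k))
    for t, (name, m) in enumerate(config.traits.items()):
        pop_means[:, t] = m.mu
        for var, slope in m.climate_slopes.items():
            pop_means[:, t] += slope * z[var].to_numpy()[:config.n_populations]
        if m.climate_response is not None:
            for p in range(config.n_populations):
                cvs = ClimateVariableSet(
                    {v: float(climate.iloc[p][v]) for v in CLIMATE_VARIABLES})
                pop_means[p, t] += m.climate_response(cvs)
    # random population deviations (independent across traits)
    pop_sds = np.array([np.sqrt(m.sigma2_pop) for m in models])
    pop_means = pop_means + rng.standard_normal((config.n_populations, k)) * pop_sds

    block_sds = np.array([np.sqrt(m.sigma2_block) for m in models])
    block_eff = rng.standard_normal((config.n_blocks, k)) * block_sds

    n_fam = config.n_populations * config.families_per_population
    fam_sds = np.array([np.sqrt(m.sigma2_fam) for m in models])
    Lg = _corr_chol(config.genetic_corr, k)
    fam_eff = _correlated_normal(rng, n_fam, fam_sds, Lg)

    fb_sds = np.array([np.sqrt(m.sigma2_famblock) for m in models])
    fb_eff = rng.standard_normal((n_fam, config.n_blocks, k)) * fb_sds

    err_sds = np.array([np.sqrt(m.sigma2_err) for m in models])
    Le = _corr_chol(config.residual_corr, k)

    rows = []
    values = []
    tree = 0
    for p, pop in enumerate(pops):
        for f in range(config.families_per_population):
            fam_idx = p * config.families_per_population + f
            fam_label = f"{pop}_F{f + 1:02d}"
            for r in range(config.replicates_per_family):
                b = r % config.n_blocks
                tree += 1
                rows.append({"tree_id": f"T{tree:05d}", "block": f"B{b + 1}",
                             "population": pop, "family": fam_label})
                values.append(pop_means[p] + block_eff[b] + fam_eff[fam_idx]
                              + fb_eff[fam_idx, b])
    vals = np.array(values)
    vals = vals + _correlated_normal(rng, len(vals), err_sds, Le)
    df = pd.DataFrame(rows)
    for t, name in enumerate(traits):
        df[name] = vals[:, t]
    fam_labels = [f"{pop}_F{f + 1:02d}" for pop in pops
                  for f in range(config.families_per_population)]
    return SyntheticDataset(
        table=TraitTable(df, traits),
        true_population_means=pd.DataFrame(pop_means, index=pops, columns=traits),
        true_family_effects=pd.DataFrame(fam_eff, index=fam_labels, columns=traits),
        true_block_effects=pd.DataFrame(
            block_eff, index=[f"B{b + 1}" for b in range(config.n_blocks)],
            columns=traits),
        config=config, seed=seed)


def dataset1_config(**kwargs) -> SimulationConfig:
    """Heritability data set: 4 populations x 10 families x 12
    replicates over 6 blocks (480 trees)."""
    kwargs.setdefault("n_populations", 4)
    kwargs.setdefault("families_per_population", 10)
    kwargs.setdefault("replicates_per_family", 12)
    return SimulationConfig(**kwargs)


def dataset2_config(**kwargs) -> SimulationConfig:
    """Modelling data set: 12 populations x 10 families x 4 replicates
    over 6 blocks (480 trees)."""
    kwargs.setdefault("n_populations", 12)
    kwargs.setdefault("families_per_population", 10)
    kwargs.setdefault("replicates_per_family", 4)
    return SimulationConfig(**kwargs)


def synthetic_population_climate(n_populations: int = 12, seed: int = 0,
                                 cross_corr: float = 0.4) -> pd.DataFrame:
    """A synthetic population climate table with controlled correlation.

    T_MAX runs along a gradient across populations; every other
    variable is ``cross_corr`` correlated with it (in expectation) and
    otherwise independent, then mapped onto realistic regional scales.
    Use this for driver-recovery experiments: the published climate
    table contains near-collinear pairs (T_MA and T_MAX at r ~ 0.97)
    for which no selector can attribute a signal to one member.
    """
    rng = np.random.default_rng(seed)
    n = n_populations
    zt = np.linspace(-1.5, 1.5, n)
    rng.shuffle(zt)
    rho = float(cross_corr)
    scales = {"T_MA": (16.5, 2.2), "T_RANGE": (14.0, 1.2),
              "P_MA": (850.0, -230.0), "P_DM": (15.0, -7.0),
              "P_RANGE": (120.0, -25.0), "AI_inv": (1.6, 0.55)}
    cols = {"T_MAX": 28.8 + 2.6 * zt}
    for var, (center, load) in scales.items():
        z = rho * zt + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        cols[var] = center + load * z
    df = pd.DataFrame(cols, index=[f"P{i + 1:02d}" for i in range(n)])
    df["P_DM"] = df["P_DM"].clip(lower=1.0)
    df["AI_inv"] = df["AI_inv"].clip(lower=0.3)
    df.index.name = "population"
    return df[list(CLIMATE_VARIABLES)]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

#: anchor wavelengths (nm) of the smooth base leaf spectrum
_SPECTRUM_ANCHORS = (350.0, 445.0, 500.0, 531.0, 570.0, 620.0, 680.0,
                     705.0, 750.0, 800.0, 1100.0, 1400.0, 1900.0, 2500.0)


def simulate_spectra(target_pri: float, target_ndvi: float, n_leaves: int = 3,
                     noise_sd: float = 0.0, seed: int = 0,
                     wavelength_range: tuple[int, int] = (350, 2500),
                     tree_id: str = "T00001") -> list[ReflectanceSpectrum]:
    """Construct leaf spectra whose band values solve the two index
    equations exactly, plus optional band-wise Gaussian noise (%).

    The PRI bands are set to R531 = c(1+p), R570 = c(1-p) around a
    green-reflectance level c; the red-edge bands solve the mND705
    equation for the target given fixed R445 and R705.  A smooth
    monotone (PCHIP) curve through physiologically plausible anchors
    fills the rest of the spectrum.
    """
    if not -1.0 < target_pri < 1.0:
        raise ConfigError("target PRI must lie in (-1, 1)")
    if target_ndvi >= 1.0:
        raise ConfigError("target mND705 must be < 1 for positive reflectance")
    c, r445, r705 = 8.0, 3.5, 12.0
    r531 = c * (1.0 + target_pri)
    r570 = c * (1.0 - target_pri)
    r750 = (r705 * (1.0 + target_ndvi) - 2.0 * target_ndvi * r445) / (1.0 - target_ndvi)
    if r750 <= 0 or r750 > 100:
        raise ConfigError(f"target mND705 {target_ndvi} gives R750 = {r750:.1f}%")
    anchor_vals = {350.0: 4.0, 445.0: r445, 500.0: 6.5, 531.0: r531,
                   570.0: r570, 620.0: 7.0, 680.0: 5.0, 705.0: r705,
                   750.0: r750, 800.0: r750 * 1.03, 1100.0: 48.0,
                   1400.0: 35.0, 1900.0: 12.0, 2500.0: 8.0}
    curve = PchipInterpolator(list(_SPECTRUM_ANCHORS),
                              [anchor_vals[a] for a in _SPECTRUM_ANCHORS])
    lo, hi = wavelength_range
    grid = np.arange(lo, hi + 1, dtype=float)
    base = curve(grid)
    rng = np.random.default_rng(seed)
    out = []
    for leaf in range(n_leaves):
        refl = base + (rng.standard_normal(len(grid)) * noise_sd
                       if noise_sd > 0 else 0.0)
        out.append(ReflectanceSpectrum(grid.copy(), refl, tree_id=tree_id,
                                       leaf_id=f"L{leaf + 1}"))
    return out


# ---------------------------------------------------------------------------
# climate rasters
# ---------------------------------------------------------------------------


def simulate_climate_rasters(
        n_rows: int, n_cols: int,
        gradients: Mapping[str, tuple[float, float, float]],
        future_offsets: Mapping[str, float] | None = None,
        mask: np.ndarray | None = None,
) -> tuple[dict[str, RasterGrid], dict[str, RasterGrid], RasterGrid]:
    """Co-registered current and future climate stacks plus a
    distribution mask.

    ``gradients[var] = (base, per_col, per_row)`` defines the current
    affine field; the future layer adds ``future_offsets.get(var, 0)``
    everywhere (e.g. +T, -P for a hotter, drier 2070).  ``mask`` marks
    distribution cells (True = inside); default all inside.
    """
    if n_rows < 1 or n_cols < 1:
        raise ConfigError("raster dimensions must be positive")
    future_offsets = dict(future_offsets or {})
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    current: dict[str, RasterGrid] = {}
    future: dict[str, RasterGrid] = {}
    for var, (base, dx, dy) in gradients.items():
        field_now = base + dx * jj + dy * ii
        current[var] = RasterGrid(field_now.astype(float), scenario="current")
        future[var] = RasterGrid(field_now + future_offsets.get(var, 0.0),
                                 scenario="future")
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    mask_grid = RasterGrid(mask.astype(float), scenario="distribution")
    return current, future, mask_grid


def gradients_spanning(climate: pd.DataFrame,
                       variables: Sequence[str],
                       n_rows: int, n_cols: int,
                       margin: float = 0.0) -> dict[str, tuple[float, float, float]]:
    """Affine gradient specs whose fields span each variable's range in
    a population climate table (column direction), so predictions stay
    inside the training range when ``margin=0``."""
    out = {}
    for var in variables:
        lo, hi = float(climate[var].min()), float(climate[var].max())
        span = hi - lo
        lo -= margin * span
        hi += margin * span
        out[var] = (lo, (hi - lo) / max(n_cols - 1, 1), 0.0)
    return out
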