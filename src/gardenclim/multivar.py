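"""Family-mean multivariate analyses: PCA over traits (optionally with
climate-of-origin variables) and pairwise trait regressions.

Working on family means rather than tree-level records removes most of
the within-family environmental noise, so the patterns reflect the
genetic component of trait (co)variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitTable

logger = logging.getLogger("gardenclim")


@dataclass
class PcaResult:
    """Principal components of the family-mean matrix.

    ``loadings`` has one column per axis (rows = variables), ``scores``
    one row per family; ``explained`` is percent variance per axis and
    sums to 100 over all axes.  Axis signs follow the convention that
    the largest-magnitude loading on each axis is positive.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: np.ndarray
    standardized: bool
    center: np.ndarray
    scale: np.ndarray


@dataclass
class TraitPairRegression:
    """OLS of one trait's family means on another's."""

    x: str
    y: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def family_means(table: TraitTable, columns: list[str] | None = None,
                 min_replicates: int = 1) -> pd.DataFrame:
    """Arithmetic mean per family of each trait column.

    Returns a frame indexed by family with a ``population`` column and
    one column per trait.  A family with zero non-missing values for a
    requested trait gets NaN there (and is dropped later by
    complete-case filtering); replicate counts are logged.
    """
    cols = columns or table.trait_names
    grp = table.data.groupby("family", observed=True)
    out = grp[cols].mean()
    out.insert(0, "population", grp["population"].first())
    counts = grp[cols].count()
    n_empty = int((counts == 0).to_numpy().sum())
    if n_empty:
        logger.warning("family_means: %d family x trait cells have no data", n_empty)
    small = counts.min(axis=1)
    keep = small >= min_replicates
    logger.info("family_means: %d families, replicates %d-%d",
                len(out), int(small.min()), int(counts.max().max()))
    return out.loc[keep]


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a family-mean matrix (numeric columns only).

    With ``standardize=True`` (the default — the traits have
    incommensurate units) columns are centred and scaled to unit
    variance, i.e. a correlation-matrix PCA.
    """
    num = matrix.select_dtypes(include=[np.number]).dropna()
    if num.shape[0] < 3 or num.shape[1] < 2:
        raise ValueError("need >= 3 complete rows and >= 2 numeric columns")
    Xc = num.to_numpy(dtype=float)
    center = Xc.mean(axis=0)
    Xc = Xc - center
    if standardize:
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = num.columns[scale == 0][0]
            raise ValueError(f"constant column {bad!r} cannot be standardized")
    else:
        scale = np.ones(Xc.shape[1])
    Xc = Xc / scale
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive per axis
    for a in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[a]))
        if vt[a, i] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    var = s ** 2 / (Xc.shape[0] - 1)
    explained = 100.0 * var / var.sum()
    axes = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=num.columns, columns=axes)
    scores = pd.DataFrame(u * s, index=num.index, columns=axes)
    return PcaResult(loadings=loadings, scores=scores, explained=explained,
                     standardized=standardize, center=center, scale=scale)


def fit_trait_pair(matrix: pd.DataFrame, x: str, y: str) -> TraitPairRegression:
    """OLS regression of family-mean trait ``y`` on trait ``x``."""
    sub = matrix[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete family-mean pairs")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.var(xv) == 0:
        raise ValueError(f"zero variance in {x!r}")
    res = stats.linregress(xv, yv)
    return TraitPairRegression(x=x, y=y, slope=float(res.slope),
                               intercept=float(res.intercept),
                               r2=float(res.rvalue ** 2),
                               p_value=float(res.pvalue), n=len(sub))


#: the four trait pairs examined for correlation/coordination
DEFAULT_TRAIT_PAIRS = (("d13C", "PRI"), ("LS", "NDVI"),
                       ("WD", "N_CONC"), ("SLA", "N_CONC"))


def trait_pair_report(matrix: pd.DataFrame,
                      pairs=DEFAULT_TRAIT_PAIRS) -> pd.DataFrame:
    rows = []
    for x, y in pairs:
        r = fit_trait_pair(matrix, x, y)
        rows.append({"x": x, "y": y, "slope": r.slope, "intercept": r.intercept,
                     "r2": r.r2, "p_value": r.p_value, "n": r.n})
    return pd.DataFrame(rows)


def biplot(result: PcaResult, ax=None, population: pd.Series | None = None):
    """Plain PCA biplot: family scores as points, loadings as arrows.

    Requires matplotlib (the ``plot`` extra); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = result.scores
    if population is not None:
        for pop, grp in sc.groupby(population):
            ax.scatter(grp["PC1"], grp["PC2"], s=12, label=str(pop))
        ax.legend(fontsize="small")
    else:
        ax.scatter(sc["PC1"], sc["PC2"], s=12)
    span = np.abs(sc[["PC1", "PC2"]].to_numpy()).max()
    for var, row in result.loadings.iterrows():
        ax.annotate("", xy=(row["PC1"] * span, row["PC2"] * span),
                    xytext=(0, 0), arrowprops={"arrowstyle": "->"})
        ax.text(row["PC1"] * span * 1.05, row["PC2"] * span * 1.05, str(var),
                fontsize="small")
    ax.set_xlabel(f"PC1 ({result.explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.explained[1]:.1f}%)")
    return ax
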