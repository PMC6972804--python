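"""REML variance components, narrow-sense heritability, and population
differentiation for the half-sib common-garden design.

The heritability model is the all-random univariate model

    y_ijkl = mu + b_i + p_j + f_j.k + (b x f)_i.jk + e_ijkl

with independent Gaussian random effects for block, population,
family-within-population, block x family, and residual.  Narrow-sense
heritability is estimated from the family variance component with a
mixed-mating multiplier,

    h^2 = 2.5 * s2_fam / (s2_fam + s2_famxblock + s2_err),

where rho = 1/2.5 is the assumed coefficient of relationship for
open-pollinated eucalypt families with roughly 30% selfing; under pure
half-sibs the multiplier would be 4.  The denominator deliberately
excludes the block and population components.

Estimation is REML with an EM warm start followed by average-information
(AI) updates; components are constrained non-negative by clamping at a
small floor, and a clamped component is reported as a boundary zero.
Significance of the family component uses a likelihood-ratio test with
the boundary-corrected 0.5*chi2_0 + 0.5*chi2_1 reference mixture.

Population differentiation refits the model with population as a fixed
effect (family random), then performs all-pairs Tukey comparisons and
summarises them as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, lapack

from .io import TraitTable

DEFAULT_RANDOM_TERMS = ("block", "population", "family", "block:family")


class ConvergenceError(RuntimeError):
    """REML failed to converge within the iteration cap."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class DesignError(ValueError):
    """The plantation design cannot identify the requested model."""


@dataclass(frozen=True)
class RandomModelSpec:
    """Random terms of the univariate model, named by design column.

    ``"block:family"`` denotes the interaction cell.  Every term enters
    once; the residual is implicit.
    """

    terms: tuple[str, ...] = DEFAULT_RANDOM_TERMS

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate random term")


@dataclass
class VarianceComponents:
    """REML estimates of the five random components (trait units squared).

    ``cov`` is the asymptotic covariance of the component vector in the
    order (block, pop, fam, famblock, err) from the inverse average
    information, with boundary components set to NaN rows/columns.
    """

    sigma2_block: float
    sigma2_pop: float
    sigma2_fam: float
    sigma2_famblock: float
    sigma2_err: float
    reml_loglik: float
    cov: np.ndarray
    converged: bool
    n_iterations: int
    boundary: dict[str, bool] = field(default_factory=dict)
    n_obs: int = 0

    COMPONENT_ORDER = ("block", "population", "family", "block:family", "residual")

    def as_dict(self) -> dict[str, float]:
        return {"sigma2_block": self.sigma2_block,
                "sigma2_pop": self.sigma2_pop,
                "sigma2_fam": self.sigma2_fam,
                "sigma2_famblock": self.sigma2_famblock,
                "sigma2_err": self.sigma2_err}


@dataclass
class HeritabilityEstimate:
    """Narrow-sense heritability with delta-method SE and family LRT."""

    h2: float
    se_h2: float
    multiplier: float = 2.5
    lrt_stat: float | None = None
    p_value: float | None = None
    boundary: bool = False


@dataclass
class PopulationComparison:
    """All-pairs Tukey comparison of population means.

    ``pairs`` has one row per unordered pair with the difference
    estimate, SE, t, unadjusted and single-step adjusted p; ``letters``
    is the compact letter display (populations sharing a letter are not
    significantly different at ``alpha``).
    """

    means: pd.Series
    pairs: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05
    df_resid: float = np.nan


# ---------------------------------------------------------------------------
# the REML engine
# ---------------------------------------------------------------------------


def _group_codes(labels: Sequence) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.intp), len(uniques)


class _RemlProblem:
    """y = X beta + sum_i Z_i u_i + e with u_i ~ N(0, s2_i I)."""

    def __init__(self, y: np.ndarray, term_codes: list[np.ndarray],
                 X: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self.codes = term_codes
        self.q = [int(c.max()) + 1 for c in term_codes]
        self.X = np.ones((self.n, 1)) if X is None else np.asarray(X, dtype=float)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("fixed-effect design is rank deficient")
        # dense n x n relationship matrix per term (same-level indicator)
        self.G = [(c[:, None] == c[None, :]).astype(float) for c in term_codes]

    def _evaluate(self, theta: np.ndarray) -> dict:
        """Build V(theta), the REML projector P, log-likelihood, score
        and average-information matrix."""
        n, X = self.n, self.X
        V = theta[-1] * np.eye(n)
        for t, G in zip(theta[:-1], self.G):
            V += t * G
        L, info = lapack.dpotrf(V, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError("V is not positive definite")
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vinv, info = lapack.dpotri(L, lower=1, overwrite_c=1)
        if info != 0:
            raise np.linalg.LinAlgError("inversion of V failed")
        ix = np.triu_indices(n, 1)
        Vinv[ix] = Vinv.T[ix]  # dpotri fills one triangle only
        W = Vinv @ X
        XtVinvX = X.T @ W
        cx = cho_factor(XtVinvX, lower=True)
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        P = Vinv - W @ cho_solve(cx, W.T)
        Py = P @ self.y
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetX + yPy)
        # G_i Py via per-level sums; residual term last
        M = np.empty((n, len(theta)))
        trPG = np.empty(len(theta))
        for i, (codes, G) in enumerate(zip(self.codes, self.G)):
            s = np.bincount(codes, weights=Py, minlength=self.q[i])
            M[:, i] = s[codes]
            trPG[i] = float(np.einsum("ij,ij->", P, G))
        M[:, -1] = Py
        trPG[-1] = float(np.trace(P))
        yPGPy = Py @ M
        score = 0.5 * (yPGPy - trPG)
        AI = 0.5 * (M.T @ (P @ M))
        return {"ll": ll, "score": score, "AI": AI, "P": P, "Py": Py,
                "beta_cov": cho_solve(cx, np.eye(X.shape[1])),
                "beta": cho_solve(cx, X.T @ (Vinv @ self.y))}

    def fit(self, em_iterations: int = 10, max_iterations: int = 200,
            ll_tol: float = 1e-8, par_tol: float = 1e-6) -> dict:
        vary = float(np.var(self.y, ddof=1))
        if vary == 0:
            raise DesignError("response has zero variance")
        floor = 1e-10 * vary
        k = len(self.G) + 1
        theta = np.full(k, vary / k)
        state = self._evaluate(theta)
        trace = [state["ll"]]
        q = np.array(self.q + [self.n], dtype=float)
        converged = False
        it = 0
        for it in range(1, max_iterations + 1):
            if it <= em_iterations:
                new = theta + theta ** 2 * (2.0 * state["score"]) / q
                new = np.maximum(new, floor)
                new_state = self._evaluate(new)
            else:
                free = theta > floor * 10
                delta = np.zeros(k)
                AI = state["AI"][np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(AI, state["score"][free])
                except np.linalg.LinAlgError:
                    delta[free] = np.linalg.lstsq(AI, state["score"][free],
                                                  rcond=None)[0]
                step = 1.0
                for _ in range(12):
                    new = np.maximum(theta + step * delta, floor)
                    new_state = self._evaluate(new)
                    if new_state["ll"] >= state["ll"] - 1e-12:
                        break
                    step *= 0.5
                else:  # AI step failed; fall back to one EM step
                    new = np.maximum(
                        theta + theta ** 2 * (2.0 * state["score"]) / q, floor)
                    new_state = self._evaluate(new)
            dll = abs(new_state["ll"] - state["ll"])
            dpar = np.max(np.abs(new - theta)) / vary
            theta, state = new, new_state
            trace.append(state["ll"])
            if it > em_iterations and dll < ll_tol * (1.0 + abs(state["ll"])) \
                    and dpar < par_tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {max_iterations} iterations", trace)
        boundary = theta <= floor * 10
        cov = np.full((k, k), np.nan)
        free = ~boundary
        if free.any():
            AI = state["AI"][np.ix_(free, free)]
            cov[np.ix_(free, free)] = np.linalg.pinv(AI)
        theta = np.where(boundary, 0.0, theta)
        return {"theta": theta, "loglik": state["ll"], "cov": cov,
                "boundary": boundary, "n_iterations": it,
                "beta": state["beta"], "beta_cov": state["beta_cov"]}


def _term_codes(table: TraitTable, terms: Sequence[str],
                rows: np.ndarray) -> list[np.ndarray]:
    df = table.data.loc[rows]
    codes = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            labels = df[a].astype(str) + "\x1f" + df[b].astype(str)
        else:
            labels = df[term].astype(str)
        codes.append(_group_codes(labels)[0])
    return codes


def fit_random_model(table: TraitTable, trait: str,
                     spec: RandomModelSpec | None = None,
                     **fit_kwargs) -> VarianceComponents:
    """REML fit of the all-random univariate model for one trait.

    Complete cases only; requires >= 2 blocks and >= 2 families in
    >= 2 populations.  Deterministic: fixed starting values (equal
    split of the phenotypic variance) and a fixed convergence rule.
    """
    spec = spec or RandomModelSpec()
    df = table.data
    ok = df[trait].notna().to_numpy()
    if (~ok).any():
        logging.getLogger("gardenclim").info(
            "fit_random_model(%s): %d of %d trees missing, complete-case",
            trait, int((~ok).sum()), len(ok))
    rows = df.index[ok]
    sub = df.loc[rows]
    if sub["block"].nunique() < 2:
        raise DesignError("need >= 2 blocks")
    if sub["population"].nunique() < 2 or sub["family"].nunique() < 4:
        raise DesignError("need >= 2 families in each of >= 2 populations")
    y = sub[trait].to_numpy(dtype=float)
    problem = _RemlProblem(y, _term_codes(table, spec.terms, rows))
    res = problem.fit(**fit_kwargs)
    names = list(spec.terms) + ["residual"]
    th = dict(zip(names, res["theta"]))
    return VarianceComponents(
        sigma2_block=th.get("block", 0.0),
        sigma2_pop=th.get("population", 0.0),
        sigma2_fam=th.get("family", 0.0),
        sigma2_famblock=th.get("block:family", 0.0),
        sigma2_err=th["residual"],
        reml_loglik=res["loglik"],
        cov=res["cov"],
        converged=True,
        n_iterations=res["n_iterations"],
        boundary=dict(zip(names, res["boundary"])),
        n_obs=len(y))


def heritability(vc: VarianceComponents,
                 multiplier: float = 2.5) -> HeritabilityEstimate:
    """h^2 with first-order delta-method SE from the component covariance.

    The denominator is s2_fam + s2_famxblock + s2_err only; block and
    population variance are excluded by construction.
    """
    sf, sfb, se = vc.sigma2_fam, vc.sigma2_famblock, vc.sigma2_err
    denom = sf + sfb + se
    if denom <= 0:
        raise ValueError("zero phenotypic denominator")
    h2 = multiplier * sf / denom
    # gradient wrt (s2_fam, s2_famblock, s2_err)
    g = multiplier / denom ** 2 * np.array([denom - sf, -sf, -sf])
    idx = [2, 3, 4]  # positions in the (block, pop, fam, famblock, err) order
    cov = vc.cov[np.ix_(idx, idx)]
    cov = np.where(np.isnan(cov), 0.0, cov)  # boundary components: no variance
    var_h2 = float(g @ cov @ g)
    return HeritabilityEstimate(h2=h2, se_h2=float(np.sqrt(max(var_h2, 0.0))),
                                multiplier=multiplier,
                                boundary=vc.boundary.get("family", False))


def lrt_family(vc_full: VarianceComponents, table: TraitTable, trait: str,
               spec: RandomModelSpec | None = None,
               mixture: bool = True) -> tuple[float, float]:
    """Likelihood-ratio test of the family variance component.

    Refits the model without the family term; the statistic
    2*(ll_full - ll_reduced) is referred to the boundary mixture
    0.5*chi2_0 + 0.5*chi2_1 (``mixture=False`` switches to plain
    chi2_1).  At a boundary estimate the statistic is 0 and the
    mixture p-value is 0.5.
    """
    spec = spec or RandomModelSpec()
    reduced_terms = tuple(t for t in spec.terms if t != "family")
    reduced = fit_random_model(table, trait, RandomModelSpec(reduced_terms))
    stat = max(0.0, 2.0 * (vc_full.reml_loglik - reduced.reml_loglik))
    p = float(stats.chi2.sf(stat, 1))
    if mixture:
        p = 0.5 if stat == 0.0 else 0.5 * p
    return stat, p


def estimate_heritability(table: TraitTable, trait: str,
                          multiplier: float = 2.5,
                          spec: RandomModelSpec | None = None,
                          lrt: bool = True) -> tuple[VarianceComponents, HeritabilityEstimate]:
    """Convenience wrapper: REML fit, h^2 with SE, and the family LRT."""
    vc = fit_random_model(table, trait, spec)
    est = heritability(vc, multiplier)
    if lrt:
        est.lrt_stat, est.p_value = lrt_family(vc, table, trait, spec)
    return vc, est


# ---------------------------------------------------------------------------
# population differentiation
# ---------------------------------------------------------------------------


def _compact_letters(pops: list[str], means: pd.Series,
                     significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Populations sharing a letter are not significantly different; the
    letter sets are built by splitting on each significant pair and
    absorbing subsets, with populations ordered by mean.
    """
    order = list(means.sort_values().index)
    sets: list[set[str]] = [set(pops)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        sets = [s for s in new_sets if s]
        # absorb subsets
        sets = [s for s in sets
                if not any(s < t for t in sets)]
        # deduplicate
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(order.index(p) for p in s))
    letters = {p: "" for p in pops}
    for letter, s in zip(string.ascii_lowercase, sets):
        for p in order:
            if p in s:
                letters[p] += letter
    return letters


def diff_populations(table: TraitTable, trait: str, alpha: float = 0.05,
                     include_block: bool = False) -> PopulationComparison:
    """Mixed model with fixed population and random family, followed by
    all-pairs Tukey comparisons.

    The adjusted p-values use the single-step studentized-range
    probability on sqrt(2)*|t| — the classical Tukey correction, equal
    to the max-|t| multivariate-t adjustment for balanced designs.
    Denominator df follow the containment rule
    n_populations * (mean families per population - 1).
    """
    df = table.data
    ok = df[trait].notna().to_numpy()
    rows = df.index[ok]
    sub = df.loc[rows]
    pops = sorted(sub["population"].astype(str).unique())
    if len(pops) < 2:
        raise DesignError("need >= 2 populations")
    fam_per_pop = sub.groupby("population", observed=True)["family"].nunique()
    if (fam_per_pop < 2).any():
        raise DesignError("need >= 2 families per population")
    y = sub[trait].to_numpy(dtype=float)
    pop_codes, _ = _group_codes(sub["population"].astype(str))
    X = np.zeros((len(y), len(pops)))
    X[np.arange(len(y)), pop_codes] = 1.0  # cell-means parameterisation
    terms = ["family"] + (["block"] if include_block else [])
    problem = _RemlProblem(y, _term_codes(table, terms, rows), X=X)
    res = problem.fit()
    beta, beta_cov = res["beta"], res["beta_cov"]
    means = pd.Series(beta, index=pops, name=trait)
    k = len(pops)
    df_resid = k * (float(fam_per_pop.mean()) - 1.0)
    recs = []
    significant: dict[tuple[str, str], bool] = {}
    for i, j in itertools.combinations(range(k), 2):
        diff = beta[i] - beta[j]
        se = float(np.sqrt(beta_cov[i, i] + beta_cov[j, j] - 2 * beta_cov[i, j]))
        t = diff / se
        p_un = 2.0 * float(stats.t.sf(abs(t), df_resid))
        p_adj = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df_resid))
        p_adj = min(1.0, max(p_adj, p_un))  # single-step p dominates the raw p
        recs.append({"pop_a": pops[i], "pop_b": pops[j], "estimate": diff,
                     "se": se, "t": t, "p_unadj": p_un, "p_adj": p_adj})
        significant[(pops[i], pops[j])] = p_adj < alpha
    pairs = pd.DataFrame(recs)
    letters = _compact_letters(pops, means, significant)
    return PopulationComparison(means=means, pairs=pairs, letters=letters,
                                alpha=alpha, df_resid=df_resid)
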