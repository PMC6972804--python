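import numpy as np
import pandas as pd
import pytest

import gardenclim as gc
from gardenclim.varcomp import DesignError, RandomModelSpec, _RemlProblem


def balanced_family_design(sigma2_fam, sigma2_err, n_fam=30, n_rep=10, seed=0):
    """One-way balanced half-sib layout with two populations and two
    blocks so the standard model is identifiable."""
    rng = np.random.default_rng(seed)
    rows = []
    fam_eff = rng.normal(0, np.sqrt(sigma2_fam), n_fam)
    t = 0
    for f in range(n_fam):
        pop = "A" if f < n_fam // 2 else "B"
        for r in range(n_rep):
            t += 1
            rows.append({"tree_id": f"t{t}", "block": f"B{r % 2 + 1}",
                         "population": pop, "family": f"F{f:02d}",
                         "y": fam_eff[f] + rng.normal(0, np.sqrt(sigma2_err))})
    return gc.TraitTable(pd.DataFrame(rows), ["y"])


def anova_family_estimates(table):
    """Closed-form method-of-moments estimators for the balanced
    one-way family model: s2_fam = (MS_between - MS_within)/n."""
    df = table.data
    n = df.groupby("family")["y"].size().iloc[0]
    fam_means = df.groupby("family")["y"].mean()
    grand = df["y"].mean()
    k = len(fam_means)
    ms_between = n * ((fam_means - grand) ** 2).sum() / (k - 1)
    ms_within = ((df["y"] - df["family"].map(fam_means)) ** 2).sum() / (len(df) - k)
    return (ms_between - ms_within) / n, ms_within


class TestRemlEngine:
    def test_matches_anova_on_balanced_family_design(self):
        """For a balanced one-way design REML equals the closed-form
        ANOVA estimator when the estimate is interior."""
        table = balanced_family_design(2.0, 5.0, seed=3)
        codes = [pd.factorize(table.data["family"])[0]]
        res = _RemlProblem(table.data["y"].to_numpy(), codes).fit()
        s2_fam_anova, s2_err_anova = anova_family_estimates(table)
        assert res["theta"][0] == pytest.approx(s2_fam_anova, abs=1e-6)
        assert res["theta"][1] == pytest.approx(s2_err_anova, abs=1e-6)

    def test_zero_variance_data_lands_on_boundary(self):
        cfg = gc.dataset1_config(traits={"y": gc.TraitModel(
            mu=5, sigma2_block=0, sigma2_pop=0, sigma2_fam=0,
            sigma2_famblock=0, sigma2_err=4.0)})
        ds = gc.simulate_plantation(cfg, seed=2)
        vc = gc.fit_random_model(ds.table, "y")
        assert vc.sigma2_fam == 0.0 and vc.boundary["family"]
        assert vc.sigma2_pop == 0.0
        sample_var = ds.table.data["y"].var(ddof=1)
        assert vc.sigma2_err == pytest.approx(sample_var, rel=0.05)

    def test_location_invariance_and_scale_equivariance(self, dataset1):
        vc = gc.fit_random_model(dataset1.table, "WD")
        shifted = dataset1.table.with_trait("WD", dataset1.table.data["WD"] + 100.0)
        vc_shift = gc.fit_random_model(shifted, "WD")
        for key, val in vc.as_dict().items():
            assert getattr(vc_shift, key) == pytest.approx(val, abs=1e-5 * max(val, 1))
        scaled = dataset1.table.with_trait("WD", dataset1.table.data["WD"] * 3.0)
        vc_scaled = gc.fit_random_model(scaled, "WD")
        assert vc_scaled.sigma2_fam == pytest.approx(9.0 * vc.sigma2_fam, rel=1e-3)
        assert vc_scaled.sigma2_err == pytest.approx(9.0 * vc.sigma2_err, rel=1e-3)

    def test_determinism(self, dataset1):
        a = gc.fit_random_model(dataset1.table, "WD")
        b = gc.fit_random_model(dataset1.table, "WD")
        assert a.as_dict() == b.as_dict()
        assert a.reml_loglik == b.reml_loglik

    def test_design_errors(self, dataset1):
        one_block = dataset1.table.data[dataset1.table.data["block"] == "B1"]
        with pytest.raises(DesignError):
            gc.fit_random_model(gc.TraitTable(one_block.reset_index(drop=True),
                                              ["WD"]), "WD")


class TestHeritability:
    def test_h2_arithmetic(self):
        vc = gc.VarianceComponents(0.2, 0.3, 1.0, 0.5, 8.5, 0.0,
                                   np.zeros((5, 5)), True, 1)
        est = gc.heritability(vc)
        assert est.h2 == pytest.approx(2.5 * 1.0 / 10.0)

    def test_h2_zero_at_family_boundary(self):
        vc = gc.VarianceComponents(0.2, 0.3, 0.0, 0.5, 8.5, 0.0,
                                   np.full((5, 5), np.nan), True, 1,
                                   boundary={"family": True})
        assert gc.heritability(vc).h2 == 0.0

    def test_multiplier_override(self):
        vc = gc.VarianceComponents(0, 0, 1.0, 0.5, 8.5, 0.0,
                                   np.zeros((5, 5)), True, 1)
        assert gc.heritability(vc, multiplier=4.0).h2 == pytest.approx(0.4)

    def test_delta_se_matches_parametric_resampling(self, dataset1):
        """The delta-method SE should agree with the SD of h^2 over
        parametric draws of the variance components from their
        asymptotic Gaussian."""
        vc = gc.fit_random_model(dataset1.table, "WD")
        est = gc.heritability(vc)
        idx = [2, 3, 4]
        mean = np.array([vc.sigma2_fam, vc.sigma2_famblock, vc.sigma2_err])
        cov = np.where(np.isnan(vc.cov), 0.0, vc.cov)[np.ix_(idx, idx)]
        rng = np.random.default_rng(77)
        draws = rng.multivariate_normal(mean, cov, size=1000)
        keep = (draws.sum(axis=1) > 0)
        h2s = 2.5 * draws[keep, 0] / draws[keep].sum(axis=1)
        assert est.se_h2 == pytest.approx(h2s.std(ddof=1), rel=0.15)


class TestFamilyLrt:
    def test_boundary_gives_stat_zero_p_half(self):
        cfg = gc.dataset1_config(traits={"y": gc.TraitModel(
            sigma2_fam=0.0, sigma2_famblock=0.3, sigma2_err=9.0,
            sigma2_block=0.3, sigma2_pop=0.5)})
        # find a seed where the family estimate is at the boundary
        for seed in range(10):
            ds = gc.simulate_plantation(cfg, seed=seed)
            vc = gc.fit_random_model(ds.table, "y")
            if vc.boundary["family"]:
                break
        else:
            pytest.fail("no boundary replicate found in 10 seeds")
        stat, p = gc.lrt_family(vc, ds.table, "y")
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_strong_family_signal_significant(self, dataset1):
        vc = gc.fit_random_model(dataset1.table, "WD")
        stat, p = gc.lrt_family(vc, dataset1.table, "WD")
        assert stat > 0
        assert p < 0.05

    def test_mixture_halves_chi2_pvalue(self, dataset1):
        vc = gc.fit_random_model(dataset1.table, "WD")
        _, p_mix = gc.lrt_family(vc, dataset1.table, "WD", mixture=True)
        _, p_chi = gc.lrt_family(vc, dataset1.table, "WD", mixture=False)
        assert p_mix == pytest.approx(p_chi / 2)


class TestPopulationDifferentiation:
    def test_extreme_separation_gets_distinct_letters(self):
        cfg = gc.SimulationConfig(
            n_populations=2, families_per_population=8,
            replicates_per_family=6,
            traits={"y": gc.TraitModel(sigma2_pop=0, sigma2_block=0,
                                       sigma2_fam=0.2, sigma2_famblock=0,
                                       sigma2_err=1.0)},
            population_climate=gc.default_population_climate(2))
        ds = gc.simulate_plantation(cfg, seed=5)
        shifted = ds.table.data.copy()
        shifted.loc[shifted["population"] == shifted["population"].iloc[0], "y"] += 10.0
        comp = gc.diff_populations(gc.TraitTable(shifted, ["y"]), "y")
        letters = list(comp.letters.values())
        assert letters[0] != letters[1]

    def test_adjusted_p_not_below_unadjusted(self, dataset1):
        comp = gc.diff_populations(dataset1.table, "WD")
        assert (comp.pairs["p_adj"] >= comp.pairs["p_unadj"] - 1e-12).all()

    def test_letters_consistent_with_significance(self, dataset2):
        comp = gc.diff_populations(dataset2.table, "WD")
        for _, row in comp.pairs.iterrows():
            shared = set(comp.letters[row["pop_a"]]) & set(comp.letters[row["pop_b"]])
            if row["p_adj"] < comp.alpha:
                assert not shared
            else:
                assert shared

    def test_single_population_rejected(self, dataset1):
        sub = dataset1.table.subset_populations(
            [dataset1.table.data["population"].iloc[0]])
        with pytest.raises(DesignError):
            gc.diff_populations(sub, "WD")

    def test_null_pair_shares_letter_usually(self):
        """Two populations with identical distributions should share a
        letter in >= 93% of null replicates at alpha = 0.05."""
        cfg = gc.SimulationConfig(
            n_populations=2, families_per_population=10,
            replicates_per_family=6,
            traits={"y": gc.TraitModel(sigma2_pop=0.0, sigma2_block=0.3,
                                       sigma2_fam=0.5, sigma2_famblock=0.2,
                                       sigma2_err=5.0, climate_slopes={})},
            population_climate=gc.default_population_climate(2))
        share = 0
        n_rep = 200
        for seed in range(n_rep):
            ds = gc.simulate_plantation(cfg, seed=seed)
            comp = gc.diff_populations(ds.table, "y")
            a, b = comp.letters.values()
            share += bool(set(a) & set(b))
        assert share / n_rep >= 0.93
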