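"""Narrow-sense heritability and population differentiation from a
simulated half-sib common-garden trial.

The design mirrors the heritability data set: 4 populations x 10
families x 12 replicate trees over 6 blocks (480 trees).  The trait is
simulated with a true h^2 of 0.20.
"""

import gardenclim as gc

cfg = gc.dataset1_config(traits={
    "WD": gc.trait_model_for_h2(0.20, climate_slopes={"P_DM": 1.0})})
ds = gc.simulate_plantation(cfg, seed=1)

vc, est = gc.estimate_heritability(ds.table, "WD")
print("variance components (REML):")
for name, val in vc.as_dict().items():
    print(f"  {name:18s} {val:7.3f}")
print(f"h^2 = {est.h2:.3f} +/- {est.se_h2:.3f} SE  (multiplier 2.5)")
print(f"family LRT: stat = {est.lrt_stat:.2f}, p = {est.p_value:.4f} "
      "(0.5*chi2_0 + 0.5*chi2_1 mixture)")

comp = gc.diff_populations(ds.table, "WD")
print("\npopulation means and Tukey letters (alpha = 0.05):")
for pop, mean in comp.means.sort_values().items():
    print(f"  {pop:5s} {mean:7.3f}  {comp.letters[pop]}")
print()
print("The estimate recovers the simulated h^2 = 0.20 within its SE;")
print("populations sharing a letter are not significantly different")
print("after the single-step all-pairs adjustment.")
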