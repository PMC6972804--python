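# Methods

This note documents the statistical models implemented in `gardenclim`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
problem left the design genuinely open.

## The half-sib common-garden model

A provenance trial grows families (maternal half-sib seed lots) from
multiple source populations together in one plantation, in replicated
blocks. The univariate all-random model for one trait is

    y_ijkl = μ + b_i + p_j + f_j.k + (b×f)_i.jk + e_ijkl

with independent Gaussian effects: block b, population p, family
within population f, block×family interaction, and residual e.
Narrow-sense heritability is estimated from the family variance:

    h² = m · σ²_fam / (σ²_fam + σ²_fam×block + σ²_err),   m = 2.5.

The multiplier m = 1/ρ comes from the coefficient of relationship
among open-pollinated eucalypt sibs: pure half-sibs give ρ = 1/4, but
with the ~30% selfing typical of a mixed mating system ρ = 1/2.5 is
the standard correction and is the package default (`multiplier` is an
argument). The denominator deliberately excludes block and population
variance: it is the within-population phenotypic variance on which
family selection acts.

### REML algorithm

Variance components are estimated by REML with a deterministic
two-phase scheme: 10 EM iterations to warm-start, then
average-information (AI) updates with step-halving whenever a proposed
step decreases the restricted likelihood. Convergence requires a
relative log-likelihood change below 1e-8 and a maximum component
change below 1e-6 of the phenotypic variance. Components are clamped
at 1e-10 × var(y); a clamped component is reported as a boundary zero
and its row of the asymptotic covariance (the inverse AI matrix on the
interior components) is set to NaN. Starting values split the sample
variance equally across components. The engine was cross-checked
against `lme4::lmer` on identical data (agreement to the printed
precision of both, including boundary fits).

The delta-method SE of h² uses the gradient of h² in
(σ²_fam, σ²_fam×block, σ²_err) and the AI covariance; boundary
components contribute zero variance. Note that with only a few dozen
families the family and block×family components are weakly separated
(two trees per family×block cell), so genuinely boundary REML fits
occur at moderate true h²; they are flagged rather than hidden.

### Family LRT

Significance of σ²_fam uses 2·(ll_full − ll_reduced) where the reduced
model drops the family term. Because the null value lies on the
boundary of the parameter space, the reference distribution is the
mixture 0.5·χ²₀ + 0.5·χ²₁ (so a boundary estimate gives statistic 0
and p = 0.5); `mixture=False` switches to plain χ²₁ for comparability
with software that does not apply the correction. Simulation at the
trial's design size shows the mixture holds the nominal 5% level.

### Population differentiation

The differentiation model treats population as fixed (cell means) and
family as random, mirroring standard practice for provenance
comparisons. All-pairs comparisons use the single-step studentized
range probability on √2·|t| — the classical Tukey adjustment, which
coincides with the max-|t| multivariate-t adjustment for balanced
designs (the trial's designs are balanced) and is slightly
conservative otherwise. Denominator df follow the containment rule
n_pops · (mean families per population − 1). The compact letter
display uses insert-and-absorb: populations sharing a letter are not
significantly different at α = 0.05, and the display is asserted
against the significance matrix in tests.

## Spectral indices

PRI = (R531 − R570)/(R531 + R570) and
mND705 = (R750 − R705)/(R750 + R705 − 2·R445), from % reflectance on a
1-nm grid. The pipeline averages the (typically three) leaf spectra
band-wise first and computes indices from the mean spectrum; the
reverse order gives a different number for these nonlinear ratios and
is not used. Band extraction takes the exact grid value, falling back
to the nearest neighbour within ±2 nm (logged) for instruments with
small gaps. Both indices are ratios, so % versus fractional
reflectance is immaterial; this scale invariance is asserted in tests.

## Leaf and wood traits

Leaf area is foreground-pixel count × (25.4/dpi)² mm². SLA pools the
sampled leaves — areas summed over masses summed — which is the
mass-weighted estimator; a dedicated test documents how it differs
from the mean of per-leaf ratios. Scans are accepted pre-thresholded,
with an Otsu binarization helper for greyscale input. Wood density is
dry mass over water-displacement volume (g/cm³).

## Trait–climate GAMs

The response is the vector of population trait means (n = 12): climate
is constant within a population, so population means are the natural
aggregation level. Each candidate smooth is a natural cubic regression
spline in value-at-knot parameterisation with basis dimension k = 3
(knots at the min, median and max of the training covariate),
penalized by the integrated squared second derivative; the sum-to-zero
constraint is absorbed, leaving two coefficients per term of which the
linear direction is unpenalized. "Smoothness bound three" is thus
read as mgcv's `k = 3` convention — at most ~2 effective df per term —
which is the common reading of that phrase in this toolchain.

Covariates are internally mapped to [0, 1] over their training range,
making the basis construction exactly invariant to affine rescaling of
the inputs; extrapolation beyond the knots is linear, as for natural
splines.

Smoothing parameters are chosen per term by GCV with edf-cost
inflation γ = 1.4, optimized by coordinate-wise golden-section search
on log₁₀λ ∈ [−6, 8] over three sweeps. Plain GCV (γ = 1) demonstrably
undersmooths at n = 12 — winning three-term models carry 6–7 effective
df of pure noise — and γ ≈ 1.4 is the standard published remedy; γ is
an argument for users who want the uncorrected criterion. When the
GCV profile has plateaued at a search bound (the linear limit), λ is
snapped to the bound so the chosen value is reproducible. One
numerical caveat is worth stating: near a GCV optimum the objective is
often flat to ~1e-9 relative while λ wanders ~1e-3 relative, so fitted
values from GCV-chosen smoothing are reproducible under input
reparameterisation only to ~1e-4; with fixed λ they are reproducible
to floating-point accuracy, and the invariance test distinguishes the
two regimes.

Model selection fits all 63 subsets of size 1–3 of the seven climate
variables (T_MA, T_MAX, T_RANGE, P_MA, P_DM, P_RANGE, 1/AI) and
reports both selection quantities practitioners inspect: adjusted R²
(mgcv's reported R²) and deviance explained — for the Gaussian
identity-link family used throughout, identical to variance
explained. Ranking is by adjusted R² with deviance explained as the
first tie-break, then fewer variables, then lexicographic order:
adjusted R² charges a model for its effective df, which matters at
n = 12 where raw deviance systematically rewards three-term models
for chasing noise. An overfit guard raises if
total effective df reaches n (structurally impossible at k = 3 with
≤ 3 terms, and asserted). Per-term F statistics are Wald statistics
on the penalized coefficients using the sandwich covariance
σ̂²(X'X+S)⁻¹X'X(X'X+S)⁻¹, divided by the term's effective df, with
residual df = n − total edf; significance stars at 0.05/0.01. This is
one of several defensible conventions and is documented as this
package's, not as a canonical one.

## Landscape projection

A fitted GAM is evaluated per raster cell over a co-registered climate
stack (row 0 = north, cell-centre registration). Cells where any
selected covariate leaves the fit's training range are still predicted
(linear spline extension) but flagged extrapolated and excluded from
summaries and slope tests by default (`include_extrapolated=True`
retains them). An optional species-distribution mask raster restricts
all analyses to distribution cells; the mask is an input, not
computed.

Proportional change is (future − current)/current per cell. Cells
with |current| below 1e-6 × the 95th percentile of |current| are
marked undefined instead of dividing — PRI crosses zero, so the guard
prevents spurious ±∞. Summaries report mean, range and the shares of
cells increasing/decreasing, over defined non-extrapolated cells.

The decoupling test regresses trait y on trait x over pixels within
each scenario and tests slope equality via the F statistic on the
scenario×x interaction of the stacked regression (algebraically the
two-sample slope z² with pooled variance; the equivalence is asserted
to 1e-9 in tests). Pixels are treated as independent observations —
no spatial-autocorrelation correction — exactly as is conventional for
this descriptive comparison; the caveat is recorded in the test
metadata. When observed population or family means are supplied, the
current spatial slope is also compared against the slope over those
means.

## The synthetic-data generator

`simulate_plantation` draws tree values as
μ + pop(climate) + pop_random + block + family + block×family +
residual, mirroring the fitted model exactly so parameter recovery is
well-posed. Family effects carry the additive signal at variance
σ²_A/2.5; multi-trait draws use a genetic correlation matrix for
family effects and a residual correlation matrix for errors (block
terms independent across traits). Default dimensions mirror the
trial's two data sets — 4 populations × 10 families × 12 replicates
and 12 × 10 × 4, both 480 trees in 6 blocks — and the default
variance components (0.5, 1.0, 0.8, 0.5, 8.7) give h² = 0.20, inside
the 0.08–0.22 band such trials report. Replicates are assigned to
blocks cyclically. Everything is reproducible bit-for-bit from
(config, seed).

The packaged climate-of-origin table carries the published station
values (T_MAX, P_MA, P_DM, 1/AI) for the twelve source populations;
the three untabulated variables (T_MA, T_RANGE, P_RANGE) are derived
deterministically from geography on plausible regional scales. Those
derived layers are strongly correlated with the tabulated ones — as
real bioclim layers are (T_MA ~ T_MAX at r ≈ 0.97). For
driver-recovery experiments that correlation makes "which variable is
the true driver" ill-posed, so `synthetic_population_climate`
generates a 12-population climate table in which every other variable
has controlled moderate correlation (default 0.2) with the T_MAX
gradient; recovery experiments use it, realistic examples use the
published table. Driver-recovery experiments simulate population
means as a smooth curved function of T_MAX (linear plus quadratic
bend) at a 5:1 signal-to-noise ratio: curvature is what distinguishes
the true driver from variables that merely correlate with it, since a
proxy can mimic a linear response through correlation alone but not
the bend.

`simulate_spectra` constructs smooth leaf-like spectra (monotone cubic
through physiological anchor points) whose exact band values solve the
two index equations for requested targets, plus optional band-wise
Gaussian noise. `simulate_climate_rasters` builds co-registered affine
gradient fields with configurable future offsets (e.g. +T, −P for a
hotter, drier 2070) and a distribution mask.

What the generator does **not** emulate: spatial autocorrelation of
the field microenvironment, non-Gaussian trait distributions,
dominance/epistasis, unbalanced family availability, and missing-data
mechanisms. Passing tests therefore demonstrate correctness of the
estimators under the stated Gaussian half-sib model at the study's
design sizes, not robustness to those departures.

## Problem sizes used in validation

The validation experiments run at the study's design dimensions:
heritability recovery over 200 simulated trials of 480 trees,
LRT calibration over 500 null trials, driver recovery over 100
twelve-population data sets, decoupling calibration over 500 repeats
of 1,000 pixels per scenario and power over 100 repeats. These sizes
make each check a few minutes on one CPU; the estimator code is
identical at any size.

## Known limitations

- Multivariate (genetic-correlation) REML is out of scope; genetic
  correlations appear only in the generator.
- The Tukey adjustment is exact for balanced designs only (see above).
- GCV smoothing at n = 12 has high variance even with γ = 1.4;
  model-selection results at this sample size should be read as the
  original analysis intended — descriptive ranking, not inference.
- Raster support covers reading, writing, stacking and masking of
  co-registered grids; reprojection and resampling are out of scope.
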