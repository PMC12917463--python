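# Methods

This note documents the statistical models implemented in `gwdvar`, the
design of the synthetic-data generator, and the numerical and design choices
a maintainer or reviewer would want to audit.

## The mixed-model engine

Every analysis reduces to the Gaussian mixed model

y = Xβ + Σₜ Zₜuₜ + ε, with uₜ ~ N(0, σₜ²I) independent across terms and
ε ~ N(0, σ²I).

Each random term is a random intercept or a random slope for one grouping
factor; nested factors (`family/genus/species`) are expanded into separate
terms keyed on the concatenated levels, and crossed factors (the bibliographic
"source") are simply additional terms.  Two structural assumptions follow
from this parameterisation:

* **Isotropic, independent terms.**  Every term has a single SD; random
  intercepts and random slopes of the same factor are uncorrelated (diagonal
  covariance).  The analyses this package supports report only per-term SDs,
  never intercept–slope correlations, so the diagonal structure is the
  natural estimand — but it makes 0/1-coding of a contrast *slightly*
  non-equivalent under relabelling (swapping the roles of trunk and branch
  changes which level carries the intercept variance).  The fixed contrast
  flips sign to ~1e-4 rather than machine precision; the tests check this
  explicitly.
* **Homoscedastic residual.**  One residual variance across species; the
  per-species distribution-shape assessment (Shapiro–Wilk raw vs log) is the
  diagnostic for this simplification.

### Estimation

REML (default) or ML, by expectation–conditional-maximisation over the
variance components with the residual profiled in the same sweep:

1. With current (σₜ², σ²), solve Henderson's mixed-model equations
   C·[β̂, û] = A'y, where A = [X Z] and C = A'A + diag(0, σ²/σₜ²).
2. E-step totals: E[‖uₜ‖² | y] = ‖ûₜ‖² + σ²·tr(C⁻¹)ₜₜ and
   E[‖ε‖² | y] = ê'ê + σ²[(p+q) − Σₜ (σ²/σₜ²)tr(C⁻¹)ₜₜ] (REML treats β with
   a flat prior; ML conditions on the GLS β̂ and uses the u-block inverse).
3. M-step: σₜ² ← E[‖uₜ‖²]/qₜ, σ² ← E[‖ε‖²]/n.

Each update can only increase the (restricted) likelihood; this monotonicity
is asserted on every iteration, so a numerical fault surfaces as a hard error
rather than a silent mis-fit.  A SQUAREM-style extrapolation on the
log-variance scale accelerates the sweep; an extrapolated step is accepted
only if it does not fall below the two plain EM steps it replaces, preserving
the monotone guarantee.  Typical fits converge in 10–30 solves.

Two linear-algebra paths serve the same interface:

* a **dense path** for arbitrary crossed/nested designs — the (p+q)×(p+q)
  coefficient matrix is assembled from sparse A'A, Cholesky-factored, and the
  diagonal of its inverse obtained from the inverted triangular factor
  (adequate to a few thousand random-effect levels; the full-scale variance
  partition, q ≈ 1 350 at n = 40 500, takes ~2 s);
* a **grouped path** used automatically when all terms share one grouping
  factor (the within/between model: species intercept + per-covariate
  slopes) — the u-block is block-diagonal per species, so a p×p Schur
  complement solves the system in O(n·k²) per iteration.

Both paths are cross-checked against each other and against an independent
dense V-matrix evaluation of the REML criterion
(−½[log|V| + log|X'V⁻¹X| + y'Py + (n−p)log 2π]) in the test suite, and
against statsmodels' `MixedLM` on single-factor models.

### Numerical choices

* Convergence: relative objective change < 1e-8, cap 2 000 iterations
  (non-convergence returns the last iterate flagged `converged=False`).
* Boundary handling: a component whose SD falls below 1e-8 is clamped to 0
  and frozen out of the design (a "singular fit" is a result, not an error).
* Constant response: all components 0, σ floored at numerical epsilon, β by
  OLS.
* Initialisation is deterministic (half the response variance split equally
  across terms), so fits are reproducible and permutation-invariant to
  ~1e-10.
* Fixed-effect SEs come from σ²·(X'V⁻¹X)⁻¹ (the β-block of C⁻¹); component
  SEs from a finite-difference observed information on the log-SD scale with
  a delta-method back-transform.  Components at the zero boundary get NaN
  SEs.
* Likelihood profiling re-optimises the remaining components at each grid
  value of the profiled SD — the package's convergence diagnostic in place
  of sampler-based checks.

## Within/between decomposition

Covariates are z-scored over the modelled records *before* splitting into
species means (between part) and within-species deviations, so β and γ share
the per-global-SD scale and are directly comparable; the deviations average
to zero exactly within every species.  A covariate with no within-species
variance anywhere yields an *inestimable* within effect (NaN + flag), never
a silent zero.  For effect rescaling, a species' realized range is the 95%
inter-quantile span of its (standardised) record values — record quantiles,
not site quantiles, an undocumented detail chosen once here — computed only
for species with ≥ 3 records; the rescaled per-species effect is the species'
total slope (fixed + BLUP) times that range, summarised as the mean over
species.  Whether species environmental means average over records or over
individuals is configurable through the grouping column; the default is
records.

The within-vs-between correlation reported alongside the effect table is the
Pearson correlation of the K (γₖ, βₖ) pairs of one joint fit — a reporting
statistic, not a model parameter.

## Tissue contrasts and model II regression

Tissue indicators are 0/1 (heartwood/trunk = 0).  The contrast model has
fixed slope, species random intercept and slope, and a crossed source term;
`pairing="same_individual"` restricts to individuals measured in both
tissues and samples one record per tissue per individual (seeded), matching
the robustness variant fitted at plant level.  The Gaussian tail share
converts a fitted (mean, slope SD) pair into the fraction of species beyond
a threshold — e.g. with a mean trunk→branch change of −0.023 and slope SD
0.075 g cm⁻³, ~30% of species still have branchwood denser by > 0.015.

Major-axis regression takes the slope of the leading eigenvector of the 2×2
covariance of paired species tissue means (computed from the closed form,
verified against the eigendecomposition at 1e-10).  The 95% CI is the
classical Jolicoeur–Mosimann angular interval: rotate the axis by
φ = ½·arcsin(2√(H·λ₁λ₂)/(λ₁−λ₂)), H = t²₀.₀₂₅,ₙ₋₂/(n−2); if the rotation
reaches 90° the interval is unbounded.  A seeded simulation in the tests
confirms ~95% coverage.  Species means are unweighted over records (weighting
is unstated in the conventions this follows).

## Prediction experiments

Species-mean protocol: reference truth is the mean over all of a species'
records (species with > 5 records); per target, all but k ∈ {0, 1, 2}
randomly retained records are masked, and the species mean is re-estimated by
(a) genus/species averaging or (b) a hierarchical model with
family/genus/species and site-within-study random terms (optionally a
trunk/branch fixed effect).  Individual protocol: species sampled at ≥ 3
sites with ≥ 4 individuals each; per target individual, k ∈ {0..3} local
conspecific individuals are retained and the rest of the site's conspecifics
masked along with the target; estimators are the global species average,
same-study average, local average and the hierarchical models.

Masked rows are structurally excluded from every estimator's training input
(asserted at run time).  The retention draw depends only on
(seed, k, target), so all estimators face identical information.  By default
the hierarchical estimator freezes variance components at their full-pool
estimates and re-solves only Henderson's equations per mask — an
approximation that keeps the protocol O(targets × solve) instead of
O(targets × EM); exact per-mask refits are available
(`refit_components=True`) and agree with the frozen path to < 0.02 g cm⁻³ on
the instances where both are run.  R² is reported both as squared Pearson
correlation (headline, affine-invariant) and as 1 − SSE/SST about the 1:1
line.

## The synthetic generator

`gwdvar.synthetic` draws records nested in individuals ⊂ sites ⊂ species ⊂
genera ⊂ families, assigns each site to one of `n_sources` studies (making
source crossed with taxonomy), gives each site coordinates whose 30-arcsec
grid cell defines `site_id`, and composes

wsg = β₀ + a_fam + a_gen + a_sp + a_site + a_ind + a_src +
Σ_c s_c(species)·tissue_c + Σₖ[βₖ·envₖⱼ + (γₖ + γₖⱼ)·Δenvₖᵢⱼ] + ε,

all effects independent zero-mean Gaussians.  Each structural level draws
from its own child stream of the master seed, so changing one level's count
leaves the others' draws untouched; identical configs are bit-reproducible.
Residual draws that would push a record to ≤ 0.01 g cm⁻³ (physically
impossible densities, ~0.1% of draws at the default conditions) are redrawn;
the effect on the realized residual SD is negligible but noted.  A configured
share of records (default 20%) is "reported" as air-dry density with the
physical conversion factor stored, exercising the conversion bookkeeping.

Named configurations carry the study conditions:

* `default_table1_config` — the global variance partition: intercept 0.557,
  family/genus/species/source/residual SDs 0.098/0.097/0.074/0.049/0.068
  g cm⁻³; 100 families × 3 genera × 3 species, 60 sources, 40 500 records.
  Site and individual SDs are zero here because the global residual already
  bundles all intraspecific variation — generating extra site/individual
  variance on top would double-count it and push the refit residual to
  ~0.079.
* `intraspecific_config` — the within-species partition: site SD 0.033 and
  individual SD 0.022 (mid-points of the reported 0.025–0.042 and
  0.017–0.028 ranges), within-individual residual 0.0425 (mid 0.040–0.045).
* `tissue_contrast_config` — species-level branch contrast N(−0.023, 0.075²)
  on top of the global taxon/source structure, 50/50 trunk/branch records.
* `within_between_config` — the group-mean-centred equation: species
  intercept SD 0.156 (the pooled among-taxon SD), residual 0.068; within
  effects 0.012 (temperature) and 0.010 (water deficit) per SD with slope SD
  0.038; between effects 0.038 (water deficit, as reported) and 0.048
  (temperature — not printed; set from the reported 70–80% attenuation of
  within relative to between effects).  Covariates split 0.9/0.436
  between/within so species sample much narrower gradients than the globe.
* `prediction_config` — full nesting incl. sites (SD 0.033) and individuals
  (SD 0.022) with within-individual residual 0.0425, ≥ 4 individuals per
  site, and a 70/30 trunk/branch mix.

What the generator does **not** emulate: phylogenetic covariance beyond the
three-level taxonomy, spatial autocorrelation among sites, covariate
measurement error, unbalanced real-world sampling (counts are uniform or
narrow ranges), heavy-tailed or skewed intraspecific distributions, and
site-sharing across species.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
these real-data features.

## Problem sizes used by the tests and the reproduction script

Fast feedback dictated the sizes, chosen once: oracle and behaviour tests run
on hundreds to a few thousand records; the replicate-based recovery/coverage
test uses 20 replicates of a 1 280-record design (40 families, 25 sources);
the full-scale recovery check and the reproduction script use the complete
40 500-record conditions, with 5 seeds for the family SD and branch-contrast
averages and 10 seeds × 4 000 species for the within-effect average (Monte
Carlo SE ≈ 3–4% of the target in each case).  The cross-validation ordering
check runs 5 seeds of a 160-species design with ~120 targets per protocol.

## Known limitations

* No intercept–slope or slope–slope correlations; no heteroscedastic or
  non-Gaussian residuals; no spatial/temporal correlation structures.
* Uncertainty is asymptotic (observed information); no credible intervals or
  bootstrap are built in.
* The dense solver's O(q³) iteration cost makes individual-level partitions
  with tens of thousands of plants slow; the intraspecific analyses here are
  designed around subsets where q stays in the low thousands.
* Component-freezing in the CV protocols slightly understates the variance
  of the hierarchical estimator when the left-out species dominates a
  component — negligible at the tested scales, and avoidable via
  `refit_components=True`.
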