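# gwdvar

Hierarchical analysis of global wood density variation.

Basic wood density — oven-dry mass over fresh volume, g cm⁻³ — underpins
forest carbon accounting and is a backbone trait of plant functional ecology.
Large compilations such as the Global Wood Density Database mix records from
hundreds of studies, species, sites and tissue types, so the interesting
questions are hierarchical: how much density variation sits between families,
genera and species versus *within* species; how much is study methodology;
whether sapwood/branchwood differ systematically from heartwood/trunkwood;
whether individuals in drier, hotter sites build denser wood than conspecifics
elsewhere; and how well a plant's density can be predicted from sparse
sampling.  `gwdvar` implements that analysis suite for ecologists working with
GWDD-style tables, together with a synthetic-data generator so every model can
be exercised and validated without downloading the database.

## The models

All estimation runs through one Gaussian mixed model,

```
y = Xβ + Σₜ Zₜ uₜ + ε,   uₜ ~ N(0, σₜ² I),   ε ~ N(0, σ² I),
```

where each random term *t* is an intercept or slope for a (possibly nested)
grouping factor.  Fitting is REML (or ML) via an
expectation–conditional-maximisation sweep over the variance components with
the residual profiled; each iteration solves Henderson's mixed-model
equations, so conditional modes (BLUPs) for prediction come for free.
On top of this engine the package encodes:

* **Variance partitioning** — intercept-only fits with species ⊂ genus ⊂
  family nesting (or individual ⊂ site ⊂ species for the intraspecific
  partition) plus a crossed study ("source") effect; reported as SDs and
  variance shares (`run_variance_partition`, `compose_variance_report`).
* **Tissue contrasts** — 0/1 sapwood-vs-heartwood or branch-vs-trunk
  indicators with species-level random intercepts and slopes
  (`run_tissue_contrast`), and major-axis (model II) regression of paired
  species tissue means with the classical angular confidence interval
  (`major_axis_fit`).
* **Within/between environmental effects** — the group-mean-centred model
  `wd_ij = β₀ + Σₖ βₖ·env_kj + Σₖ γₖ·Δenv_kij + γ₀j + Σₖ γₖj·Δenv_kij + ε_ij`,
  separating interspecific (βₖ, on species-mean covariates) from
  intraspecific (γₖ, on within-species deviations) responses, with
  per-species random slopes and rescaling to realized environmental ranges
  (`run_within_between`, `rescale_to_realized_range`).
* **Prediction experiments** — leave-out protocols comparing genus/species
  averaging against hierarchical shrinkage for species means and for
  individual plants, scored by RMSE and R² (`species_mean_experiment`,
  `individual_experiment`).
* **Database plumbing** — reading/validating GWDD-style CSVs, density
  conversions (air-/oven-dry → basic), the standard exclusion filters,
  30-arcsecond grid site assignment and sampling-depth subsets (`gwdvar.io`).

## Worked example

Generate a 40 500-record dataset at the published global variance components
(intercept 0.557; family/genus/species/source/residual SDs
0.098/0.097/0.074/0.049/0.068 g cm⁻³) and refit the variance partition:

```python
from gwdvar import generate, default_table1_config, run_variance_partition

ds = generate(default_table1_config(seed=1))
res, rep = run_variance_partition(ds.records, include_source=True)
print(res.summary())
```

```
Mixed model fit (REML)
  formula:   wsg ~ 1 + (1 | family) + (1 | family:genus) + (1 | family:genus:species) + (1 | source)
  nobs: 40500   loglik: 49069.417   converged: True (iter 13)

Fixed effects:
  Intercept                        0.5409  (SE 0.0128, z   42.16)

Random effects (SD scale, %Var in brackets):
  (1 | family)                   0.0928  ( 28.0%)  groups: 100
  (1 | family:genus)             0.0965  ( 30.3%)  groups: 300
  (1 | family:genus:species)     0.0755  ( 18.6%)  groups: 900
  (1 | source)                   0.0495  (  8.0%)  groups: 60
  Residual                       0.0681  ( 15.1%)
```

The fit recovers the generative truth: the residual ("intraspecific plus
unknown") SD comes back as 0.0681 vs the generative 0.068, the family SD as
0.0928 vs 0.098, and the taxonomic levels jointly carry ~77% of the variance
— the structure that makes species-level averaging defensible at large scales
while leaving a ±0.19 g cm⁻³ two-draw spread between conspecific
measurements (`two_draw_interval(0.068)`).

A command-line interface mirrors the library (`gwdvar simulate`, `filter`,
`fit`, `partition`, `tissue`, `envmodel`, `ma`, `predict`, `report`,
`make-fixtures`); `gwdvar report --config run.yaml` executes a named scenario
bundle (M-numbered models) and writes JSON/CSV outputs plus a manifest.

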