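"""Concrete analyses of wood density variation built on the mixed-model engine.

Covers the full model suite run on the global database: variance partitioning
over nested taxonomic (or species/site/individual) levels with an optional
crossed study effect; within-plant tissue contrasts with species-level random
slopes; the within/between (group-mean-centred) environmental-effects model;
rescaling of standardised effects to species' realized environmental ranges;
Gaussian tail shares and the two-draw separation interval; and per-species
distribution-shape checks (normal vs lognormal).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import MixedModel, MixedModelResults, ModelSpec, RandomTerm, \
    center_within_between, CenteredDesign

__all__ = [
    "VarianceReport",
    "EffectTable",
    "TissueContrast",
    "run_variance_partition",
    "compose_variance_report",
    "run_tissue_contrast",
    "run_within_between",
    "rescale_to_realized_range",
    "normal_tail_share",
    "two_draw_interval",
    "distribution_shape",
    "subtract_source_effect",
]

TAXONOMY_LEVELS = ("family", "family:genus", "family:genus:species")


@dataclass
class VarianceReport:
    """Per-level SDs, variance shares and grouped shares of one partition."""

    sd: dict                 # level -> SD (g cm^-3), includes "Residual"
    share: dict              # level -> fraction of total variance
    total_sd: float
    grouped_shares: dict = field(default_factory=dict)
    dropped_levels: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sd": pd.Series(self.sd),
            "share": pd.Series(self.share),
        })


def compose_variance_report(sd_components: dict,
                            grouping_labels: dict | None = None) -> VarianceReport:
    """Variance shares and total SD from per-level SDs.

    shares are SD^2 / sum(SD^2); total SD is the root of summed variances;
    grouped shares sum the shares of the listed levels (e.g. the taxonomic
    group family+genus+species).
    """
    sds = {k: float(v) for k, v in sd_components.items()}
    if any(v < 0 for v in sds.values()):
        raise ValueError("component SDs must be >= 0")
    total_var = sum(v ** 2 for v in sds.values())
    if total_var <= 0:
        raise ValueError("all components are zero; variance shares undefined")
    share = {k: v ** 2 / total_var for k, v in sds.items()}
    grouped = {}
    for name, levels in (grouping_labels or {}).items():
        missing = set(levels) - set(sds)
        if missing:
            raise KeyError(f"unknown levels in group {name!r}: {sorted(missing)}")
        grouped[name] = sum(share[l] for l in levels)
    return VarianceReport(sd=sds, share=share, total_sd=float(np.sqrt(total_var)),
                          grouped_shares=grouped)


def _drop_single_level_terms(data: pd.DataFrame, terms: list) -> tuple[list, list]:
    kept, dropped = [], []
    for t in terms:
        if len(t.factors) == 1:
            n = data[t.factors[0]].nunique(dropna=True)
        else:
            n = data[list(t.factors)].drop_duplicates().shape[0]
        if n < 2:
            dropped.append(t.label)
            warnings.warn(f"random term {t.label} has a single group; dropped")
        else:
            kept.append(t)
    return kept, dropped


def run_variance_partition(records: pd.DataFrame, include_source: bool = True,
                           nesting: str = "taxonomy", method: str = "reml",
                           include_plant_agg: bool = False,
                           ) -> tuple[MixedModelResults, VarianceReport]:
    """Intercept-only variance partition with the requested nesting.

    nesting = "taxonomy": species in genera in families (the global
    partition); "species_site_individual": individuals in sites in species
    (the intraspecific partition; restricted to rows carrying site and plant
    identifiers, and — by default — excluding multi-plant aggregate records,
    which carry no individual-level information).
    Optionally adds the crossed study ("source") effect.  Any level left with
    a single group is dropped with a warning and reported.
    """
    if nesting == "taxonomy":
        paths = [("family", "genus", "species")]
        data = records
    elif nesting == "species_site_individual":
        paths = [("species", "site_id", "id_plant")]
        data = records.dropna(subset=["site_id", "id_plant"])
        if not include_plant_agg and "plant_agg" in data.columns:
            data = data.loc[~data["plant_agg"].fillna(False).astype(bool)]
    else:
        raise ValueError(f"unknown nesting {nesting!r}")
    terms = []
    for path in paths:
        for depth in range(1, len(path) + 1):
            terms.append(RandomTerm(tuple(path[:depth]), None))
    if include_source:
        terms.append(RandomTerm(("source",), None))
    terms, dropped = _drop_single_level_terms(data, terms)
    if not terms:
        raise ValueError("no estimable random terms remain")
    spec = ModelSpec(response="wsg", fixed=[], intercept=True,
                     random=terms, method=method)
    res = MixedModel(data, spec).fit()
    sds = {lab: float(v) for lab, v in res.sd_components.items()}
    sds["Residual"] = res.sigma
    groups = {}
    tax = [l for l in sds if l.startswith("(1 | family")]
    if tax:
        groups["taxonomic"] = tax
    intra = [l for l in sds if l.startswith("(1 | species")]
    if intra:
        groups["intraspecific_structured"] = intra
    report = compose_variance_report(sds, groups)
    report.dropped_levels = dropped
    return res, report


# ---------------------------------------------------------------------------
# tissue contrasts
# ---------------------------------------------------------------------------

_CONTRASTS = {
    # contrast name: (column, level coded 1, level coded 0)
    "sapwood_vs_heartwood": ("type_tissue", "sapwood", "heartwood"),
    "branch_vs_trunk": ("location_sample", "branch", "trunk"),
}


@dataclass
class TissueContrast:
    """Mean 0/1 tissue contrast, its among-species spread, species predictions."""

    contrast: str
    mean_effect: float        # fixed slope, g cm^-3 (level1 minus level0)
    se_effect: float
    slope_sd: float           # among-species SD of the contrast
    n_species: int
    per_species: pd.Series    # species -> predicted contrast (fixed + BLUP)


def run_tissue_contrast(records: pd.DataFrame, contrast: str,
                        pairing: str = "none", include_source: bool = True,
                        seed: int | None = 0,
                        ) -> tuple[MixedModelResults, TissueContrast]:
    """Within-plant tissue contrast with species random intercepts and slopes.

    The tissue indicator is coded 0/1 (heartwood/sapwood or trunk/branch).
    ``pairing="same_individual"`` restricts to individuals measured in both
    tissues and samples one record per tissue per individual (seeded), fitting
    at the individual-plant level.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    col, one, zero = _CONTRASTS[contrast]
    df = records.loc[records[col].isin([one, zero])].copy()
    df["_x"] = (df[col] == one).astype(float)
    if pairing == "same_individual":
        df = df.dropna(subset=["id_plant"])
        both = df.groupby("id_plant")["_x"].nunique()
        df = df.loc[df["id_plant"].map(both).fillna(0) == 2]
        rng = np.random.default_rng(seed)
        picks = []
        for (_, _), sub in df.groupby(["id_plant", "_x"], sort=True):
            picks.append(sub.index[rng.integers(len(sub))])
        df = df.loc[sorted(picks)]
    elif pairing != "none":
        raise ValueError(f"unknown pairing {pairing!r}")
    sp_levels = df.groupby("species")["_x"].nunique()
    if (sp_levels == 2).sum() < 2 or df["_x"].nunique() < 2:
        raise ValueError(
            f"contrast {contrast} inestimable: both tissue levels must be "
            "present for at least two species")
    terms = [RandomTerm(("species",), None), RandomTerm(("species",), "_x")]
    if include_source:
        terms.append(RandomTerm(("source",), None))
    spec = ModelSpec(response="wsg", fixed=["_x"], intercept=True, random=terms)
    res = MixedModel(df, spec).fit()
    beta = float(res.fe_params["_x"])
    slope_lab = RandomTerm(("species",), "_x").label
    blups = res.random_effects[slope_lab]
    summary = TissueContrast(
        contrast=contrast,
        mean_effect=beta,
        se_effect=float(res.bse_fe["_x"]),
        slope_sd=float(res.sd_components[slope_lab]),
        n_species=int(df["species"].nunique()),
        per_species=beta + blups,
    )
    return res, summary


# ---------------------------------------------------------------------------
# within/between environmental model
# ---------------------------------------------------------------------------


@dataclass
class EffectTable:
    """Between- and within-species environmental effects from one joint fit.

    effects : per covariate — between-species effect (on species-mean
        covariate), within-species effect (on the group-centred deviation),
        their SEs, the among-species random-slope SD, and an estimability
        flag.  All effects in g cm^-3 per global covariate SD.
    within_between_correlation : Pearson correlation between the within and
        between effect vectors (a reporting statistic over the K covariates).
    per_species_slopes : species x covariate total within-species slopes
        (fixed + BLUP), for rescaling to realized ranges.
    """

    effects: pd.DataFrame
    within_between_correlation: float
    per_species_slopes: pd.DataFrame
    group_ranges: pd.DataFrame
    rescaled: pd.DataFrame | None = None


def run_within_between(records: pd.DataFrame, covariates,
                       grouping: str = "species", subset_tag: str | None = None,
                       include_source: bool = False,
                       centered: CenteredDesign | None = None,
                       ) -> tuple[MixedModelResults, EffectTable]:
    """Joint among-/within-species environmental-effects model.

    Fits  wd_ij = b0 + sum_k beta_k env_kj + sum_k gamma_k d_env_kij
                 + g0_j + sum_k g_kj d_env_kij + eps_ij
    on globally standardised covariates split into species means (env_kj) and
    within-species deviations (d_env_kij).  A covariate without any
    within-species variance has its within effect reported as inestimable
    (NaN + flag), never as 0.
    """
    covariates = list(covariates)
    cd = centered or center_within_between(records, covariates, grouping)
    df = cd.data
    fixed, random = [], [RandomTerm((grouping,), None)]
    estimable = {}
    for v in covariates:
        fixed.append(f"{v}_between")
        within_sd = float(df[f"{v}_within"].std(ddof=0))
        estimable[v] = within_sd > 1e-10
        if estimable[v]:
            fixed.append(f"{v}_within")
            random.append(RandomTerm((grouping,), f"{v}_within"))
    if include_source:
        random.append(RandomTerm(("source",), None))
    spec = ModelSpec(response="wsg", fixed=fixed, intercept=True, random=random)
    res = MixedModel(df, spec).fit()
    rows = []
    slopes = {}
    for v in covariates:
        bw = float(res.fe_params[f"{v}_between"])
        bw_se = float(res.bse_fe[f"{v}_between"])
        if estimable[v]:
            wi = float(res.fe_params[f"{v}_within"])
            wi_se = float(res.bse_fe[f"{v}_within"])
            lab = RandomTerm((grouping,), f"{v}_within").label
            sd = float(res.sd_components[lab])
            slopes[v] = wi + res.random_effects[lab]
        else:
            wi = wi_se = sd = np.nan
        rows.append({"covariate": v, "between": bw, "between_se": bw_se,
                     "within": wi, "within_se": wi_se, "slope_sd": sd,
                     "estimable_within": estimable[v]})
    eff = pd.DataFrame(rows).set_index("covariate")
    ok = eff["estimable_within"]
    if ok.sum() >= 2:
        corr = float(np.corrcoef(eff.loc[ok, "between"], eff.loc[ok, "within"])[0, 1])
    else:
        corr = np.nan
    per_species = pd.DataFrame(slopes)
    table = EffectTable(effects=eff, within_between_correlation=corr,
                        per_species_slopes=per_species,
                        group_ranges=cd.group_ranges)
    if subset_tag:
        table.effects.attrs["subset"] = subset_tag
    return res, table


def rescale_to_realized_range(table: EffectTable,
                              per_species_ranges: pd.DataFrame | None = None,
                              quantile: float = 0.95) -> EffectTable:
    """Express within-species effects over each species' realized range.

    For species j and covariate k the rescaled effect is the species' total
    within slope (fixed + BLUP, per global SD) times the species' realized
    95%-interval covariate range in global-SD units; the summary row is the
    mean over species with a computable range (>= 3 records).  Standardised
    effects stay in the table untouched.
    """
    ranges = per_species_ranges if per_species_ranges is not None \
        else table.group_ranges
    out = {}
    for v in table.per_species_slopes.columns:
        col = f"{v}_range"
        if col not in ranges.columns:
            raise KeyError(f"no realized range for covariate {v!r}")
        r = table.per_species_slopes[v].index.map(ranges[col])
        vals = table.per_species_slopes[v] * pd.Series(
            np.asarray(r, dtype=float), index=table.per_species_slopes.index)
        out[v] = vals
    per_species = pd.DataFrame(out)
    summary = per_species.mean(skipna=True)
    table.rescaled = per_species
    table.effects["rescaled_mean"] = summary
    return table


# ---------------------------------------------------------------------------
# closed-form summaries
# ---------------------------------------------------------------------------


def normal_tail_share(mean_effect: float, slope_sd: float, threshold: float,
                      side: str = "upper") -> float:
    """Share of species whose Gaussian species-level effect lies beyond a bound.

    With effects ~ N(mean, sd^2), "upper" returns P(effect > threshold),
    "lower" returns P(effect < threshold).
    """
    if slope_sd <= 0:
        raise ValueError("slope SD must be positive")
    if side == "upper":
        return float(stats.norm.sf(threshold, loc=mean_effect, scale=slope_sd))
    if side == "lower":
        return float(stats.norm.cdf(threshold, loc=mean_effect, scale=slope_sd))
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


def two_draw_interval(sd: float) -> float:
    """Half-width of the 95% interval of the difference of two N(., sd^2) draws."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return float(stats.norm.ppf(0.975) * np.sqrt(2.0) * sd)


def distribution_shape(records: pd.DataFrame, min_n: int = 8,
                       alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Normality of each species' density distribution, raw vs log scale.

    Shapiro-Wilk per species with >= min_n records, on untransformed and on
    natural-log densities.  Species with non-positive densities are skipped
    for the log test with a warning.  Returns the per-species table and
    summary rejection fractions at ``alpha``.
    """
    rows = []
    skipped_log = 0
    for sp, sub in records.groupby("species"):
        x = sub["wsg"].dropna().to_numpy()
        if len(x) < min_n:
            continue
        p_raw = float(stats.shapiro(x).pvalue)
        if (x <= 0).any():
            skipped_log += 1
            p_log = np.nan
        else:
            p_log = float(stats.shapiro(np.log(x)).pvalue)
        rows.append({"species": sp, "n": len(x), "p_raw": p_raw, "p_log": p_log})
    if skipped_log:
        warnings.warn(f"{skipped_log} species had non-positive densities; "
                      "log-scale test skipped for them")
    verdicts = pd.DataFrame(rows)
    if len(verdicts):
        verdicts = verdicts.set_index("species")
        frac_raw = float((verdicts["p_raw"] < alpha).mean())
        logp = verdicts["p_log"].dropna()
        frac_log = float((logp < alpha).mean()) if len(logp) else np.nan
    else:
        frac_raw = frac_log = np.nan
    summary = {"n_species": len(verdicts), "alpha": alpha,
               "frac_rejected_raw": frac_raw, "frac_rejected_log": frac_log}
    return verdicts, summary


def subtract_source_effect(records: pd.DataFrame, res: MixedModelResults,
                           column: str = "wsg") -> pd.Series:
    """Densities with the study-level (source) conditional mode removed.

    wsg_adj_i = wsg_i - u_source(i); reported biological variation then
    excludes systematic between-study measurement offsets.
    """
    lab = "(1 | source)"
    if lab not in res.random_effects:
        raise KeyError("fit has no crossed source term")
    eff = records["source"].map(res.random_effects[lab]).fillna(0.0)
    return records[column] - eff
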