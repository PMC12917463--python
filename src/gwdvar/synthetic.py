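"""Synthetic GWDD-like datasets with known generative truth.

The generator emulates the statistical structure the downstream models assume:
records nested in individuals, individuals in sites, sites in species, species
in genera, genera in families; a crossed study ("source") label; trunk/branch
and heartwood/sapwood tissue labels with species-specific contrasts; and
per-record environmental covariates split into among-species and
within-species variation.  Wood density is Gaussian:

    wsg = b0 + a_family + a_genus + a_species + a_site + a_individual
          + a_source + sum_c s_c(species) * tissue_c
          + sum_k [beta_k * env_kj + (gamma_k + g_kj) * d_env_kij] + eps

with all effects independent zero-mean Gaussians at the configured SDs.  The
default configurations carry the component SDs and effect sizes reported for
the global database, so parameter-recovery tests run against published truth.

Each structural level draws from its own child stream of the master seed, so
e.g. changing the number of sources leaves the taxon effects untouched.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import assign_sites

__all__ = [
    "EnvEffect",
    "TissueEffect",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "default_table1_config",
    "intraspecific_config",
    "tissue_contrast_config",
    "within_between_config",
    "prediction_config",
]

#: printed global variance components (g cm^-3): intercept, family, genus,
#: species, source, residual of the full-database variance partition
TABLE1_M1 = {
    "intercept": 0.557,
    "sd_family": 0.098,
    "sd_genus": 0.097,
    "sd_species": 0.074,
    "sd_source": 0.049,
    "sd_residual": 0.068,
}


@dataclass(frozen=True)
class EnvEffect:
    """Generative description of one environmental covariate (standardised).

    between_sd / within_sd : SDs of the species-mean component and of the
        record-level deviation around it; their squares sum to ~1 when the
        covariate should come out ~standardised.
    beta_between : fixed among-species effect (g cm^-3 per SD).
    gamma_within_mean / gamma_within_sd : mean and among-species SD of the
        within-species slope (g cm^-3 per SD).
    """

    between_sd: float
    within_sd: float
    beta_between: float = 0.0
    gamma_within_mean: float = 0.0
    gamma_within_sd: float = 0.0


@dataclass(frozen=True)
class TissueEffect:
    """Species-level random contrast for a 0/1 tissue indicator."""

    mean: float
    sd: float


def _as_range(v):
    if isinstance(v, (tuple, list)):
        lo, hi = int(v[0]), int(v[1])
    else:
        lo = hi = int(v)
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid count or range: {v!r}")
    return lo, hi


@dataclass
class SyntheticConfig:
    """Generative parameters; counts may be ints or inclusive (lo, hi) ranges."""

    seed: int
    n_families: int = 30
    genera_per_family: object = 2
    species_per_genus: object = 2
    sites_per_species: object = 2
    individuals_per_site: object = 2
    measurements_per_individual: object = 2
    n_sources: int = 10
    intercept: float = TABLE1_M1["intercept"]
    sd_family: float = TABLE1_M1["sd_family"]
    sd_genus: float = TABLE1_M1["sd_genus"]
    sd_species: float = TABLE1_M1["sd_species"]
    sd_site: float = 0.0
    sd_individual: float = 0.0
    sd_source: float = TABLE1_M1["sd_source"]
    sd_residual: float = TABLE1_M1["sd_residual"]
    tissue_effects: dict = field(default_factory=dict)  # {"branch"|"sapwood": TissueEffect}
    env: dict = field(default_factory=dict)             # {name: EnvEffect}
    location_mix: dict = field(default_factory=lambda: {"trunk": 1.0})
    tissue_mix: dict = field(default_factory=lambda: {"unknown": 1.0})
    frac_converted: float = 0.2   # share of records reported air-dry
    air_dry_factor: float = 0.828

    def __post_init__(self):
        for name in ("sd_family", "sd_genus", "sd_species", "sd_site",
                     "sd_individual", "sd_source", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for mix in (self.location_mix, self.tissue_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("tissue mix probabilities must sum to 1")
        for key in self.tissue_effects:
            if key not in ("branch", "sapwood"):
                raise ValueError(f"unknown tissue contrast {key!r}")
        for v in (self.n_families, self.n_sources):
            if int(v) < 1:
                raise ValueError("counts must be >= 1")
        for v in (self.genera_per_family, self.species_per_genus,
                  self.sites_per_species, self.individuals_per_site,
                  self.measurements_per_individual):
            _as_range(v)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (EnvEffect, TissueEffect)):
                return asdict(o)
            raise TypeError(o)
        return json.dumps(asdict(self), default=enc, indent=2)


@dataclass
class SyntheticDataset:
    """Generated records plus the realized truth needed to reconstruct them."""

    records: pd.DataFrame
    truth: dict

    def residuals(self) -> np.ndarray:
        """Recover the i.i.d. residual draws by subtracting all stored effects."""
        df = self.records
        t = self.truth
        lp = np.full(len(df), t["config"].intercept)
        for level, col in (("family_effects", "family"),
                           ("genus_effects", "genus"),
                           ("species_effects", "species"),
                           ("site_effects", "site_key"),
                           ("individual_effects", "id_plant"),
                           ("source_effects", "source")):
            eff = t[level]
            if len(eff):
                lp += df[col].map(eff).fillna(0.0).to_numpy()
        for contrast, slopes in t["tissue_slopes"].items():
            ind = _contrast_indicator(df, contrast)
            lp += df["species"].map(slopes).to_numpy() * ind
        for name, env_truth in t["env"].items():
            mean = df["species"].map(env_truth["species_mean"]).to_numpy()
            dev = df[name].to_numpy() - mean
            spec = t["config"].env[name]
            slope = spec.gamma_within_mean \
                + df["species"].map(env_truth["species_slope"]).to_numpy()
            lp += spec.beta_between * mean + slope * dev
        return df["wsg"].to_numpy() - lp


def _contrast_indicator(df: pd.DataFrame, contrast: str) -> np.ndarray:
    if contrast == "branch":
        return (df["location_sample"] == "branch").to_numpy(dtype=float)
    return (df["type_tissue"] == "sapwood").to_numpy(dtype=float)


def _draw_counts(rng, spec, size):
    lo, hi = _as_range(spec)
    if lo == hi:
        return np.full(size, lo, dtype=np.int64)
    return rng.integers(lo, hi + 1, size=size)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset; deterministic under a fixed config (seed included)."""
    ss = np.random.SeedSequence(int(config.seed))
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("counts", "family", "genus", "species", "site", "individual",
         "source", "assign", "tissue", "env", "residual", "coords", "report"),
        ss.spawn(13))}

    rc = streams["counts"]
    F = int(config.n_families)
    genera_per_fam = _draw_counts(rc, config.genera_per_family, F)
    n_genera = int(genera_per_fam.sum())
    species_per_gen = _draw_counts(rc, config.species_per_genus, n_genera)
    n_species = int(species_per_gen.sum())

    fam_names = np.array([f"Fam{i:04d}" for i in range(F)])
    gen_fam = np.repeat(np.arange(F), genera_per_fam)
    gen_names = np.array([f"Gen{i:05d}" for i in range(n_genera)])
    sp_gen = np.repeat(np.arange(n_genera), species_per_gen)
    sp_names = np.array([f"Sp{i:06d}" for i in range(n_species)])

    fam_eff = streams["family"].normal(0.0, config.sd_family, F)
    gen_eff = streams["genus"].normal(0.0, config.sd_genus, n_genera)
    sp_eff = streams["species"].normal(0.0, config.sd_species, n_species)

    sites_per_sp = _draw_counts(rc, config.sites_per_species, n_species)
    n_sites = int(sites_per_sp.sum())
    site_sp = np.repeat(np.arange(n_species), sites_per_sp)
    site_eff = streams["site"].normal(0.0, config.sd_site, n_sites)
    # each site gets a geographic position; the public site_id comes from the
    # 30-arcsec grid assignment so the round trip through io is exercised
    lon = streams["coords"].uniform(-179.9, 179.9, n_sites)
    lat = streams["coords"].uniform(-55.0, 70.0, n_sites)
    site_source = streams["assign"].integers(0, config.n_sources, n_sites)
    src_eff = streams["source"].normal(0.0, config.sd_source, config.n_sources)
    src_names = np.array([f"Src{i:04d}" for i in range(config.n_sources)])

    ind_per_site = _draw_counts(rc, config.individuals_per_site, n_sites)
    n_ind = int(ind_per_site.sum())
    ind_site = np.repeat(np.arange(n_sites), ind_per_site)
    ind_eff = streams["individual"].normal(0.0, config.sd_individual, n_ind)

    meas_per_ind = _draw_counts(rc, config.measurements_per_individual, n_ind)
    n_rec = int(meas_per_ind.sum())
    rec_ind = np.repeat(np.arange(n_ind), meas_per_ind)
    rec_site = ind_site[rec_ind]
    rec_sp = site_sp[rec_site]

    # tissue labels
    rt = streams["tissue"]
    loc_labels = np.array(sorted(config.location_mix))
    loc_p = np.array([config.location_mix[k] for k in loc_labels])
    location = loc_labels[rt.choice(len(loc_labels), size=n_rec, p=loc_p)]
    tis_labels = np.array(sorted(config.tissue_mix))
    tis_p = np.array([config.tissue_mix[k] for k in tis_labels])
    tissue = tis_labels[rt.choice(len(tis_labels), size=n_rec, p=tis_p)]

    lp = np.full(n_rec, config.intercept, dtype=float)
    lp += fam_eff[gen_fam[sp_gen[rec_sp]]]
    lp += gen_eff[sp_gen[rec_sp]]
    lp += sp_eff[rec_sp]
    lp += site_eff[rec_site]
    lp += ind_eff[rec_ind]
    lp += src_eff[site_source[rec_site]]

    tissue_slopes = {}
    for contrast, te in config.tissue_effects.items():
        slopes = rt.normal(te.mean, te.sd, n_species)
        tissue_slopes[contrast] = pd.Series(slopes, index=sp_names)
        ind01 = (location == "branch") if contrast == "branch" \
            else (tissue == "sapwood")
        lp += slopes[rec_sp] * ind01

    re_env = streams["env"]
    env_cols = {}
    env_truth = {}
    for name in sorted(config.env):
        spec = config.env[name]
        sp_mean = re_env.normal(0.0, spec.between_sd, n_species)
        sp_slope = re_env.normal(0.0, spec.gamma_within_sd, n_species)
        dev = re_env.normal(0.0, spec.within_sd, n_rec)
        env_cols[name] = sp_mean[rec_sp] + dev
        lp += spec.beta_between * sp_mean[rec_sp] \
            + (spec.gamma_within_mean + sp_slope[rec_sp]) * dev
        env_truth[name] = {
            "species_mean": pd.Series(sp_mean, index=sp_names),
            "species_slope": pd.Series(sp_slope, index=sp_names),
        }

    eps = streams["residual"].normal(0.0, config.sd_residual, n_rec)
    wsg = lp + eps
    # basic density is strictly positive; redraw the (rare, ~0.1%) residuals
    # that push a record to or below zero
    if config.sd_residual > 0:
        for _ in range(100):
            bad = wsg <= 0.01
            if not bad.any():
                break
            eps[bad] = streams["residual"].normal(0.0, config.sd_residual,
                                                  int(bad.sum()))
            wsg = lp + eps

    converted = streams["report"].random(n_rec) < config.frac_converted
    value_ref = np.where(converted, wsg / config.air_dry_factor, wsg)
    quantity = np.where(converted, "air_dry", "basic")
    factor = np.where(converted, config.air_dry_factor, 1.0)

    df = pd.DataFrame({
        "wsg": wsg,
        "value_reference": value_ref,
        "quantity_reference": quantity,
        "wsg_conversion": factor,
        "family": fam_names[gen_fam[sp_gen[rec_sp]]],
        "genus": gen_names[sp_gen[rec_sp]],
        "species": sp_names[rec_sp],
        "rank_taxonomic": "species",
        "id_plant": np.array([f"Pl{i:07d}" for i in range(n_ind)])[rec_ind],
        "longitude": lon[rec_site],
        "latitude": lat[rec_site],
        "source": src_names[site_source[rec_site]],
        "location_sample": location,
        "type_tissue": tissue,
        "plant_agg": False,
        "plants_sampled": 1,
        "type_forest": "natural",
        "experiment_design": "",
    })
    for name, vals in env_cols.items():
        df[name] = vals
    df = assign_sites(df)
    site_keys = np.array([f"Site{i:06d}" for i in range(n_sites)])
    df["site_key"] = site_keys[rec_site]

    truth = {
        "config": config,
        "family_effects": pd.Series(fam_eff, index=fam_names),
        "genus_effects": pd.Series(gen_eff, index=gen_names),
        "species_effects": pd.Series(sp_eff, index=sp_names),
        "site_effects": pd.Series(site_eff, index=site_keys),
        "individual_effects": pd.Series(
            ind_eff, index=[f"Pl{i:07d}" for i in range(n_ind)]),
        "source_effects": pd.Series(src_eff, index=src_names),
        "tissue_slopes": tissue_slopes,
        "env": env_truth,
    }
    return SyntheticDataset(records=df, truth=truth)


def truth_summary(ds: SyntheticDataset) -> dict:
    """JSON-serialisable sidecar ledger of the generative truth."""
    t = ds.truth
    out = {"config": json.loads(t["config"].to_json())}
    for k in ("family_effects", "genus_effects", "species_effects",
              "site_effects", "individual_effects", "source_effects"):
        out[k] = {str(i): float(v) for i, v in t[k].items()}
    out["tissue_slopes"] = {c: {str(i): float(v) for i, v in s.items()}
                            for c, s in t["tissue_slopes"].items()}
    out["env"] = {name: {part: {str(i): float(v) for i, v in ser.items()}
                         for part, ser in d.items()}
                  for name, d in t["env"].items()}
    return out


# ---------------------------------------------------------------------------
# named study conditions
# ---------------------------------------------------------------------------


def default_table1_config(seed: int) -> SyntheticConfig:
    """Global variance-partition conditions (full-database column).

    Intercept and the five component SDs are the printed point estimates of
    the full-dataset model with a source effect; the residual SD there bundles
    all intraspecific variation, so site/individual SDs are zero here (see
    :func:`intraspecific_config` for the within-species partition conditions).
    100 families x 3 genera x 3 species give 900 species and 40 500 records —
    comfortably above the scale recovery tests need.
    """
    return SyntheticConfig(
        seed=seed,
        n_families=100, genera_per_family=3, species_per_genus=3,
        sites_per_species=3, individuals_per_site=5,
        measurements_per_individual=3, n_sources=60,
        **TABLE1_M1,
    )


def intraspecific_config(seed: int) -> SyntheticConfig:
    """Within-species partition conditions (sites > individuals > residual).

    Site and individual SDs sit mid-range of the reported spans
    (0.025-0.042 and 0.017-0.028 g cm^-3); the residual is the reported
    within-individual 0.040-0.045 band's midpoint.
    """
    return SyntheticConfig(
        seed=seed,
        n_families=25, genera_per_family=2, species_per_genus=3,
        sites_per_species=4, individuals_per_site=4,
        measurements_per_individual=2, n_sources=30,
        intercept=TABLE1_M1["intercept"],
        sd_family=TABLE1_M1["sd_family"], sd_genus=TABLE1_M1["sd_genus"],
        sd_species=TABLE1_M1["sd_species"], sd_source=TABLE1_M1["sd_source"],
        sd_site=0.033, sd_individual=0.022, sd_residual=0.0425,
    )


def tissue_contrast_config(seed: int, n_species: int = 600) -> SyntheticConfig:
    """Trunk-vs-branch contrast conditions.

    Species-level branch effect drawn around the reported mean contrast
    (-0.023 g cm^-3) with the reported slope SD (0.075); taxon and source SDs
    from the global partition so fits see realistic background structure.
    """
    per_fam = 8
    return SyntheticConfig(
        seed=seed,
        n_families=max(n_species // per_fam, 1),
        genera_per_family=2, species_per_genus=4,
        sites_per_species=2, individuals_per_site=2,
        measurements_per_individual=2, n_sources=50,
        **TABLE1_M1,
        tissue_effects={"branch": TissueEffect(mean=-0.023, sd=0.075)},
        location_mix={"trunk": 0.5, "branch": 0.5},
    )


def within_between_config(seed: int, n_species: int = 2000,
                          records_per_species: int = 15) -> SyntheticConfig:
    """Within/between environmental-effect conditions.

    Generates directly from the group-mean-centred equation: a species random
    intercept carrying the pooled among-taxon SD (0.156 g cm^-3), no separate
    family/genus/source variance, residual 0.068.  Within effects are the
    printed intraspecific values (temperature 0.012, water deficit 0.010 per
    SD; slope SD 0.038).  The printed among-species water-deficit effect is
    0.038; the unprinted temperature one is set to 0.048 consistent with
    within effects being 70-80% smaller than between effects.  Covariates are
    split 0.9/0.436 between/within so species sample much narrower
    environmental ranges than the global gradient.
    """
    sites = 3
    meas = max(records_per_species // (sites * 5), 1)
    return SyntheticConfig(
        seed=seed,
        n_families=max(n_species // 40, 1), genera_per_family=5,
        species_per_genus=8,
        sites_per_species=sites, individuals_per_site=5,
        measurements_per_individual=meas, n_sources=40,
        intercept=TABLE1_M1["intercept"],
        sd_family=0.0, sd_genus=0.0, sd_species=0.156,
        sd_site=0.0, sd_individual=0.0, sd_source=0.0,
        sd_residual=TABLE1_M1["sd_residual"],
        env={
            "temperature": EnvEffect(0.9, 0.436, beta_between=0.048,
                                     gamma_within_mean=0.012,
                                     gamma_within_sd=0.038),
            "water_deficit": EnvEffect(0.9, 0.436, beta_between=0.038,
                                       gamma_within_mean=0.010,
                                       gamma_within_sd=0.038),
        },
    )


def prediction_config(seed: int, n_species: int = 160) -> SyntheticConfig:
    """Cross-validation conditions: full nesting incl. sites and individuals.

    Taxonomy and source SDs from the global partition; site/individual SDs at
    the mid-points of their reported ranges with a within-individual residual
    of 0.0425, so total intraspecific spread is ~0.058 g cm^-3.  Sites hold
    >= 4 individuals so the individual-level experiment has local conspecifics
    to draw on; a trunk/branch mix feeds the tissue-aware model variant.
    """
    return SyntheticConfig(
        seed=seed,
        n_families=max(n_species // 4, 1), genera_per_family=2,
        species_per_genus=2,
        sites_per_species=3, individuals_per_site=4,
        measurements_per_individual=1, n_sources=30,
        intercept=TABLE1_M1["intercept"],
        sd_family=TABLE1_M1["sd_family"], sd_genus=TABLE1_M1["sd_genus"],
        sd_species=TABLE1_M1["sd_species"], sd_source=TABLE1_M1["sd_source"],
        sd_site=0.033, sd_individual=0.022, sd_residual=0.0425,
        tissue_effects={"branch": TissueEffect(mean=-0.023, sd=0.075)},
        location_mix={"trunk": 0.7, "branch": 0.3},
    )
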