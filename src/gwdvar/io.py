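"""Reading, validation, filtering and subsetting of GWDD-v.2-style tables.

The database convention: one row per wood density record, with basic wood
density in ``wsg`` (g cm^-3), the originally reported value and quantity in
``value_reference`` / ``quantity_reference``, the physical conversion factor in
``wsg_conversion``, taxonomy in ``family``/``genus``/``species`` (plus
``rank_taxonomic``), provenance in ``source``, within-plant location in
``location_sample`` / ``type_tissue``, and optional geolocation in decimal
``longitude`` / ``latitude``.  Environmental covariates arrive as plain extra
columns (no raster extraction here).

Records are carried as a validated :class:`pandas.DataFrame` — the natural
container for tabular trait data — rather than per-record objects.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RowParseError",
    "ConfigError",
    "FilterReport",
    "read_records",
    "convert_to_basic",
    "apply_standard_filters",
    "assign_site",
    "assign_sites",
    "build_subset",
    "write_records",
    "TROPICS_LAT",
    "DEFAULT_CELL_DEG",
]

#: latitude of the Tropics of Cancer/Capricorn used for the tropical subset
TROPICS_LAT = 23.43622
#: default site grid cell: 30 arc seconds (~1 km), the climatology resolution
DEFAULT_CELL_DEG = 1.0 / 120.0

MANDATORY_COLUMNS = ("wsg", "species", "source")
NUMERIC_COLUMNS = ("wsg", "value_reference", "wsg_conversion",
                   "longitude", "latitude", "plants_sampled")
_QUANTITIES = ("basic", "air_dry", "oven_dry")


class SchemaError(ValueError):
    """A mandatory column is absent (or a constraint name is unknown)."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, row: int, column: str, value):
        self.row = row
        self.column = column
        super().__init__(f"row {row}: cannot parse {column}={value!r} as a number")


class ConfigError(ValueError):
    pass


@dataclass
class FilterReport:
    """Tally of the standard exclusion rules (first matching rule wins)."""

    n_in: int
    n_out: int
    removed_by_rule: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.n_in != self.n_out + sum(self.removed_by_rule.values()):
            raise ValueError("inconsistent filter report counts")

    def to_json(self, path=None) -> str:
        s = json.dumps({"n_in": self.n_in, "n_out": self.n_out,
                        "removed_by_rule": self.removed_by_rule}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def read_records(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GWDD-style CSV into a validated record table.

    Parameters
    ----------
    column_map : optional {file header: canonical name} renaming applied
        before validation, for tables with non-canonical headers.

    Raises
    ------
    SchemaError : a mandatory column (wsg, species, source) is missing.
    RowParseError : a numeric cell cannot be parsed (reports the row index).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(i, col, raw.iloc[i])
        df[col] = parsed
    # extra columns that look numeric (environmental covariates) are parsed
    # permissively; genuinely textual columns stay as strings
    known = set(NUMERIC_COLUMNS) | {"family", "genus", "species", "source",
                                    "rank_taxonomic", "quantity_reference",
                                    "location_sample", "type_tissue",
                                    "plant_agg", "id_plant", "site_id",
                                    "type_forest", "experiment_design"}
    for col in df.columns:
        if col in known:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.notna().sum() >= df[col].notna().sum() and df[col].notna().any():
            df[col] = parsed
    if "plant_agg" in df.columns:
        df["plant_agg"] = df["plant_agg"].str.lower().isin(
            ("true", "1", "yes", "y")).where(df["plant_agg"].notna(), False)
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    wsg = df["wsg"]
    if (wsg.dropna() <= 0).any():
        i = int(np.flatnonzero((wsg <= 0).fillna(False).to_numpy())[0])
        raise RowParseError(i, "wsg", float(wsg.iloc[i]))
    for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
        if col in df.columns:
            v = df[col].dropna()
            if ((v < lo) | (v > hi)).any():
                bad = v[(v < lo) | (v > hi)].index[0]
                raise RowParseError(int(bad), col, float(df.loc[bad, col]))


def convert_to_basic(value_reference: float, quantity_reference: str,
                     wsg_conversion: float | None = None) -> float:
    """Convert a reported density to basic density (g cm^-3).

    Basic density needs no factor; air- and oven-dry densities require the
    physical conversion factor recorded with the measurement.
    """
    if quantity_reference not in _QUANTITIES:
        raise ValueError(f"unknown quantity_reference {quantity_reference!r}")
    if not (value_reference > 0):
        raise ValueError("value_reference must be positive")
    if quantity_reference == "basic":
        factor = 1.0 if wsg_conversion is None or (
            isinstance(wsg_conversion, float) and math.isnan(wsg_conversion)) \
            else float(wsg_conversion)
    else:
        if wsg_conversion is None or (
                isinstance(wsg_conversion, float) and math.isnan(wsg_conversion)):
            raise ValueError(
                f"{quantity_reference} density requires a conversion factor")
        factor = float(wsg_conversion)
    if not factor > 0:
        raise ValueError("wsg_conversion must be positive")
    return float(value_reference) * factor


# rule order is fixed so that a record matching several rules is counted once,
# under the first rule, and reports stay comparable across runs
_FILTER_RULES = ("genus_rank", "bark", "experiment", "plantation", "root")


def apply_standard_filters(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop genus-rank records, bark, experiments, plantations and root samples.

    Experiment detection is a case-insensitive substring match for
    "fertilizer" / "treatment" in ``experiment_design``.  Returns the filtered
    table and a :class:`FilterReport` tallying each rule (first match wins).
    Idempotent by construction.
    """
    def col(name):
        return df[name] if name in df.columns else pd.Series(pd.NA, index=df.index)

    masks = {
        "genus_rank": col("rank_taxonomic").astype("string").str.lower() == "genus",
        "bark": col("type_tissue").astype("string").str.lower() == "bark",
        "experiment": col("experiment_design").astype("string").str.lower()
                      .str.contains("fertilizer|treatment", regex=True),
        "plantation": col("type_forest").astype("string").str.lower() == "plantation",
        "root": col("location_sample").astype("string").str.lower() == "root",
    }
    removed = pd.Series("", index=df.index, dtype=object)
    for rule in _FILTER_RULES:
        m = masks[rule].fillna(False).astype(bool)
        removed[m & (removed == "")] = rule
    out = df.loc[removed == ""].copy()
    tally = {rule: int((removed == rule).sum())
             for rule in _FILTER_RULES if (removed == rule).any()}
    return out, FilterReport(n_in=len(df), n_out=len(out), removed_by_rule=tally)


def assign_site(longitude: float, latitude: float,
                cell_size_deg: float = DEFAULT_CELL_DEG) -> tuple[int, int]:
    """Grid-cell key for a point: cells anchored at (0, 0), floor semantics.

    The default cell is 30 arc seconds (~1 km), matching the resolution of the
    climatologies the site definition mirrors.  Identical keys <=> same site.
    """
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    if longitude is None or latitude is None or \
            (isinstance(longitude, float) and math.isnan(longitude)) or \
            (isinstance(latitude, float) and math.isnan(latitude)):
        raise ValueError("missing coordinates")
    if not (-180 <= longitude <= 180 and -90 <= latitude <= 90):
        raise ValueError(f"coordinates out of range: ({longitude}, {latitude})")
    return (int(math.floor(longitude / cell_size_deg)),
            int(math.floor(latitude / cell_size_deg)))


def assign_sites(df: pd.DataFrame,
                 cell_size_deg: float = DEFAULT_CELL_DEG) -> pd.DataFrame:
    """Add a ``site_id`` column ("ix_iy") for rows with coordinates.

    Rows without coordinates keep a missing site_id: they remain usable for
    every model that does not need sites.
    """
    out = df.copy()
    if "longitude" not in out.columns or "latitude" not in out.columns:
        out["site_id"] = pd.NA
        return out
    lon = pd.to_numeric(out["longitude"], errors="coerce")
    lat = pd.to_numeric(out["latitude"], errors="coerce")
    okay = lon.notna() & lat.notna()
    ix = np.floor(lon[okay] / cell_size_deg).astype(np.int64)
    iy = np.floor(lat[okay] / cell_size_deg).astype(np.int64)
    site = pd.Series(pd.NA, index=out.index, dtype=object)
    site[okay] = ix.astype(str) + "_" + iy.astype(str)
    out["site_id"] = site
    return out


_KNOWN_CONSTRAINTS = {
    "min_sites_per_species", "min_individuals_per_site",
    "min_measurements_per_individual", "min_species_per_genus",
    "min_genera_per_family", "env_range_thresholds", "zone",
}


def build_subset(df: pd.DataFrame, constraints: dict) -> pd.DataFrame:
    """Retain species satisfying all active sampling-depth constraints.

    Supported constraints (any subset may be given):

    - ``min_sites_per_species``: species seen in at least k distinct sites;
    - ``min_individuals_per_site``: at least one site with >= k individuals;
    - ``min_measurements_per_individual``: at least one individual with >= k
      measurements;
    - ``min_species_per_genus`` / ``min_genera_per_family``: applied after the
      species-level rules, counting retained species/genera;
    - ``env_range_thresholds``: {covariate: threshold}; a species is kept if
      ANY listed covariate spans at least its threshold (max - min over the
      species' records);
    - ``zone``: "all" | "tropical" | "extratropical" (|lat| <= 23.43622 deg).
    """
    unknown = set(constraints) - _KNOWN_CONSTRAINTS
    if unknown:
        raise ConfigError(f"unknown constraint(s): {sorted(unknown)}")
    out = df.copy()
    zone = constraints.get("zone", "all")
    if zone not in ("all", "tropical", "extratropical"):
        raise ConfigError(f"unknown zone {zone!r}")
    if zone != "all":
        lat = pd.to_numeric(out.get("latitude"), errors="coerce")
        trop = lat.abs() <= TROPICS_LAT
        out = out.loc[trop.fillna(False) if zone == "tropical"
                      else (~trop).fillna(False)]
    keep = pd.Series(True, index=pd.Index(out["species"].unique(), name="species"))

    # k <= 1 is satisfied by any record, with or without metadata
    k = constraints.get("min_sites_per_species")
    if k is not None and k > 1:
        n_sites = out.dropna(subset=["site_id"]).groupby("species")["site_id"].nunique()
        keep &= keep.index.to_series().map(n_sites).fillna(0) >= k
    k = constraints.get("min_individuals_per_site")
    if k is not None and k > 1:
        sub = out.dropna(subset=["site_id", "id_plant"])
        best = (sub.groupby(["species", "site_id"])["id_plant"].nunique()
                .groupby("species").max())
        keep &= keep.index.to_series().map(best).fillna(0) >= k
    k = constraints.get("min_measurements_per_individual")
    if k is not None and k > 1:
        sub = out.dropna(subset=["id_plant"])
        best = (sub.groupby(["species", "id_plant"]).size()
                .groupby("species").max())
        keep &= keep.index.to_series().map(best).fillna(0) >= k
    thresholds = constraints.get("env_range_thresholds")
    if thresholds:
        any_ok = pd.Series(False, index=keep.index)
        for cov, thr in thresholds.items():
            if cov not in out.columns:
                raise ConfigError(f"environmental covariate {cov!r} not in data")
            rng = out.groupby("species")[cov].agg(lambda s: s.max() - s.min())
            any_ok |= keep.index.to_series().map(rng).fillna(-np.inf) >= thr
        keep &= any_ok
    out = out.loc[out["species"].map(keep).fillna(False)]

    k = constraints.get("min_species_per_genus")
    if k is not None and "genus" in out.columns:
        n_sp = out.groupby("genus")["species"].nunique()
        out = out.loc[out["genus"].map(n_sp).fillna(0) >= k]
    k = constraints.get("min_genera_per_family")
    if k is not None and "family" in out.columns:
        n_gen = out.groupby("family")["genus"].nunique()
        out = out.loc[out["family"].map(n_gen).fillna(0) >= k]
    return out


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
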