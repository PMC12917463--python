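"""Leave-out prediction experiments: averaging vs hierarchical shrinkage.

Two protocols mirror how wood densities are imputed in practice:

* species-mean experiment — how well can a species' reference mean (computed
  from all its records) be recovered when only 0-2 of its measurements are
  available?  Estimators: the field default (genus average when nothing is
  sampled, species average otherwise) vs a hierarchical model pooling the
  retained measurements with the full taxonomy (family/genus/species) and
  nested site-within-study random effects, optionally with a trunk/branch
  fixed effect.

* individual experiment — how well can one plant's density be predicted when
  0-3 locally measured conspecifics are retained?  Estimators: global species
  average, same-study average, local (same 1-km site) average, and the same
  hierarchical models.

The hierarchical estimator freezes variance components at their full-pool
estimates and re-solves Henderson's equations on the masked training rows per
target (exact per-target refits available via ``refit_components=True``); the
target's held-out records are never part of any estimator's training rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import MixedModel, ModelSpec, RandomTerm

__all__ = ["Scenario", "ExperimentResult", "score",
           "species_mean_experiment", "individual_experiment"]

_SPECIES_ESTIMATORS = ("species_average", "genus_average", "hierarchical",
                       "hierarchical_tissue")
_INDIVIDUAL_ESTIMATORS = ("species_average", "study_average", "local_average",
                          "hierarchical", "hierarchical_tissue")


@dataclass(frozen=True)
class Scenario:
    """One cell of the experiment grid."""

    level: str            # "species_mean" | "individual"
    k_retained: int
    estimator: str

    def __post_init__(self):
        if self.level not in ("species_mean", "individual"):
            raise ValueError(f"unknown level {self.level!r}")
        allowed = _SPECIES_ESTIMATORS if self.level == "species_mean" \
            else _INDIVIDUAL_ESTIMATORS
        if self.estimator not in allowed:
            raise ValueError(
                f"estimator {self.estimator!r} not valid for {self.level}")
        if self.k_retained < 0:
            raise ValueError("k_retained must be >= 0")
        if self.k_retained == 0 and self.estimator in ("species_average",
                                                       "local_average"):
            raise ValueError(
                f"{self.estimator} needs k_retained >= 1 (nothing to average)")


@dataclass
class ExperimentResult:
    scenario: Scenario
    rmse: float
    r2: float                  # squared Pearson correlation ("regression")
    r2_one_to_one: float       # 1 - SSE/SST against the 1:1 line
    n_targets: int
    n_skipped: int = 0
    predictions: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {"level": self.scenario.level,
                "k_retained": self.scenario.k_retained,
                "estimator": self.scenario.estimator,
                "rmse": self.rmse, "r2": self.r2,
                "r2_one_to_one": self.r2_one_to_one,
                "n_targets": self.n_targets, "n_skipped": self.n_skipped}


def results_frame(results) -> pd.DataFrame:
    """Tidy scenario x metric table (one row per scenario)."""
    return pd.DataFrame([r.to_row() for r in results])


def score(pred, obs, mode: str = "regression") -> tuple[float, float]:
    """RMSE and R^2 of predictions.

    mode="regression": R^2 is the squared Pearson correlation (affine
    invariant, the headline metric); mode="one_to_one": 1 - SSE/SST against
    the identity line (penalises bias).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and obs must be equal-length 1-d, n >= 2")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("observations have zero variance; R^2 undefined")
    if mode == "regression":
        if np.std(pred) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    elif mode == "one_to_one":
        r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rmse, r2


# ---------------------------------------------------------------------------
# hierarchical estimator plumbing
# ---------------------------------------------------------------------------


def _hierarchical_spec(with_tissue: bool) -> ModelSpec:
    random = [RandomTerm(("family",), None),
              RandomTerm(("family", "genus"), None),
              RandomTerm(("family", "genus", "species"), None),
              RandomTerm(("source",), None),
              RandomTerm(("source", "site_id"), None)]
    fixed = ["branch01"] if with_tissue else []
    return ModelSpec(response="wsg", fixed=fixed, intercept=True, random=random)


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["branch01"] = (df.get("location_sample") == "branch").astype(float)
    return df


def _fit_pool(df: pd.DataFrame, with_tissue: bool):
    spec = _hierarchical_spec(with_tissue)
    return MixedModel(df, spec, allow_single_group=True).fit()


def _blup_predict(base_fit, training: pd.DataFrame, where: pd.DataFrame,
                  refit_components: bool) -> float:
    if refit_components:
        model = MixedModel(training, base_fit.spec_copy(),
                           allow_single_group=True)
        res = model.fit()
    else:
        res = base_fit.reestimate(training)
    return float(res.predict(where)[0])


# ---------------------------------------------------------------------------
# species-mean experiment
# ---------------------------------------------------------------------------


def species_mean_experiment(records: pd.DataFrame, scenarios,
                            min_records: int = 5, seed: int = 0,
                            refit_components: bool = False,
                            max_targets: int | None = None,
                            keep_predictions: bool = False):
    """Leave-species-out recovery of reference species means.

    Reference truth per species = mean over all its records (species with
    more than ``min_records`` records).  Per scenario and target species all
    records except ``k_retained`` randomly chosen ones are masked; the
    retained set depends only on (seed, k, species), so estimators face
    identical information.  Returns one :class:`ExperimentResult` per
    scenario.
    """
    df = _prepare(records)
    counts = df.groupby("species").size()
    targets = counts[counts > min_records].index.to_numpy()
    targets.sort()
    if max_targets is not None and len(targets) > max_targets:
        pick = np.random.default_rng(seed).choice(
            len(targets), size=max_targets, replace=False)
        targets = targets[np.sort(pick)]
    truth = df.groupby("species")["wsg"].mean()
    base_fits = {}
    need_hier = {s.estimator for s in scenarios} & {"hierarchical",
                                                    "hierarchical_tissue"}
    for est in need_hier:
        base_fits[est] = _fit_pool(df, est == "hierarchical_tissue")
    sp_rows = {sp: df.index[df["species"] == sp] for sp in targets}
    genus_of = df.groupby("species")["genus"].first()
    results = []
    for sc in scenarios:
        if sc.level != "species_mean":
            raise ValueError("scenario level must be 'species_mean'")
        preds, obs, kept, skipped = [], [], [], 0
        for j, sp in enumerate(targets):
            rows = sp_rows[sp]
            rng = np.random.default_rng([seed, sc.k_retained, j])
            k = min(sc.k_retained, len(rows))
            retained = pd.Index(rng.choice(rows.to_numpy(), size=k,
                                           replace=False)) if k else pd.Index([])
            masked = rows.difference(retained)
            training = df.loc[df.index.difference(masked)]
            assert not training.index.intersection(masked).size  # no leakage
            if sc.estimator == "species_average":
                yhat = float(df.loc[retained, "wsg"].mean())
            elif sc.estimator == "genus_average":
                g = genus_of[sp]
                pool = training.loc[(training["genus"] == g)
                                    & (training["species"] != sp), "wsg"]
                if len(pool) == 0:
                    skipped += 1
                    continue
                yhat = float(pool.mean())
            else:
                where = df.loc[rows[:1], ["family", "genus", "species"]].copy()
                where["source"] = "\x00unseen"
                where["site_id"] = "\x00unseen"
                where["branch01"] = float(df.loc[rows, "branch01"].mean())
                yhat = _blup_predict(base_fits[sc.estimator], training, where,
                                     refit_components)
            preds.append(yhat)
            obs.append(float(truth[sp]))
            kept.append(sp)
        if len(preds) >= 2:
            rmse, r2 = score(preds, obs, "regression")
            _, r2_id = score(preds, obs, "one_to_one")
        else:
            rmse = r2 = r2_id = float("nan")
        res = ExperimentResult(sc, rmse, r2, r2_id, len(preds), skipped)
        if keep_predictions:
            res.predictions = pd.DataFrame(
                {"target": kept, "pred": preds, "obs": obs})
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# individual experiment
# ---------------------------------------------------------------------------


def qualifying_species(df: pd.DataFrame, min_sites: int = 3,
                       min_individuals_per_site: int = 4) -> pd.Index:
    """Species measured at >= min_sites sites, each with enough individuals."""
    sub = df.dropna(subset=["site_id", "id_plant"])
    per_site = sub.groupby(["species", "site_id"])["id_plant"].nunique()
    good_sites = per_site[per_site >= min_individuals_per_site]
    n_good = good_sites.groupby("species").size()
    return n_good[n_good >= min_sites].index


def individual_experiment(records: pd.DataFrame, scenarios,
                          min_sites: int = 3,
                          min_individuals_per_site: int = 4,
                          seed: int = 0, max_targets: int | None = 200,
                          refit_components: bool = False,
                          keep_predictions: bool = False):
    """Leave-individual-out prediction from 0-3 retained local conspecifics.

    Targets are individuals of species sampled at >= 3 sites with >= 4
    individuals each.  For a target, ``k_retained`` random conspecific
    individuals at its site stay in the training data; the other local
    conspecifics and the target itself are masked.  The observed value is the
    individual's mean density.  Targets with fewer than ``k_retained`` local
    conspecifics are skipped and counted.
    """
    df = _prepare(records).dropna(subset=["site_id", "id_plant"])
    good = qualifying_species(df, min_sites, min_individuals_per_site)
    pool = df.loc[df["species"].isin(good)]
    ind_info = (pool.groupby("id_plant")
                .agg(species=("species", "first"), site_id=("site_id", "first"),
                     source=("source", "first"), wsg=("wsg", "mean")))
    targets = ind_info.index.to_numpy()
    targets.sort()
    if max_targets is not None and len(targets) > max_targets:
        pick = np.random.default_rng(seed).choice(
            len(targets), size=max_targets, replace=False)
        targets = targets[np.sort(pick)]
    need_hier = {s.estimator for s in scenarios} & {"hierarchical",
                                                    "hierarchical_tissue"}
    base_fits = {est: _fit_pool(df, est == "hierarchical_tissue")
                 for est in need_hier}
    rows_of_ind = df.groupby("id_plant").groups
    locals_of = df.groupby(["species", "site_id"])["id_plant"].agg(
        lambda s: sorted(set(s)))
    results = []
    for sc in scenarios:
        if sc.level != "individual":
            raise ValueError("scenario level must be 'individual'")
        preds, obs, skipped = [], [], 0
        for j, ind in enumerate(targets):
            info = ind_info.loc[ind]
            sp, site = info["species"], info["site_id"]
            conspecifics = [i for i in locals_of[(sp, site)] if i != ind]
            if len(conspecifics) < sc.k_retained:
                skipped += 1
                continue
            rng = np.random.default_rng([seed, sc.k_retained, j])
            retained = list(rng.choice(conspecifics, size=sc.k_retained,
                                       replace=False)) if sc.k_retained else []
            drop_inds = [ind] + [c for c in conspecifics if c not in retained]
            masked = pd.Index(np.concatenate(
                [np.asarray(rows_of_ind[i]) for i in drop_inds]))
            training = df.loc[df.index.difference(masked)]
            assert not training.index.intersection(masked).size  # no leakage
            tr_sp = training.loc[training["species"] == sp]
            if sc.estimator == "species_average":
                if tr_sp.empty:
                    skipped += 1
                    continue
                yhat = float(tr_sp["wsg"].mean())
            elif sc.estimator == "study_average":
                same = tr_sp.loc[tr_sp["source"] == info["source"], "wsg"]
                if same.empty:
                    skipped += 1
                    continue
                yhat = float(same.mean())
            elif sc.estimator == "local_average":
                local = tr_sp.loc[tr_sp["site_id"] == site, "wsg"]
                if local.empty:
                    skipped += 1
                    continue
                yhat = float(local.mean())
            else:
                where = df.loc[rows_of_ind[ind][:1],
                               ["family", "genus", "species", "source",
                                "site_id"]].copy()
                where["branch01"] = float(
                    df.loc[rows_of_ind[ind], "branch01"].mean())
                yhat = _blup_predict(base_fits[sc.estimator], training, where,
                                     refit_components)
            preds.append(yhat)
            obs.append(float(info["wsg"]))
        if len(preds) >= 2:
            rmse, r2 = score(preds, obs, "regression")
            _, r2_id = score(preds, obs, "one_to_one")
        else:
            rmse = r2 = r2_id = float("nan")
        res = ExperimentResult(sc, rmse, r2, r2_id, len(preds), skipped)
        if keep_predictions:
            res.predictions = pd.DataFrame({"pred": preds, "obs": obs})
        results.append(res)
    return results
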