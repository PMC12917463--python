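import numpy as np
import pandas as pd
import pytest

from gwdvar import (EnvEffect, SyntheticConfig, TissueEffect, generate,
                    compose_variance_report, distribution_shape,
                    normal_tail_share, rescale_to_realized_range,
                    run_tissue_contrast, run_variance_partition,
                    run_within_between, subtract_source_effect,
                    two_draw_interval)


class TestComposeVarianceReport:
    def test_published_global_components(self):
        """The five global SDs compose to total 0.178, taxonomy 77%, residual 15%."""
        rep = compose_variance_report(
            {"family": 0.098, "genus": 0.097, "species": 0.074,
             "source": 0.049, "Residual": 0.068},
            {"taxonomic": ["family", "genus", "species"]})
        assert rep.total_sd == pytest.approx(0.178, abs=5e-4)
        # per-level shares reproduce the printed integers exactly
        printed = {"family": 30, "genus": 30, "species": 17,
                   "source": 8, "Residual": 15}
        for level, pct in printed.items():
            assert round(100 * rep.share[level]) == pct, level
        assert rep.grouped_shares["taxonomic"] == pytest.approx(0.77, abs=0.01)
        tax_sd = np.sqrt(rep.grouped_shares["taxonomic"]) * rep.total_sd
        assert tax_sd == pytest.approx(0.156, abs=5e-4)
        assert sum(rep.share.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_component(self):
        rep = compose_variance_report({"only": 0.3})
        assert rep.share["only"] == 1.0 and rep.total_sd == 0.3

    def test_two_equal_components(self):
        s = 0.1
        rep = compose_variance_report({"a": s, "b": s})
        assert rep.share["a"] == pytest.approx(0.5)
        assert rep.total_sd == pytest.approx(s * np.sqrt(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compose_variance_report({"a": 0.0, "b": 0.0})


class TestVariancePartition:
    def test_taxonomy_nesting_recovers_components(self, small_table1_ds):
        res, rep = run_variance_partition(small_table1_ds.records,
                                          include_source=True)
        cfg = small_table1_ds.truth["config"]
        # moderate data: generous bands, ordering and magnitude must hold
        assert rep.sd["Residual"] == pytest.approx(cfg.sd_residual, rel=0.10)
        assert rep.sd["(1 | family)"] == pytest.approx(cfg.sd_family, rel=0.5)
        assert rep.grouped_shares["taxonomic"] > 0.5

    def test_single_family_level_dropped(self):
        cfg = SyntheticConfig(seed=3, n_families=1, genera_per_family=10,
                              species_per_genus=4, sites_per_species=2,
                              individuals_per_site=3,
                              measurements_per_individual=2, n_sources=8)
        ds = generate(cfg)
        with pytest.warns(UserWarning, match="single group"):
            res, rep = run_variance_partition(ds.records)
        assert rep.dropped_levels == ["(1 | family)"]
        assert rep.sd["Residual"] == pytest.approx(cfg.sd_residual, rel=0.2)

    def test_site_share_exceeds_individual_share(self):
        cfg = SyntheticConfig(seed=21, n_families=10, genera_per_family=2,
                              species_per_genus=3, sites_per_species=4,
                              individuals_per_site=3,
                              measurements_per_individual=2, n_sources=8,
                              sd_site=0.06, sd_individual=0.02,
                              sd_residual=0.04)
        ds = generate(cfg)
        df = ds.records.copy()
        df["site_id"] = df["site_key"]
        res, rep = run_variance_partition(df, include_source=False,
                                          nesting="species_site_individual")
        site = rep.share["(1 | species:site_id)"]
        ind = rep.share["(1 | species:site_id:id_plant)"]
        assert site > ind

    def test_plant_agg_records_excluded_from_individual_partition(self):
        cfg = SyntheticConfig(seed=4, n_families=6, genera_per_family=2,
                              species_per_genus=2, sites_per_species=2,
                              individuals_per_site=3,
                              measurements_per_individual=2, n_sources=5)
        df = generate(cfg).records.copy()
        df["site_id"] = df["site_key"]
        df.loc[df.index[:10], "plant_agg"] = True
        res, _ = run_variance_partition(df, include_source=False,
                                        nesting="species_site_individual")
        assert res.nobs == len(df) - 10


class TestTissueContrast:
    def test_zero_effect_everywhere(self):
        cfg = SyntheticConfig(seed=5, n_families=20, genera_per_family=2,
                              species_per_genus=2, sites_per_species=2,
                              individuals_per_site=2,
                              measurements_per_individual=2, n_sources=10,
                              tissue_effects={"branch": TissueEffect(0.0, 0.0)},
                              location_mix={"trunk": 0.5, "branch": 0.5})
        ds = generate(cfg)
        res, summ = run_tissue_contrast(ds.records, "branch_vs_trunk")
        assert abs(summ.mean_effect) < 3 * summ.se_effect
        assert summ.slope_sd < 0.03

    def test_recoding_flips_sign_exactly(self):
        cfg = SyntheticConfig(seed=6, n_families=15, genera_per_family=2,
                              species_per_genus=2, sites_per_species=2,
                              individuals_per_site=2,
                              measurements_per_individual=2, n_sources=8,
                              tissue_effects={"branch": TissueEffect(-0.05, 0.03)},
                              location_mix={"trunk": 0.5, "branch": 0.5})
        df = generate(cfg).records
        _, fwd = run_tissue_contrast(df, "branch_vs_trunk")
        flipped = df.copy()
        flipped["location_sample"] = flipped["location_sample"].map(
            {"trunk": "branch", "branch": "trunk"})
        _, rev = run_tissue_contrast(flipped, "branch_vs_trunk")
        # near-exact: the diagonal intercept/slope covariance makes the two
        # codings slightly non-equivalent models
        assert rev.mean_effect == pytest.approx(-fwd.mean_effect, abs=5e-4)

    def test_one_level_inestimable(self):
        df = pd.DataFrame({"wsg": [0.5] * 8, "species": list("aabbccdd"),
                           "source": "S", "location_sample": "trunk"})
        with pytest.raises(ValueError, match="inestimable"):
            run_tissue_contrast(df, "branch_vs_trunk")

    def test_same_individual_pairing_samples_one_per_tissue(self):
        cfg = SyntheticConfig(seed=7, n_families=10, genera_per_family=2,
                              species_per_genus=2, sites_per_species=2,
                              individuals_per_site=2,
                              measurements_per_individual=4, n_sources=6,
                              tissue_effects={"branch": TissueEffect(-0.03, 0.02)},
                              location_mix={"trunk": 0.5, "branch": 0.5})
        df = generate(cfg).records
        res, summ = run_tissue_contrast(df, "branch_vs_trunk",
                                        pairing="same_individual", seed=1)
        both = (df.assign(b=df["location_sample"])
                .groupby("id_plant")["b"].nunique() == 2).sum()
        # one record per tissue per individual with both tissues
        assert res.nobs == 2 * both


class TestWithinBetween:
    def test_equal_between_within_construction(self):
        cfg = SyntheticConfig(
            seed=8, n_families=20, genera_per_family=3, species_per_genus=5,
            sites_per_species=3, individuals_per_site=4,
            measurements_per_individual=1, n_sources=5,
            sd_family=0, sd_genus=0, sd_species=0.12, sd_source=0,
            sd_residual=0.06,
            env={"temperature": EnvEffect(0.8, 0.6, beta_between=0.03,
                                          gamma_within_mean=0.03,
                                          gamma_within_sd=0.0)})
        ds = generate(cfg)
        res, table = run_within_between(ds.records, ["temperature"])
        row = table.effects.loc["temperature"]
        diff = row["between"] - row["within"]
        se = np.hypot(row["between_se"], row["within_se"])
        assert abs(diff) < 3 * se

    def test_no_within_variance_between_equals_species_mean_ols(self):
        cfg = SyntheticConfig(
            seed=9, n_families=10, genera_per_family=3, species_per_genus=4,
            sites_per_species=1, individuals_per_site=4,
            measurements_per_individual=1, n_sources=4,
            sd_family=0, sd_genus=0, sd_species=0.10, sd_source=0,
            sd_residual=0.05,
            env={"temperature": EnvEffect(1.0, 0.0, beta_between=0.04)})
        ds = generate(cfg)
        res, table = run_within_between(ds.records, ["temperature"])
        row = table.effects.loc["temperature"]
        assert not row["estimable_within"]
        assert np.isnan(row["within"])  # inestimable, not zero
        df = res.model.data
        sp = df.groupby("species").agg(y=("wsg", "mean"),
                                       x=("temperature_between", "first"))
        ols = np.polyfit(sp["x"], sp["y"], 1)[0]
        # balanced design: GLS on species means coincides with OLS
        assert row["between"] == pytest.approx(ols, abs=1e-8)

    def test_no_spurious_effects_on_noise_covariates(self):
        hits = 0
        for rep in range(10):
            cfg = SyntheticConfig(
                seed=300 + rep, n_families=10, genera_per_family=2,
                species_per_genus=4, sites_per_species=3,
                individuals_per_site=3, measurements_per_individual=1,
                n_sources=4, sd_family=0, sd_genus=0, sd_species=0.12,
                sd_source=0, sd_residual=0.06,
                env={"noise": EnvEffect(0.7, 0.7)})
            ds = generate(cfg)
            _, table = run_within_between(ds.records, ["noise"])
            row = table.effects.loc["noise"]
            ok = (abs(row["between"]) < 3 * row["between_se"]) and \
                 (abs(row["within"]) < 3 * row["within_se"])
            hits += ok
        assert hits >= 9

    def test_recovery_of_generative_effects(self):
        from gwdvar import within_between_config
        ds = generate(within_between_config(13, n_species=600))
        res, table = run_within_between(
            ds.records, ["temperature", "water_deficit"])
        eff = table.effects
        for cov in ("temperature", "water_deficit"):
            truth = ds.truth["config"].env[cov].gamma_within_mean
            row = eff.loc[cov]
            assert abs(row["within"] - truth) < 3 * row["within_se"]
        assert eff.loc["water_deficit", "slope_sd"] == pytest.approx(
            0.038, rel=0.25)


class TestRescale:
    def _table(self):
        from gwdvar.analysis import EffectTable
        slopes = pd.DataFrame({"temp": [0.01, 0.02]}, index=["a", "b"])
        ranges = pd.DataFrame({"temp_range": [2.0, 0.0], "n": [5, 5]},
                              index=["a", "b"])
        eff = pd.DataFrame({"within": [0.015]}, index=pd.Index(["temp"],
                                                               name="covariate"))
        return EffectTable(effects=eff, within_between_correlation=np.nan,
                           per_species_slopes=slopes, group_ranges=ranges)

    def test_arithmetic_and_zero_range(self):
        table = rescale_to_realized_range(self._table())
        assert table.rescaled.loc["a", "temp"] == pytest.approx(0.02)
        assert table.rescaled.loc["b", "temp"] == 0.0

    def test_pipeline_scale_invariance(self):
        cfg_env = {"temperature": EnvEffect(0.8, 0.6, beta_between=0.04,
                                            gamma_within_mean=0.012,
                                            gamma_within_sd=0.02)}
        cfg = SyntheticConfig(
            seed=10, n_families=10, genera_per_family=3, species_per_genus=5,
            sites_per_species=3, individuals_per_site=3,
            measurements_per_individual=1, n_sources=4,
            sd_family=0, sd_genus=0, sd_species=0.1, sd_source=0,
            sd_residual=0.05, env=cfg_env)
        ds = generate(cfg)
        _, t1 = run_within_between(ds.records, ["temperature"])
        t1 = rescale_to_realized_range(t1)
        doubled = ds.records.copy()
        doubled["temperature"] = 2.0 * doubled["temperature"]
        _, t2 = run_within_between(doubled, ["temperature"])
        t2 = rescale_to_realized_range(t2)
        # doubling raw covariates is absorbed by the z-scoring
        assert np.allclose(t1.rescaled["temperature"],
                           t2.rescaled["temperature"], atol=1e-8)


class TestClosedForms:
    @pytest.mark.parametrize("mean,sd,thr,side,expect", [
        (-0.023, 0.075, 0.015, "upper", 0.306),
        (0.010, 0.038, -0.010, "lower", 0.299),
        (0.0, 0.5, 0.0, "upper", 0.5),
    ])
    def test_tail_shares(self, mean, sd, thr, side, expect):
        assert normal_tail_share(mean, sd, thr, side) == pytest.approx(
            expect, abs=5e-3)

    def test_tails_and_centre_sum_to_one(self):
        up = normal_tail_share(0.02, 0.05, 0.03, "upper")
        lo = normal_tail_share(0.02, 0.05, -0.03, "lower")
        centre = normal_tail_share(0.02, 0.05, 0.03, "lower") - lo
        assert up + lo + centre == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("sd,expect", [
        (0.068, 0.19), (0.0, 0.0), (1.0, 2.7718)])
    def test_two_draw_interval(self, sd, expect):
        assert two_draw_interval(sd) == pytest.approx(expect, abs=5e-3)


class TestDistributionShape:
    def test_gaussian_rejection_near_alpha(self):
        rng = np.random.default_rng(1)
        n_sp, n = 300, 30
        df = pd.DataFrame({
            "species": np.repeat([f"s{i}" for i in range(n_sp)], n),
            "wsg": 0.6 + 0.05 * rng.standard_normal(n_sp * n)})
        verdicts, summary = distribution_shape(df, min_n=8, alpha=0.05)
        assert summary["n_species"] == n_sp
        assert 0.02 <= summary["frac_rejected_raw"] <= 0.10

    def test_lognormal_species_rejected_on_raw_scale(self):
        rng = np.random.default_rng(2)
        n_sp, n = 80, 60
        df = pd.DataFrame({
            "species": np.repeat([f"s{i}" for i in range(n_sp)], n),
            "wsg": np.exp(rng.normal(-0.6, 0.6, n_sp * n))})
        _, summary = distribution_shape(df, min_n=8)
        assert summary["frac_rejected_raw"] > summary["frac_rejected_log"]

    def test_species_below_min_n_absent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"species": ["few"] * 4 + ["many"] * 20,
                           "wsg": 0.5 + 0.02 * rng.standard_normal(24)})
        verdicts, _ = distribution_shape(df, min_n=8)
        assert list(verdicts.index) == ["many"]


def test_subtract_source_effect_removes_study_offsets(small_table1_ds):
    df = small_table1_ds.records
    res, _ = run_variance_partition(df, include_source=True)
    adj = subtract_source_effect(df, res)
    raw_within = df.groupby("source")["wsg"].mean().std()
    adj_within = adj.groupby(df["source"]).mean().std()
    assert adj_within < raw_within
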