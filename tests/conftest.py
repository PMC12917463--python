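import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture()
def tiny_csv(tmp_path):
    """Hand-written 3-row table with one missing latitude cell."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "wsg,value_reference,quantity_reference,wsg_conversion,family,genus,"
        "species,rank_taxonomic,source,location_sample,type_tissue,"
        "longitude,latitude\n"
        "0.60,0.60,basic,1.0,Fagaceae,Quercus,Quercus robur,species,S1,"
        "trunk,heartwood,10.004,45.008\n"
        "0.56,0.70,air_dry,0.8,Fagaceae,Quercus,Quercus ilex,species,S1,"
        "branch,sapwood,10.005,45.009\n"
        "0.70,0.70,basic,1.0,Pinaceae,Pinus,Pinus nigra,species,S2,"
        "trunk,unknown,2.5,\n")
    return path


@pytest.fixture()
def filter_frame():
    """Ten records: one bark, one root, one genus-rank, one plantation."""
    base = dict(wsg=0.5, species="Sp a", genus="Ga", family="Fa",
                rank_taxonomic="species", source="S1", type_tissue="unknown",
                location_sample="trunk", type_forest="natural",
                experiment_design="")
    rows = [dict(base) for _ in range(10)]
    rows[1]["type_tissue"] = "bark"
    rows[3]["location_sample"] = "root"
    rows[5]["rank_taxonomic"] = "genus"
    rows[7]["type_forest"] = "plantation"
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_table1_ds():
    """Moderate nested/crossed dataset with the published component SDs."""
    from gwdvar import SyntheticConfig, generate
    cfg = SyntheticConfig(seed=11, n_families=30, genera_per_family=2,
                          species_per_genus=2, sites_per_species=2,
                          individuals_per_site=2,
                          measurements_per_individual=2, n_sources=12)
    return generate(cfg)


@pytest.fixture(scope="session")
def prediction_ds():
    from gwdvar import generate, prediction_config
    return generate(prediction_config(7))
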