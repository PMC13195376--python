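import pandas as pd
import pytest

from tractprev import GeneratorConfig, run_study
from tractprev.synthetic_ehr import generate_ehr_tables, generate_population


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=11, n_persons=4000, n_tracts=40, n_systems=5)


@pytest.fixture(scope="session")
def small_truth_census(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_tables(small_config, small_truth_census):
    truth, _ = small_truth_census
    return generate_ehr_tables(small_config, truth)


@pytest.fixture(scope="session")
def small_study(small_config):
    return run_study(small_config)


@pytest.fixture(scope="session")
def recovery_config():
    """Full care-seeking, perfect diagnosis coding and geocoding, no census
    undercount: downstream estimates must recover the truth exactly."""
    mix = GeneratorConfig().demographic_mix
    return GeneratorConfig(
        seed=5,
        n_persons=6000,
        n_tracts=40,
        n_systems=5,
        care_seeking_prob={s: 1.0 for s in mix},
        dx_sensitivity=1.0,
        geocode_success_prob=1.0,
        multi_system_prob=0.3,
    )


@pytest.fixture(scope="session")
def recovery_study(recovery_config):
    return run_study(recovery_config)


def make_persons(rows):
    """Person-table helper for linkage tests."""
    cols = [
        "identity_hash",
        "system_id",
        "birth_date",
        "death_date",
        "sex",
        "race_ethnicity",
        "tract_id",
        "zip_code",
        "address_date",
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("birth_date", "death_date", "address_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def make_encounters(rows):
    df = pd.DataFrame(rows, columns=["identity_hash", "system_id", "encounter_date"])
    df["encounter_date"] = pd.to_datetime(df["encounter_date"])
    return df
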