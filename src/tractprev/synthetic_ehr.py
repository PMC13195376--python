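"""Seeded generator for a complete synthetic study input set.

Produces, from a single :class:`~tractprev.config.GeneratorConfig`, everything
the surveillance pipeline consumes: per-system EHR extracts (person, encounter,
condition occurrence, blood pressure, HbA1c tables), a census-style population
cross-tabulation by tract and demographic stratum, a model-based tract
prevalence table standing in for survey small-area estimates, a zip-to-tract
crosswalk, tract covariates, and the underlying ground truth for
parameter-recovery tests.

The statistical structure emulated:

* a statewide population partitioned across overlapping health systems, with
  care-seeking probabilities varying by age/sex/race stratum so downstream
  EHR-to-census stratum ratios differ from 1;
* diagnosis-code sensitivity below 1, supplemented by blood-pressure and
  HbA1c capture so the vitals/labs arms of the computable phenotypes matter;
* tract-level true prevalence driven linearly by tract covariates (age
  structure, race composition, social vulnerability, rurality, poverty,
  education);
* a fraction of addresses that fail to geocode and carry only a zip code;
* noisy, optionally biased model-based tract estimates.

Identity keys are salted hashes of a synthetic (name, birth date) pair with
the salt fixed per run — a stand-in for privacy-preserving hashed identifiers,
with no cryptographic claims.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_GROUPS, CONDITIONS, ConfigurationError, GeneratorConfig

__all__ = [
    "TruthTable",
    "generate_population",
    "generate_ehr_tables",
    "generate_places_like",
    "simulate",
    "concat_systems",
    "tract_linear_predictor",
]

_AGE_RANGE = {"0-17": (0, 17), "18-44": (18, 44), "45-64": (45, 64), "65+": (65, 95)}

URBANICITY_LEVELS = ("urban", "exurban", "rural", "small_town")

PERSON_COLUMNS = [
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


@dataclass
class TruthTable:
    """Ground truth behind one synthetic run.

    Attributes
    ----------
    persons
        One row per person: identity hash, demographic stratum, true tract,
        birth date and true condition indicators (minors are never cases; the
        phenotypes are defined on adults).
    tracts
        Per-tract county, zip, population counts and realized true prevalence
        (the exact person-level mean of indicators among the tract's adults,
        percent scale).
    tract_covariates
        Tract covariate table used both to drive true prevalence and as the
        regression design downstream.
    crosswalk
        Zip-to-tract allocation weights (population ratios; each zip's weights
        sum to 1).
    stratum_counts
        True population count per (age_group, sex, race_ethnicity) stratum.
    """

    persons: pd.DataFrame
    tracts: pd.DataFrame
    tract_covariates: pd.DataFrame
    crosswalk: pd.DataFrame
    stratum_counts: pd.DataFrame


def _identity_hashes(seed: int, person_ids: np.ndarray, birth_dates: np.ndarray) -> list[str]:
    salt = f"run-salt-{seed}".encode()
    out = []
    for pid, bd in zip(person_ids, birth_dates):
        h = hashlib.sha256(salt + f"|P{pid:08d}|{bd}".encode()).hexdigest()
        out.append(h[:24])
    return out


def tract_linear_predictor(covariates: pd.DataFrame, coefs) -> np.ndarray:
    """Evaluate a linear predictor over the tract covariate table.

    Keys of ``coefs``: ``intercept``, covariate column names (``svi`` maps to
    the continuous 0-1 ``svi_continuous`` column), and ``urbanicity:<level>``
    additive shifts relative to urban.
    """
    out = np.full(len(covariates), float(coefs.get("intercept", 0.0)))
    for key, c in coefs.items():
        if key == "intercept":
            continue
        if key == "svi":
            out += c * covariates["svi_continuous"].to_numpy()
        elif key.startswith("urbanicity:"):
            level = key.split(":", 1)[1]
            out += c * (covariates["urbanicity"] == level).to_numpy()
        else:
            out += c * covariates[key].to_numpy()
    return out


def _generate_covariates(rng: np.random.Generator, n_tracts: int) -> pd.DataFrame:
    """Tract covariates with realistic marginal spread (percent scales)."""
    cov = pd.DataFrame(
        {
            "tract_id": [f"T{i:04d}" for i in range(n_tracts)],
            "pct_over_65": np.clip(rng.normal(17.0, 6.0, n_tracts), 2.0, 45.0),
            "pct_black": np.clip(rng.gamma(1.0, 5.0, n_tracts), 0.0, 60.0),
            "pct_aian": np.clip(rng.gamma(0.5, 2.0, n_tracts), 0.0, 80.0),
            "pct_asian_hpi": np.clip(rng.gamma(1.0, 4.0, n_tracts), 0.0, 40.0),
            "svi_continuous": rng.uniform(0.0, 1.0, n_tracts),
            "urbanicity": np.asarray(URBANICITY_LEVELS)[
                rng.choice(4, n_tracts, p=[0.55, 0.15, 0.20, 0.10])
            ],
            "pct_below_poverty": np.clip(rng.gamma(2.0, 4.0, n_tracts), 0.0, 60.0),
            "pct_hs_or_ged": np.clip(rng.normal(92.0, 5.0, n_tracts), 50.0, 100.0),
        }
    )
    return cov


def generate_population(config: GeneratorConfig):
    """Generate the true population and its census cross-tabulation.

    Returns
    -------
    (TruthTable, DataFrame)
        The truth table and the census table (one row per observed
        tract x age_group x sex x race_ethnicity cell with a ``count``
        column; counts equal the truth cross-tabulation exactly unless a
        per-stratum undercount factor is configured).
    """
    config.validate()
    rng = np.random.default_rng([0, config.seed])
    n = config.n_persons
    n_tracts = config.n_tracts

    covariates = _generate_covariates(rng, n_tracts)
    tract_ids = covariates["tract_id"].to_numpy()
    n_counties = max(1, n_tracts // 15)
    county_of_tract = np.array(
        [f"C{i * n_counties // n_tracts:03d}" for i in range(n_tracts)]
    )

    strata = config.strata
    probs = np.array([config.demographic_mix[s] for s in strata])
    stratum_idx = rng.choice(len(strata), size=n, p=probs)
    age_group = np.array([strata[i][0] for i in stratum_idx])
    sex = np.array([strata[i][1] for i in stratum_idx])
    race = np.array([strata[i][2] for i in stratum_idx])

    tract_weights = rng.dirichlet(np.full(n_tracts, 8.0))
    tract_idx = rng.choice(n_tracts, size=n, p=tract_weights)

    lo = np.array([_AGE_RANGE[a][0] for a in age_group])
    hi = np.array([_AGE_RANGE[a][1] for a in age_group])
    age = rng.integers(lo, hi + 1)
    birth_year = config.index_year - age
    birth_month = rng.integers(1, 13, n)
    birth_day = rng.integers(1, 29, n)
    birth_date = pd.to_datetime(
        {"year": birth_year, "month": birth_month, "day": birth_day}
    ).to_numpy()

    adult = age >= 18
    target_prev = {}
    for cond in CONDITIONS:
        lp = tract_linear_predictor(covariates, config.prevalence_coefs[cond])
        target_prev[cond] = np.clip(lp, 0.5, 95.0)
    indicators = {}
    for cond in CONDITIONS:
        u = rng.random(n)
        indicators[cond] = adult & (u < target_prev[cond][tract_idx] / 100.0)

    # Zip codes: consecutive tracts grouped into zips of 1-3 tracts each.
    zip_of_tract = np.empty(n_tracts, dtype=object)
    i, z = 0, 0
    while i < n_tracts:
        size = int(rng.integers(1, 4))
        for j in range(i, min(i + size, n_tracts)):
            zip_of_tract[j] = f"55{z:03d}"
        i += size
        z += 1

    person_ids = np.arange(n)
    hashes = _identity_hashes(config.seed, person_ids, birth_date.astype("datetime64[D]"))

    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "identity_hash": hashes,
            "age_group": age_group,
            "sex": sex,
            "race_ethnicity": race,
            "age": age,
            "birth_date": birth_date,
            "tract_id": tract_ids[tract_idx],
            "zip_code": zip_of_tract[tract_idx],
            "hypertension": indicators["hypertension"],
            "diabetes": indicators["diabetes"],
        }
    )

    pop_by_tract = np.bincount(tract_idx, minlength=n_tracts).astype(float)
    adult_by_tract = np.bincount(tract_idx[adult], minlength=n_tracts).astype(float)
    tracts = pd.DataFrame(
        {
            "tract_id": tract_ids,
            "county_id": county_of_tract,
            "zip_code": zip_of_tract,
            "population": pop_by_tract,
            "adult_population": adult_by_tract,
        }
    )
    for cond in CONDITIONS:
        cases = np.bincount(tract_idx[indicators[cond]], minlength=n_tracts)
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = np.where(adult_by_tract > 0, 100.0 * cases / adult_by_tract, np.nan)
        tracts[f"{cond}_true_prev_pct"] = prev
        tracts[f"{cond}_true_cases"] = cases.astype(float)

    # Crosswalk weights: each zip's population allocated across its tracts.
    zpop = tracts.groupby("zip_code")["population"].transform("sum")
    weight = np.where(zpop > 0, tracts["population"] / zpop.replace(0, np.nan), np.nan)
    crosswalk = pd.DataFrame(
        {"zip_code": tracts["zip_code"], "tract_id": tracts["tract_id"], "weight": weight}
    )
    # Zips whose realized population is zero get uniform weights.
    zero = crosswalk["weight"].isna()
    if zero.any():
        sizes = crosswalk.groupby("zip_code")["tract_id"].transform("size")
        crosswalk.loc[zero, "weight"] = 1.0 / sizes[zero]
    crosswalk = crosswalk.sort_values(["zip_code", "tract_id"]).reset_index(drop=True)

    stratum_counts = (
        persons.groupby(["age_group", "sex", "race_ethnicity"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["age_group", "sex", "race_ethnicity"])
        .reset_index(drop=True)
    )

    census = (
        persons.groupby(["tract_id", "age_group", "sex", "race_ethnicity"], observed=True)
        .size()
        .rename("count")
        .astype(float)
        .reset_index()
    )
    if config.census_undercount:
        factors = census.apply(
            lambda r: config.census_undercount.get(
                (r["age_group"], r["sex"], r["race_ethnicity"]), 1.0
            ),
            axis=1,
        )
        census["count"] = census["count"] * factors
    census = census.merge(tracts[["tract_id", "county_id"]], on="tract_id")
    census = census.sort_values(
        ["tract_id", "age_group", "sex", "race_ethnicity"]
    ).reset_index(drop=True)

    truth = TruthTable(
        persons=persons,
        tracts=tracts,
        tract_covariates=covariates,
        crosswalk=crosswalk,
        stratum_counts=stratum_counts,
    )
    return truth, census


def _window(index_year: int):
    start = np.datetime64(f"{index_year - 2}-01-01")
    end = np.datetime64(f"{index_year}-12-31")
    ndays = int((end - start).astype(int)) + 1
    return start, ndays


def generate_ehr_tables(config: GeneratorConfig, truth: TruthTable) -> dict[str, dict[str, pd.DataFrame]]:
    """Generate per-system EHR extracts consistent with the truth table.

    Every care-seeking person appears in at least one system with at least one
    encounter inside the 3-calendar-year window ending December 31 of the
    index year; multi-system persons carry the same identity hash in each
    system. True cases emit a condition code with probability
    ``dx_sensitivity`` and a qualifying vitals/lab signature per
    ``measurement_rates``; non-cases only ever emit sub-threshold values.

    Returns a mapping ``system_id -> {"persons", "encounters", "conditions",
    "bp", "a1c"}`` of DataFrames.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    p = truth.persons
    n = len(p)
    start, ndays = _window(config.index_year)

    strata = config.strata
    care_p = np.empty(n)
    key = list(zip(p["age_group"], p["sex"], p["race_ethnicity"]))
    lookup = {s: config.care_seeking_prob.get(s, 0.0) for s in strata}
    care_p[:] = [lookup[k] for k in key]
    care = rng.random(n) < care_p

    n_sys = config.n_systems
    primary = rng.integers(0, n_sys, n)
    multi = care & (rng.random(n) < config.multi_system_prob) & (n_sys > 1)
    if n_sys > 1:
        secondary = (primary + 1 + rng.integers(0, n_sys - 1, n)) % n_sys
    else:
        secondary = primary.copy()

    sys_labels = np.array(config.system_ids)

    def _encounter_block(person_mask: np.ndarray, system_idx: np.ndarray, lam: float):
        idx = np.flatnonzero(person_mask)
        counts = 1 + rng.poisson(lam, idx.size)
        rep = np.repeat(idx, counts)
        offs = rng.integers(0, ndays, rep.size)
        return pd.DataFrame(
            {
                "identity_hash": p["identity_hash"].to_numpy()[rep],
                "system_id": sys_labels[system_idx[rep]],
                "encounter_date": start + offs.astype("timedelta64[D]"),
                "_pidx": rep,
            }
        )

    enc_primary = _encounter_block(care, primary, 2.0)
    enc_secondary = _encounter_block(multi, secondary, 0.7)
    encounters = pd.concat([enc_primary, enc_secondary], ignore_index=True)

    rates = config.measurement_rates
    p_bp = float(rates.get("bp", 0.0))
    p_a1c = float(rates.get("a1c", 0.0))

    # Condition occurrences: one token per condition, emitted in the primary
    # system with probability dx_sensitivity, dated inside the 3-year window
    # (hence also inside any 5-year code lookback ending at the index year).
    cond_frames = []
    for cond, token in (("hypertension", "HTN"), ("diabetes", "DM")):
        mask = care & p[cond].to_numpy() & (rng.random(n) < config.dx_sensitivity)
        idx = np.flatnonzero(mask)
        offs = rng.integers(0, ndays, idx.size)
        cond_frames.append(
            pd.DataFrame(
                {
                    "identity_hash": p["identity_hash"].to_numpy()[idx],
                    "system_id": sys_labels[primary[idx]],
                    "condition": token,
                    "condition_date": start + offs.astype("timedelta64[D]"),
                }
            )
        )
    conditions = pd.concat(cond_frames, ignore_index=True)

    # Blood pressure. Routine per-visit capture is always sub-threshold
    # (SBP < 140 and DBP < 90); true hypertensives additionally receive a
    # qualifying pair (SBP >= 140) on two distinct days with probability
    # measurement_rates["bp"], isolating the distinct-day rule.
    routine_mask = rng.random(len(enc_primary)) < p_bp
    routine = enc_primary.loc[routine_mask]
    bp_routine = pd.DataFrame(
        {
            "identity_hash": routine["identity_hash"].to_numpy(),
            "system_id": routine["system_id"].to_numpy(),
            "measurement_date": routine["encounter_date"].to_numpy(),
            "systolic": np.round(rng.uniform(100, 139, len(routine)), 0),
            "diastolic": np.round(rng.uniform(60, 88, len(routine)), 0),
            "outpatient": True,
        }
    )
    htn_pair = care & p["hypertension"].to_numpy() & (rng.random(n) < p_bp)
    hidx = np.flatnonzero(htn_pair)
    d1 = rng.integers(0, ndays, hidx.size)
    d2 = (d1 + 1 + rng.integers(0, ndays - 1, hidx.size)) % ndays
    pair_frames = []
    for d in (d1, d2):
        pair_frames.append(
            pd.DataFrame(
                {
                    "identity_hash": p["identity_hash"].to_numpy()[hidx],
                    "system_id": sys_labels[primary[hidx]],
                    "measurement_date": start + d.astype("timedelta64[D]"),
                    "systolic": np.round(rng.uniform(141, 180, hidx.size), 0),
                    "diastolic": np.round(rng.uniform(60, 88, hidx.size), 0),
                    "outpatient": True,
                }
            )
        )
    bp = pd.concat([bp_routine, *pair_frames], ignore_index=True)

    # HbA1c: one qualifying value (>= 6.5%) for true diabetics with
    # probability measurement_rates["a1c"]; background sub-threshold values
    # for a fraction of non-diabetic care-seekers.
    dm_mask = care & p["diabetes"].to_numpy() & (rng.random(n) < p_a1c)
    didx = np.flatnonzero(dm_mask)
    bg_mask = care & ~p["diabetes"].to_numpy() & (rng.random(n) < 0.5 * p_a1c)
    bidx = np.flatnonzero(bg_mask)
    a1c = pd.DataFrame(
        {
            "identity_hash": np.concatenate(
                [p["identity_hash"].to_numpy()[didx], p["identity_hash"].to_numpy()[bidx]]
            ),
            "system_id": np.concatenate([sys_labels[primary[didx]], sys_labels[primary[bidx]]]),
            "measurement_date": np.concatenate(
                [
                    start + rng.integers(0, ndays, didx.size).astype("timedelta64[D]"),
                    start + rng.integers(0, ndays, bidx.size).astype("timedelta64[D]"),
                ]
            ),
            "a1c_pct": np.concatenate(
                [
                    np.round(rng.uniform(6.5, 9.5, didx.size), 1),
                    np.round(rng.uniform(4.8, 6.4, bidx.size), 1),
                ]
            ),
        }
    )

    # Person rows: one per (person, system) pair with any encounter; the
    # address record is dated at the person's latest encounter in that system.
    geocoded = rng.random(n) < config.geocode_success_prob
    addr = (
        encounters.groupby(["_pidx", "system_id"], observed=True)["encounter_date"]
        .max()
        .rename("address_date")
        .reset_index()
    )
    pidx = addr["_pidx"].to_numpy()
    persons_all = pd.DataFrame(
        {
            "identity_hash": p["identity_hash"].to_numpy()[pidx],
            "system_id": addr["system_id"].to_numpy(),
            "birth_date": p["birth_date"].to_numpy()[pidx],
            "death_date": pd.NaT,
            "sex": p["sex"].to_numpy()[pidx],
            "race_ethnicity": p["race_ethnicity"].to_numpy()[pidx],
            "tract_id": np.where(geocoded[pidx], p["tract_id"].to_numpy()[pidx], None),
            "zip_code": p["zip_code"].to_numpy()[pidx],
            "address_date": addr["address_date"].to_numpy(),
        }
    )

    encounters = encounters.drop(columns="_pidx")
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    for s in config.system_ids:
        tables[s] = {
            "persons": persons_all[persons_all["system_id"] == s]
            .sort_values("identity_hash")
            .reset_index(drop=True),
            "encounters": encounters[encounters["system_id"] == s]
            .sort_values(["identity_hash", "encounter_date"])
            .reset_index(drop=True),
            "conditions": conditions[conditions["system_id"] == s]
            .sort_values(["identity_hash", "condition", "condition_date"])
            .reset_index(drop=True),
            "bp": bp[bp["system_id"] == s]
            .sort_values(["identity_hash", "measurement_date"])
            .reset_index(drop=True),
            "a1c": a1c[a1c["system_id"] == s]
            .sort_values(["identity_hash", "measurement_date"])
            .reset_index(drop=True),
        }
    return tables


def generate_places_like(truth: TruthTable, config: GeneratorConfig) -> pd.DataFrame:
    """Model-based tract prevalence estimates: truth + bias + Gaussian noise.

    The survey small-area model itself is out of scope; its output regime is
    emulated as ``clip(true_prev + bias + N(0, sd), 0, 100)`` per tract and
    condition, alongside the tract's adult population denominator.
    """
    config.validate()
    rng = np.random.default_rng([2, config.seed])
    t = truth.tracts
    out = pd.DataFrame(
        {"tract_id": t["tract_id"], "adult_population": t["adult_population"]}
    )
    for cond in CONDITIONS:
        true = t[f"{cond}_true_prev_pct"].to_numpy()
        noise = rng.normal(0.0, config.places_noise_sd, len(t))
        est = np.clip(true + config.places_bias + noise, 0.0, 100.0)
        out[f"{cond}_prev_pct"] = np.where(np.isnan(true), np.nan, est)
    return out


def concat_systems(tables: dict[str, dict[str, pd.DataFrame]], name: str) -> pd.DataFrame:
    """Concatenate one table kind across all systems."""
    return pd.concat([t[name] for t in tables.values()], ignore_index=True)


def simulate(config: GeneratorConfig, out_dir: str | Path) -> None:
    """Run all three generation stages and write the CSV file set.

    Emits ``persons_<system>.csv``, ``encounters_<system>.csv``,
    ``conditions_<system>.csv``, ``bp_<system>.csv``, ``a1c_<system>.csv``
    per system, plus ``census.csv``, ``places.csv``, ``crosswalk.csv``,
    ``tract_covariates.csv``, ``truth.csv`` and ``tract_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, census = generate_population(config)
    tables = generate_ehr_tables(config, truth)
    places = generate_places_like(truth, config)
    for s, tabs in tables.items():
        for name, df in tabs.items():
            df.to_csv(out / f"{name}_{s}.csv", index=False)
    census.to_csv(out / "census.csv", index=False)
    places.to_csv(out / "places.csv", index=False)
    truth.crosswalk.to_csv(out / "crosswalk.csv", index=False)
    truth.tract_covariates.to_csv(out / "tract_covariates.csv", index=False)
    truth.persons.to_csv(out / "truth.csv", index=False)
    truth.tracts.to_csv(out / "tract_truth.csv", index=False)
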