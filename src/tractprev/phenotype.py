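"""Eligibility rules and computable phenotypes for hypertension and diabetes.

A person is in the surveillance denominator for a given index year if they are
alive on December 31 of that year, meet the age condition on that date (18+
for prevalence analyses; no age floor for all-ages population counts), and
have at least one encounter in their assigned health system within the 3
calendar years ending that December 31.

Computable phenotypes (all windows are whole calendar years ending December 31
of the index year, so e.g. a 3-year window for 2020 is 2018-2020):

* hypertension — at least one hypertension condition code in the last 5
  years, OR an elevated outpatient blood pressure (systolic >= 140 mm Hg or
  diastolic >= 90 mm Hg within a single reading) on 2 or more distinct days
  in the last 3 years;
* diabetes — at least one diabetes condition code in the last 5 years, OR at
  least one hemoglobin A1c value >= 6.5% in the last 3 years.

All thresholds are inclusive. A day qualifies for the blood-pressure arm if
any outpatient reading that day qualifies; missing components are
non-qualifying for that component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EligibilityRule",
    "PhenotypeRule",
    "hypertension_rule",
    "diabetes_rule",
    "eligible_mask",
    "hypertension_mask",
    "diabetes_mask",
    "has_hypertension",
    "has_diabetes",
    "build_cohort",
]

CONDITION_TOKENS = {"hypertension": "HTN", "diabetes": "DM"}


@dataclass(frozen=True)
class EligibilityRule:
    index_year: int
    min_age: int | None = 18
    lookback_years_encounter: int = 3


@dataclass(frozen=True)
class PhenotypeRule:
    condition: str
    dx_lookback_years: int = 5
    measure_lookback_years: int = 3
    bp_systolic_threshold: float = 140.0
    bp_diastolic_threshold: float = 90.0
    bp_min_distinct_days: int = 2
    a1c_threshold: float = 6.5
    a1c_min_count: int = 1


def hypertension_rule() -> PhenotypeRule:
    return PhenotypeRule("hypertension")


def diabetes_rule() -> PhenotypeRule:
    return PhenotypeRule("diabetes")


def _age_on_dec31(birth_date: pd.Series, index_year: int) -> pd.Series:
    # Age on December 31 is simply index_year - birth year: every birthday in
    # the birth year has passed by that date.
    return index_year - pd.to_datetime(birth_date).dt.year


def eligible_mask(assigned: pd.DataFrame, rule: EligibilityRule) -> pd.Series:
    """Vectorized eligibility over linked persons.

    Requires ``birth_date``, ``death_date``, ``n_encounter_days`` (distinct
    in-window days in the assigned system) and ``assignable`` columns, as
    produced by :func:`tractprev.linkage.link`.
    """
    iy = rule.index_year
    dec31 = pd.Timestamp(iy, 12, 31)
    alive = pd.to_datetime(assigned["death_date"]).isna() | (
        pd.to_datetime(assigned["death_date"]) > dec31
    )
    has_encounter = assigned["assignable"] & (assigned["n_encounter_days"] >= 1)
    ok = alive & has_encounter
    if rule.min_age is not None:
        birth = pd.to_datetime(assigned["birth_date"])
        missing = birth.isna()
        if missing.any():
            logger.warning(
                "excluding %d persons with missing birth_date under an age rule",
                int(missing.sum()),
            )
        age = _age_on_dec31(assigned["birth_date"], iy)
        ok = ok & ~missing & (age >= rule.min_age)
    return ok.rename("eligible")


def _years(dates) -> pd.Series:
    return pd.to_datetime(pd.Series(dates)).dt.year


def hypertension_mask(
    hashes: pd.Series,
    conditions: pd.DataFrame,
    bp: pd.DataFrame,
    index_year: int,
    rule: PhenotypeRule | None = None,
) -> pd.Series:
    """Boolean per identity hash: meets the hypertension phenotype."""
    rule = rule or hypertension_rule()
    iy = index_year
    cy = _years(conditions["condition_date"])
    dx = conditions.loc[
        (conditions["condition"] == CONDITION_TOKENS["hypertension"])
        & (cy >= iy - rule.dx_lookback_years + 1)
        & (cy <= iy),
        "identity_hash",
    ].unique()

    by = _years(bp["measurement_date"])
    sbp = pd.to_numeric(bp["systolic"], errors="coerce")
    dbp = pd.to_numeric(bp["diastolic"], errors="coerce")
    qual = (
        bp["outpatient"].astype(bool)
        & (
            (sbp >= rule.bp_systolic_threshold).fillna(False)
            | (dbp >= rule.bp_diastolic_threshold).fillna(False)
        )
        & (by >= iy - rule.measure_lookback_years + 1)
        & (by <= iy)
    )
    qbp = bp.loc[qual, ["identity_hash", "measurement_date"]]
    ndays = (
        qbp.assign(day=pd.to_datetime(qbp["measurement_date"]).dt.normalize())
        .drop_duplicates(["identity_hash", "day"])
        .groupby("identity_hash", observed=True)
        .size()
    )
    bp_hashes = ndays[ndays >= rule.bp_min_distinct_days].index
    flagged = set(dx) | set(bp_hashes)
    return hashes.isin(flagged).rename("hypertension")


def diabetes_mask(
    hashes: pd.Series,
    conditions: pd.DataFrame,
    a1c: pd.DataFrame,
    index_year: int,
    rule: PhenotypeRule | None = None,
) -> pd.Series:
    """Boolean per identity hash: meets the diabetes phenotype."""
    rule = rule or diabetes_rule()
    iy = index_year
    cy = _years(conditions["condition_date"])
    dx = conditions.loc[
        (conditions["condition"] == CONDITION_TOKENS["diabetes"])
        & (cy >= iy - rule.dx_lookback_years + 1)
        & (cy <= iy),
        "identity_hash",
    ].unique()
    ly = _years(a1c["measurement_date"])
    vals = pd.to_numeric(a1c["a1c_pct"], errors="coerce")
    lab = a1c.loc[
        (vals >= rule.a1c_threshold).fillna(False)
        & (ly >= iy - rule.measure_lookback_years + 1)
        & (ly <= iy),
        "identity_hash",
    ]
    lab_counts = lab.value_counts()
    lab_hashes = lab_counts[lab_counts >= rule.a1c_min_count].index
    flagged = set(dx) | set(lab_hashes)
    return hashes.isin(flagged).rename("diabetes")


def _single(hash_: str, frame_cols: dict) -> pd.DataFrame:
    return pd.DataFrame(frame_cols)


def has_hypertension(
    conditions: pd.DataFrame, bp: pd.DataFrame, index_year: int,
    rule: PhenotypeRule | None = None,
) -> bool:
    """Single-person convenience wrapper over :func:`hypertension_mask`."""
    hashes = pd.Series(["_x"])
    c = conditions.assign(identity_hash="_x") if len(conditions) else _empty_conditions()
    b = bp.assign(identity_hash="_x") if len(bp) else _empty_bp()
    return bool(hypertension_mask(hashes, c, b, index_year, rule).iloc[0])


def has_diabetes(
    conditions: pd.DataFrame, a1c: pd.DataFrame, index_year: int,
    rule: PhenotypeRule | None = None,
) -> bool:
    """Single-person convenience wrapper over :func:`diabetes_mask`."""
    hashes = pd.Series(["_x"])
    c = conditions.assign(identity_hash="_x") if len(conditions) else _empty_conditions()
    a = a1c.assign(identity_hash="_x") if len(a1c) else _empty_a1c()
    return bool(diabetes_mask(hashes, c, a, index_year, rule).iloc[0])


def _empty_conditions() -> pd.DataFrame:
    return pd.DataFrame(
        {"identity_hash": pd.Series(dtype=str), "condition": pd.Series(dtype=str),
         "condition_date": pd.Series(dtype="datetime64[ns]")}
    )


def _empty_bp() -> pd.DataFrame:
    return pd.DataFrame(
        {"identity_hash": pd.Series(dtype=str),
         "measurement_date": pd.Series(dtype="datetime64[ns]"),
         "systolic": pd.Series(dtype=float), "diastolic": pd.Series(dtype=float),
         "outpatient": pd.Series(dtype=bool)}
    )


def _empty_a1c() -> pd.DataFrame:
    return pd.DataFrame(
        {"identity_hash": pd.Series(dtype=str),
         "measurement_date": pd.Series(dtype="datetime64[ns]"),
         "a1c_pct": pd.Series(dtype=float)}
    )


def build_cohort(
    assigned: pd.DataFrame,
    conditions: pd.DataFrame,
    bp: pd.DataFrame,
    a1c: pd.DataFrame,
    index_year: int,
    min_age: int | None = 18,
) -> pd.DataFrame:
    """Eligibility-filter the linked persons and attach phenotype flags.

    Returns one row per eligible person with demographics, geography and
    boolean ``hypertension`` / ``diabetes`` columns for the index year.
    """
    rule = EligibilityRule(index_year=index_year, min_age=min_age)
    ok = eligible_mask(assigned, rule)
    cohort = assigned.loc[ok].copy()
    cohort["hypertension"] = hypertension_mask(
        cohort["identity_hash"], conditions, bp, index_year
    ).to_numpy()
    cohort["diabetes"] = diabetes_mask(
        cohort["identity_hash"], conditions, a1c, index_year
    ).to_numpy()
    return cohort.reset_index(drop=True)
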