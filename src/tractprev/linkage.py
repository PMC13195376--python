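"""Cross-system deduplication and reporting-system assignment.

Persons who sought care at multiple health systems are linked by exact match
on a privacy-preserving identity hash, then assigned to exactly one reporting
system by frequency of care: the system with the most distinct encounter days
in the 3 calendar years ending December 31 of the index year. Ties break to
the lexicographically smallest system id, making assignment deterministic and
invariant to input row order. "Frequency of care" is counted in distinct
encounter days rather than raw encounter rows, so duplicate same-day rows do
not inflate a system's claim.

Demographics are taken from the assigned system's person record, falling back
to the most recent non-missing value (by address record date) from any
system; geography comes from the most recent address record across systems.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["deduplicate", "assign_system", "link"]

_DEMOGRAPHIC_COLS = ["birth_date", "death_date", "sex", "race_ethnicity"]
_GEO_COLS = ["tract_id", "zip_code"]


def deduplicate(persons: pd.DataFrame) -> pd.DataFrame:
    """Collapse person rows to one per (identity_hash, system_id).

    Groups are exact-match equivalence classes on the identity hash; the
    number of distinct hashes in the result equals the number of linked
    persons. Duplicate (hash, system) rows are collapsed keeping the row with
    the latest address record, with a logged warning.
    """
    if (persons["identity_hash"].astype(str) == "").any():
        raise ValueError("empty identity_hash")
    dup = persons.duplicated(["identity_hash", "system_id"])
    if dup.any():
        logger.warning(
            "collapsing %d duplicate (identity_hash, system_id) rows", int(dup.sum())
        )
        persons = (
            persons.sort_values(
                ["identity_hash", "system_id", "address_date"],
                kind="mergesort",
            )
            .drop_duplicates(["identity_hash", "system_id"], keep="last")
        )
    return persons.sort_values(["identity_hash", "system_id"], kind="mergesort").reset_index(
        drop=True
    )


def assign_system(day_counts: Mapping[str, int]) -> str | None:
    """Pick the reporting system from in-window distinct-day counts.

    Returns the system with the maximal count, ties broken by smallest
    system id; ``None`` if every count is zero (no in-window care, so the
    person cannot be assigned).
    """
    positive = {s: c for s, c in day_counts.items() if c > 0}
    if not positive:
        return None
    return min(positive, key=lambda s: (-positive[s], s))


def link(
    persons: pd.DataFrame,
    encounters: pd.DataFrame,
    index_year: int,
) -> pd.DataFrame:
    """Deduplicate and assign every person to one reporting system.

    Parameters
    ----------
    persons
        Person rows from all systems (columns ``identity_hash``,
        ``system_id``, ``birth_date``, ``death_date``, ``sex``,
        ``race_ethnicity``, ``tract_id``, ``zip_code``, ``address_date``).
    encounters
        Encounter rows from all systems (``identity_hash``, ``system_id``,
        ``encounter_date``).
    index_year
        Assignment counts distinct encounter days within calendar years
        [index_year - 2, index_year].

    Returns
    -------
    DataFrame
        One row per distinct identity hash: ``assigned_system`` (NA when the
        person has no in-window encounter anywhere — retained for audit with
        ``assignable == False``), merged demographics and geography, and
        ``n_encounter_days`` (distinct in-window days in the assigned system).
    """
    persons = deduplicate(persons)
    enc = encounters.copy()
    enc["encounter_date"] = pd.to_datetime(enc["encounter_date"])
    year = enc["encounter_date"].dt.year
    inwin = enc[(year >= index_year - 2) & (year <= index_year)]
    days = (
        inwin.drop_duplicates(["identity_hash", "system_id", "encounter_date"])
        .groupby(["identity_hash", "system_id"], observed=True)
        .size()
        .rename("n_encounter_days")
        .reset_index()
    )
    # Max distinct-day count, ties to smallest system_id: sort then take first.
    chosen = (
        days.sort_values(
            ["identity_hash", "n_encounter_days", "system_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .drop_duplicates("identity_hash")
        .rename(columns={"system_id": "assigned_system"})
    )

    all_hashes = persons[["identity_hash"]].drop_duplicates().reset_index(drop=True)
    out = all_hashes.merge(chosen, on="identity_hash", how="left")
    out["assignable"] = out["assigned_system"].notna()
    out["n_encounter_days"] = out["n_encounter_days"].fillna(0).astype(int)

    # Demographics: assigned system first, else most recent non-missing.
    persons = persons.copy()
    persons["address_date"] = pd.to_datetime(persons["address_date"])
    assigned_rows = out[["identity_hash", "assigned_system"]].merge(
        persons,
        left_on=["identity_hash", "assigned_system"],
        right_on=["identity_hash", "system_id"],
        how="left",
    )
    recent = persons.sort_values(
        ["identity_hash", "address_date", "system_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    fallback = recent.groupby("identity_hash", observed=True)[_DEMOGRAPHIC_COLS].first()
    for col in _DEMOGRAPHIC_COLS:
        vals = assigned_rows.set_index("identity_hash")[col]
        filled = vals.fillna(fallback[col])
        out[col] = out["identity_hash"].map(filled)

    # Geography: the most recent address record across systems (ties prefer
    # the smallest system id).
    geo = recent.drop_duplicates("identity_hash")[["identity_hash", *_GEO_COLS]]
    out = out.merge(geo, on="identity_hash", how="left")
    return out.sort_values("identity_hash", kind="mergesort").reset_index(drop=True)
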