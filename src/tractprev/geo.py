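"""Census tract resolution with zip-to-tract crosswalk fallback.

Persons whose address geocoded to a tract keep that tract with weight 1.
Persons carrying only a zip code are allocated across the zip's tracts using
population-ratio crosswalk weights, in one of two modes:

* ``fractional`` (default) — each person contributes fractional counts equal
  to the crosswalk weights; variance-free and conserves counts exactly;
* ``sampled`` — each person is placed in one tract drawn with the crosswalk
  weights, using a per-person seed derived from the identity hash so the draw
  is deterministic and invariant to row order.

Persons whose zip is absent from the crosswalk go to an "unassigned" bucket
reported separately.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

__all__ = ["validate_crosswalk", "resolve_tracts", "tract_estimates"]


def validate_crosswalk(crosswalk: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check that each zip's allocation weights sum to 1."""
    sums = crosswalk.groupby("zip_code")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(
            f"crosswalk weights do not sum to 1 for zips: {list(bad.index[:5])}"
        )


def _person_uniform(identity_hash: pd.Series, seed: int) -> np.ndarray:
    """Order-invariant U(0,1) per person, derived from (seed, identity hash)."""
    out = np.empty(len(identity_hash))
    for i, h in enumerate(identity_hash):
        dig = hashlib.sha256(f"{seed}:{h}".encode()).digest()
        out[i] = int.from_bytes(dig[:8], "big") / 2**64
    return out


def resolve_tracts(
    persons: pd.DataFrame,
    crosswalk: pd.DataFrame,
    mode: str = "fractional",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve each person to tract allocation weights.

    Parameters
    ----------
    persons
        Rows with ``identity_hash``, ``tract_id`` (nullable) and ``zip_code``.
    crosswalk
        ``zip_code``, ``tract_id``, ``weight`` rows; weights per zip sum to 1.
    mode
        ``"fractional"`` or ``"sampled"``.
    seed
        Used in sampled mode only; combined with each identity hash so the
        assignment does not depend on row order.

    Returns
    -------
    (allocations, unassigned)
        ``allocations`` has one row per (person, tract) with a ``weight``
        column (weight 1 rows for geocoded persons and, in sampled mode, for
        crosswalk draws). ``unassigned`` lists persons with no tract and a
        zip missing from the crosswalk.
    """
    if mode not in ("fractional", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    validate_crosswalk(crosswalk)
    has_tract = persons["tract_id"].notna() & (persons["tract_id"].astype(str) != "")
    geocoded = persons.loc[has_tract, ["identity_hash", "tract_id"]].copy()
    geocoded["weight"] = 1.0

    rest = persons.loc[~has_tract, ["identity_hash", "zip_code"]]
    known = rest["zip_code"].isin(crosswalk["zip_code"])
    unassigned = rest.loc[~known].reset_index(drop=True)
    rest = rest.loc[known]

    if rest.empty:
        alloc = geocoded
    else:
        merged = rest.merge(crosswalk, on="zip_code", how="left").sort_values(
            ["identity_hash", "tract_id"], kind="mergesort"
        )
        if mode == "fractional":
            alloc = pd.concat(
                [geocoded, merged[["identity_hash", "tract_id", "weight"]]],
                ignore_index=True,
            )
        else:
            u = rest.set_index("identity_hash")
            u_map = pd.Series(
                _person_uniform(u.index.to_series(), seed), index=u.index
            )
            merged["u"] = merged["identity_hash"].map(u_map)
            cum = merged.groupby("identity_hash", observed=True)["weight"].cumsum()
            merged["hit"] = (merged["u"] < cum) & (merged["u"] >= cum - merged["weight"])
            picked = merged.loc[merged["hit"]].drop_duplicates("identity_hash")
            # Guard against float slack at the top of the cumulative scale.
            missing = set(rest["identity_hash"]) - set(picked["identity_hash"])
            if missing:
                last = merged[merged["identity_hash"].isin(missing)].drop_duplicates(
                    "identity_hash", keep="last"
                )
                picked = pd.concat([picked, last], ignore_index=True)
            picked = picked[["identity_hash", "tract_id"]].copy()
            picked["weight"] = 1.0
            alloc = pd.concat([geocoded, picked], ignore_index=True)
    return (
        alloc.sort_values(["identity_hash", "tract_id"], kind="mergesort").reset_index(
            drop=True
        ),
        unassigned,
    )


def tract_estimates(
    cohort: pd.DataFrame,
    allocations: pd.DataFrame,
    flag: str,
    source: str = "EHR",
) -> pd.DataFrame:
    """Aggregate person allocations to per-tract numerator/denominator.

    ``flag`` names a boolean column on ``cohort`` (e.g. ``hypertension``);
    the numerator is the allocation-weighted count of flagged persons and the
    denominator the weighted cohort size, so fractional allocation conserves
    totals exactly.
    """
    merged = allocations.merge(
        cohort[["identity_hash", flag]], on="identity_hash", how="inner"
    )
    merged["num"] = merged["weight"] * merged[flag].astype(float)
    agg = (
        merged.groupby("tract_id", observed=True)
        .agg(numerator=("num", "sum"), denominator=("weight", "sum"))
        .reset_index()
    )
    agg["prevalence_pct"] = 100.0 * agg["numerator"] / agg["denominator"]
    agg.insert(1, "source", source)
    return agg
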