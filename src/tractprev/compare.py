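"""Comparison of EHR-derived counts and prevalence against census and
model-based small-area estimates.

Covers the reporting arithmetic of multi-source surveillance: per-stratum
EHR-to-census count ratios, statewide coverage percentage, county ratio
summaries, tract-level relative differences against a reference source,
within-band concordance shares, and Bland-Altman agreement statistics (mean
difference and mean ± 1.96·SD limits of agreement).

Display rounding is half-up (2 decimals for ratios, 1 decimal for
percentages); unrounded values are always retained in machine output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "ratio_table",
    "coverage_percent",
    "county_ratio_summary",
    "relative_difference",
    "ConcordanceSummary",
    "concordance",
    "bland_altman_plot",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed tables), not
    banker's rounding."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ratio_table(
    ehr_counts: pd.Series,
    census_counts: pd.Series,
) -> pd.DataFrame:
    """Per-stratum EHR-to-census count ratios.

    Both inputs are indexed by stratum (any hashable label or MultiIndex);
    strata are aligned on the union of both indexes, missing counts as 0.
    Strata with zero census count get an undefined (NaN) ratio and a flag.

    Returns columns ``ehr_n``, ``census_n``, ``ratio`` (unrounded),
    ``ratio_2dp`` (half-up display value) and ``undefined``.
    """
    df = pd.DataFrame({"ehr_n": ehr_counts, "census_n": census_counts}).fillna(0.0)
    undefined = df["census_n"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, df["ehr_n"] / df["census_n"])
    df["ratio"] = ratio
    df["ratio_2dp"] = [round_half_up(r, 2) for r in ratio]
    df["undefined"] = undefined.to_numpy()
    return df


def coverage_percent(ehr_total: float, census_total: float) -> float:
    """EHR population as a percentage of the census estimate (unrounded;
    display at 1 decimal half-up)."""
    if census_total <= 0:
        raise ValueError("census_total must be positive")
    return 100.0 * ehr_total / census_total


def county_ratio_summary(ratios) -> tuple[float, tuple[float, float]]:
    """Median and IQR (25th/75th percentiles, linear interpolation) of
    per-county coverage ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one county ratio")
    med = float(np.percentile(arr, 50))
    q1, q3 = (float(np.percentile(arr, q)) for q in (25, 75))
    return med, (q1, q3)


def relative_difference(estimate_pct: float, reference_pct: float) -> float:
    """(estimate - reference) / reference; reference must be positive."""
    if reference_pct <= 0:
        raise ValueError("reference prevalence must be positive")
    return (estimate_pct - reference_pct) / reference_pct


@dataclass
class ConcordanceSummary:
    """Tract-level agreement between an estimate source and its reference.

    Within-band counts use |relative difference| <= band (inclusive) with the
    reference source in the denominator. Bland-Altman components: per-tract
    difference (estimate − reference), mean difference and
    mean ± 1.96·SD limits of agreement.
    """

    n_tracts: int
    within: dict[float, int]
    share_within: dict[float, float]
    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    n_excluded_zero_reference: int = 0
    n_excluded_unmatched: int = 0
    per_tract: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_within_10pct(self) -> int:
        return self.within[0.10]

    @property
    def n_within_25pct(self) -> int:
        return self.within[0.25]

    @property
    def share_within_10pct(self) -> float:
        return self.share_within[0.10]

    @property
    def share_within_25pct(self) -> float:
        return self.share_within[0.25]


def concordance(
    estimate: pd.DataFrame,
    reference: pd.DataFrame,
    bands: tuple[float, ...] = (0.10, 0.25),
    value_col: str = "prevalence_pct",
) -> ConcordanceSummary:
    """Concordance and Bland-Altman agreement on the common tract set.

    Both frames need ``tract_id`` and a prevalence column (percent scale).
    Tracts present in only one source are excluded and counted in
    ``n_excluded_unmatched``; tracts with zero/missing reference prevalence
    are excluded and counted in ``n_excluded_zero_reference``. Shares are
    percentages (unrounded; display at 1 decimal half-up).
    """
    e = estimate[["tract_id", value_col]].rename(columns={value_col: "est"})
    r = reference[["tract_id", value_col]].rename(columns={value_col: "ref"})
    merged = e.merge(r, on="tract_id", how="inner")
    n_unmatched = (len(e) - len(merged)) + (len(r) - len(merged))
    usable = merged["ref"].notna() & (merged["ref"] > 0) & merged["est"].notna()
    n_zero_ref = int((~usable).sum())
    m = merged.loc[usable].copy()
    m["relative_difference"] = (m["est"] - m["ref"]) / m["ref"]
    m["difference"] = m["est"] - m["ref"]
    m["mean_of_pair"] = (m["est"] + m["ref"]) / 2.0
    n = len(m)
    within = {b: int((m["relative_difference"].abs() <= b).sum()) for b in sorted(bands)}
    share = {b: (100.0 * c / n if n else float("nan")) for b, c in within.items()}
    if n:
        md = float(m["difference"].mean())
        sd = float(m["difference"].std(ddof=1)) if n > 1 else 0.0
    else:
        md, sd = float("nan"), float("nan")
    return ConcordanceSummary(
        n_tracts=n,
        within=within,
        share_within=share,
        mean_difference=md,
        sd_difference=sd,
        limits_of_agreement=(md - 1.96 * sd, md + 1.96 * sd),
        n_excluded_zero_reference=n_zero_ref,
        n_excluded_unmatched=n_unmatched,
        per_tract=m.reset_index(drop=True),
    )


def bland_altman_plot(summary: ConcordanceSummary, path) -> None:
    """Write a Bland-Altman scatter (difference vs mean of pair) with the
    mean difference and limits of agreement as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = summary.per_tract
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(m["mean_of_pair"], m["difference"], s=6, alpha=0.5)
    ax.axhline(summary.mean_difference, color="k", lw=1)
    for y in summary.limits_of_agreement:
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("Mean of estimates (%)")
    ax.set_ylabel("Difference (estimate − reference, pp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
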