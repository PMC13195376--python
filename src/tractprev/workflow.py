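"""End-to-end orchestration: generator → linkage → phenotype → geography →
comparison → tract models.

Convenience layer used by the command-line interface and by whole-pipeline
tests; each step is a thin call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import compare, geo, linkage, phenotype, synthetic_ehr, tract_model
from .config import CONDITIONS, GeneratorConfig

__all__ = ["StudyResult", "run_study", "stratum_counts_from_cohort"]

_STRATUM_COLS = ["age_group", "sex", "race_ethnicity"]
_AGE_BINS = [(0, 17, "0-17"), (18, 44, "18-44"), (45, 64, "45-64"), (65, 200, "65+")]


def _age_group(age: pd.Series) -> pd.Series:
    out = pd.Series(index=age.index, dtype=object)
    for lo, hi, label in _AGE_BINS:
        out[(age >= lo) & (age <= hi)] = label
    return out


def stratum_counts_from_cohort(cohort: pd.DataFrame, index_year: int) -> pd.Series:
    """Population counts by (age_group, sex, race_ethnicity) stratum."""
    age = index_year - pd.to_datetime(cohort["birth_date"]).dt.year
    df = cohort.assign(age_group=_age_group(age))
    return df.groupby(_STRATUM_COLS, observed=True).size().astype(float)


@dataclass
class StudyResult:
    """Everything one synthetic end-to-end run produces."""

    truth: synthetic_ehr.TruthTable
    census: pd.DataFrame
    assigned: pd.DataFrame
    population: pd.DataFrame  # all-ages eligible persons (denominator cohort)
    cohort: pd.DataFrame  # adults with phenotype flags
    ratio_table: pd.DataFrame
    coverage_pct: float
    county_summary: tuple[float, tuple[float, float]]
    ehr_estimates: dict[str, pd.DataFrame]
    places: pd.DataFrame
    concordance: dict[str, compare.ConcordanceSummary]
    models: dict[tuple[str, str], tract_model.ModelResult]
    unassigned_geo: pd.DataFrame


def run_study(config: GeneratorConfig, geo_mode: str = "fractional") -> StudyResult:
    """Generate a synthetic input set and run the full analysis on it."""
    truth, census = synthetic_ehr.generate_population(config)
    tables = synthetic_ehr.generate_ehr_tables(config, truth)
    places_raw = synthetic_ehr.generate_places_like(truth, config)

    persons = synthetic_ehr.concat_systems(tables, "persons")
    encounters = synthetic_ehr.concat_systems(tables, "encounters")
    conditions = synthetic_ehr.concat_systems(tables, "conditions")
    bp = synthetic_ehr.concat_systems(tables, "bp")
    a1c = synthetic_ehr.concat_systems(tables, "a1c")

    assigned = linkage.link(persons, encounters, config.index_year)

    population = phenotype.build_cohort(
        assigned, conditions, bp, a1c, config.index_year, min_age=None
    )
    cohort = phenotype.build_cohort(
        assigned, conditions, bp, a1c, config.index_year, min_age=18
    )

    ehr_strata = stratum_counts_from_cohort(population, config.index_year)
    census_strata = census.groupby(_STRATUM_COLS, observed=True)["count"].sum()
    ratios = compare.ratio_table(ehr_strata, census_strata)
    coverage = compare.coverage_percent(float(len(population)), float(census["count"].sum()))

    tract_county = truth.tracts.set_index("tract_id")["county_id"]
    alloc, unassigned = geo.resolve_tracts(population, truth.crosswalk, mode=geo_mode)
    county_counts = (
        alloc.assign(county_id=alloc["tract_id"].map(tract_county))
        .groupby("county_id", observed=True)["weight"]
        .sum()
    )
    census_county = census.groupby("county_id", observed=True)["count"].sum()
    county_ratios = (county_counts / census_county).dropna()
    county_summary = compare.county_ratio_summary(county_ratios)

    alloc_adult, _ = geo.resolve_tracts(cohort, truth.crosswalk, mode=geo_mode)
    ehr_estimates = {
        cond: geo.tract_estimates(cohort, alloc_adult, cond, source="EHR")
        for cond in CONDITIONS
    }

    concord = {}
    models = {}
    cov = truth.tract_covariates
    for cond in CONDITIONS:
        places_cond = places_raw.rename(columns={f"{cond}_prev_pct": "prevalence_pct"})[
            ["tract_id", "prevalence_pct"]
        ]
        concord[cond] = compare.concordance(ehr_estimates[cond], places_cond)
        models[("EHR", cond)] = tract_model.fit_prevalence_model(
            ehr_estimates[cond], cov, source="EHR", condition=cond
        )
        models[("PLACES", cond)] = tract_model.fit_prevalence_model(
            places_cond.assign(source="PLACES"), cov, source="PLACES", condition=cond
        )

    return StudyResult(
        truth=truth,
        census=census,
        assigned=assigned,
        population=population,
        cohort=cohort,
        ratio_table=ratios,
        coverage_pct=coverage,
        county_summary=county_summary,
        ehr_estimates=ehr_estimates,
        places=places_raw,
        concordance=concord,
        models=models,
        unassigned_geo=unassigned,
    )
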