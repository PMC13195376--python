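"""Study configuration for the synthetic multi-system EHR generator.

The generator emulates a statewide health-care landscape of the kind used for
EHR-based chronic disease surveillance: a population of a few million people
partitioned across ~11 overlapping health systems, with care-seeking
probabilities that vary by demographic stratum, imperfect diagnosis-code
sensitivity supplemented by vitals and labs, and tract-level true prevalence
driven by social covariates.

Default demographic structure and care-seeking probabilities follow the 2020
Minnesota population: the joint (age group, sex, race/ethnicity) mix is built
from published census marginals assuming independence of sex and race within
age group, and per-stratum care-seeking probabilities are the observed
EHR-patient-to-census ratios for those marginals (clipped to [0, 1]; observed
ratios above 1 reflect census undercount, which is exposed separately via
``census_undercount`` and defaults to no undercount).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

AGE_GROUPS = ("0-17", "18-44", "45-64", "65+")
SEXES = ("female", "male")
# Mutually exclusive race/ethnicity grouping: Hispanic of any race, then
# non-Hispanic single-race groups, with multiracial/other collapsed.
RACE_ETHNICITY = (
    "hispanic",
    "nh_american_indian",
    "nh_asian_pacific_islander",
    "nh_black",
    "nh_white",
    "nh_other",
)

CONDITIONS = ("hypertension", "diabetes")

Stratum = tuple[str, str, str]  # (age_group, sex, race_ethnicity)

# 2020 census counts by sex x age group (statewide).
_CENSUS_SEX_AGE = {
    ("male", "0-17"): 673_827,
    ("male", "18-44"): 1_012_726,
    ("male", "45-64"): 714_245,
    ("male", "65+"): 434_650,
    ("female", "0-17"): 643_634,
    ("female", "18-44"): 992_022,
    ("female", "45-64"): 720_747,
    ("female", "65+"): 514_643,
}

# 2020 census counts by race/ethnicity x age group (statewide).
_CENSUS_RACE_AGE = {
    ("nh_american_indian", "0-17"): 17_486,
    ("nh_american_indian", "18-44"): 21_439,
    ("nh_american_indian", "45-64"): 12_859,
    ("nh_american_indian", "65+"): 5_262,
    ("nh_asian_pacific_islander", "0-17"): 83_539,
    ("nh_asian_pacific_islander", "18-44"): 140_585,
    ("nh_asian_pacific_islander", "45-64"): 56_245,
    ("nh_asian_pacific_islander", "65+"): 19_712,
    ("nh_black", "0-17"): 135_497,
    ("nh_black", "18-44"): 161_303,
    ("nh_black", "45-64"): 72_834,
    ("nh_black", "65+"): 23_216,
    ("hispanic", "0-17"): 126_873,
    ("hispanic", "18-44"): 150_957,
    ("hispanic", "45-64"): 54_280,
    ("hispanic", "65+"): 13_530,
    ("nh_white", "0-17"): 844_827,
    ("nh_white", "18-44"): 1_438_283,
    ("nh_white", "45-64"): 1_197_790,
    ("nh_white", "65+"): 872_980,
    ("nh_other", "0-17"): 109_239,
    ("nh_other", "18-44"): 92_181,
    ("nh_other", "45-64"): 40_984,
    ("nh_other", "65+"): 14_593,
}

# Observed EHR-patient-to-census ratios for the same marginals.
_RATIO_SEX_AGE = {
    ("male", "0-17"): 0.83,
    ("male", "18-44"): 0.85,
    ("male", "45-64"): 0.86,
    ("male", "65+"): 1.05,
    ("female", "0-17"): 0.83,
    ("female", "18-44"): 1.04,
    ("female", "45-64"): 0.96,
    ("female", "65+"): 1.05,
}
_RATIO_RACE_AGE = {
    ("nh_american_indian", "0-17"): 0.57,
    ("nh_american_indian", "18-44"): 0.77,
    ("nh_american_indian", "45-64"): 0.68,
    ("nh_american_indian", "65+"): 0.65,
    ("nh_asian_pacific_islander", "0-17"): 0.89,
    ("nh_asian_pacific_islander", "18-44"): 0.81,
    ("nh_asian_pacific_islander", "45-64"): 0.90,
    ("nh_asian_pacific_islander", "65+"): 1.08,
    ("nh_black", "0-17"): 1.10,
    ("nh_black", "18-44"): 1.25,
    ("nh_black", "45-64"): 1.14,
    ("nh_black", "65+"): 1.17,
    ("hispanic", "0-17"): 0.64,
    ("hispanic", "18-44"): 0.77,
    ("hispanic", "45-64"): 0.85,
    ("hispanic", "65+"): 0.87,
    ("nh_white", "0-17"): 0.82,
    ("nh_white", "18-44"): 0.91,
    ("nh_white", "45-64"): 0.88,
    ("nh_white", "65+"): 1.00,
    ("nh_other", "0-17"): 0.78,
    ("nh_other", "18-44"): 1.39,
    ("nh_other", "45-64"): 1.59,
    ("nh_other", "65+"): 4.01,
}


def default_demographic_mix() -> dict[Stratum, float]:
    """Joint (age, sex, race) proportions from the census marginals.

    Sex and race are taken as independent within age group, which is the finest
    structure the published marginals determine.
    """
    age_totals = {
        a: sum(_CENSUS_SEX_AGE[(s, a)] for s in SEXES) for a in AGE_GROUPS
    }
    total = sum(age_totals.values())
    race_age_totals = {
        a: sum(_CENSUS_RACE_AGE[(r, a)] for r in RACE_ETHNICITY) for a in AGE_GROUPS
    }
    mix: dict[Stratum, float] = {}
    for a in AGE_GROUPS:
        p_age = age_totals[a] / total
        for s in SEXES:
            p_sex = _CENSUS_SEX_AGE[(s, a)] / age_totals[a]
            for r in RACE_ETHNICITY:
                p_race = _CENSUS_RACE_AGE[(r, a)] / race_age_totals[a]
                mix[(a, s, r)] = p_age * p_sex * p_race
    # Exact renormalisation against rounding drift in the marginals.
    z = sum(mix.values())
    return {k: v / z for k, v in mix.items()}


def default_care_seeking_prob() -> dict[Stratum, float]:
    """Per-stratum probability of any encounter in the 3-year window.

    Composed multiplicatively from the sex-by-age and race-by-age observed
    ratios (divided by the age-level ratio so the age effect is not counted
    twice), then clipped to [0, 1].
    """
    age_ratio = {}
    for a in AGE_GROUPS:
        ehr = sum(_CENSUS_SEX_AGE[(s, a)] * _RATIO_SEX_AGE[(s, a)] for s in SEXES)
        cen = sum(_CENSUS_SEX_AGE[(s, a)] for s in SEXES)
        age_ratio[a] = ehr / cen
    probs: dict[Stratum, float] = {}
    for a in AGE_GROUPS:
        for s in SEXES:
            for r in RACE_ETHNICITY:
                p = _RATIO_SEX_AGE[(s, a)] * _RATIO_RACE_AGE[(r, a)] / age_ratio[a]
                probs[(a, s, r)] = min(max(p, 0.02), 1.0)
    return probs


def default_prevalence_coefs() -> dict[str, dict[str, float]]:
    """Tract-covariate coefficients generating true prevalence (percent scale).

    Linear predictor on the covariate columns; ``svi`` multiplies the
    continuous 0-1 social vulnerability index and ``urbanicity:<cat>`` are
    additive shifts relative to urban tracts. Chosen to yield roughly 30%
    statewide adult hypertension and 10% diabetes prevalence with positive
    age/SVI/rurality gradients and a negative education gradient.
    """
    return {
        "hypertension": {
            "intercept": 45.0,
            "pct_over_65": 0.55,
            "pct_black": 0.05,
            "pct_aian": 0.05,
            "pct_asian_hpi": -0.05,
            "svi": 4.0,
            "urbanicity:exurban": 4.0,
            "urbanicity:rural": 4.0,
            "urbanicity:small_town": 5.0,
            "pct_below_poverty": 0.0,
            "pct_hs_or_ged": -0.25,
        },
        "diabetes": {
            "intercept": 21.0,
            "pct_over_65": 0.15,
            "pct_black": 0.02,
            "pct_aian": 0.07,
            "pct_asian_hpi": 0.02,
            "svi": 2.0,
            "urbanicity:exurban": 1.0,
            "urbanicity:rural": 2.0,
            "urbanicity:small_town": 1.5,
            "pct_below_poverty": 0.0,
            "pct_hs_or_ged": -0.16,
        },
    }


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Seeded configuration fully determining a synthetic study input set.

    Parameters
    ----------
    seed
        Root seed; identical config + seed yields byte-identical tables.
    n_tracts, n_persons, n_systems
        Problem size. Eleven systems mirrors the statewide consortium.
    index_year
        Anchor year; eligibility windows end December 31 of this year.
    demographic_mix
        Mapping (age_group, sex, race_ethnicity) -> population proportion,
        summing to 1.
    care_seeking_prob
        Per-stratum probability of having any encounter in the 3-calendar-year
        window.
    multi_system_prob
        Probability a care-seeker also visits a second system.
    dx_sensitivity
        Probability a true case receives a condition code.
    measurement_rates
        ``{"bp": p, "a1c": p}`` — probability the vitals/lab pathway fires for
        a care-seeking true case (and background capture rates for non-cases).
    prevalence_coefs
        Per-condition linear coefficients from tract covariates to true
        prevalence, percent scale.
    places_noise_sd, places_bias
        Gaussian noise SD and additive bias (percentage points) of the
        model-based small-area estimates standing in for survey-model output.
    geocode_success_prob
        Probability a person's address geocodes to a tract; failures carry a
        zip code only.
    census_undercount
        Optional per-stratum multiplicative factor applied to census counts
        (default 1.0: census equals the truth cross-tabulation exactly).
    """

    seed: int = 17
    n_tracts: int = 150
    n_persons: int = 20_000
    n_systems: int = 11
    index_year: int = 2020
    demographic_mix: Mapping[Stratum, float] = field(
        default_factory=default_demographic_mix
    )
    care_seeking_prob: Mapping[Stratum, float] = field(
        default_factory=default_care_seeking_prob
    )
    multi_system_prob: float = 0.25
    dx_sensitivity: float = 0.85
    measurement_rates: Mapping[str, float] = field(
        default_factory=lambda: {"bp": 0.7, "a1c": 0.6}
    )
    prevalence_coefs: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_prevalence_coefs
    )
    places_noise_sd: float = 1.0
    places_bias: float = 0.0
    geocode_success_prob: float = 0.95
    census_undercount: Mapping[Stratum, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tracts <= 0 or self.n_persons <= 0 or self.n_systems <= 0:
            raise ConfigurationError("n_tracts, n_persons, n_systems must be positive")
        total = sum(self.demographic_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"demographic_mix proportions sum to {total!r}, expected 1"
            )
        for k, p in self.care_seeking_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"care_seeking_prob[{k!r}]={p} outside [0, 1]")
        for name in ("multi_system_prob", "dx_sensitivity", "geocode_success_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for k, p in self.measurement_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"measurement_rates[{k!r}]={p} outside [0, 1]")
        if self.places_noise_sd < 0:
            raise ConfigurationError("places_noise_sd must be nonnegative")
        for k, f in self.census_undercount.items():
            if f < 0:
                raise ConfigurationError(f"census_undercount[{k!r}]={f} negative")

    @property
    def strata(self) -> list[Stratum]:
        """Strata in deterministic (sorted) order."""
        return sorted(self.demographic_mix)

    @property
    def system_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_systems)]
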