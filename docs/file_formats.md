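# CSV schemas

All files are plain CSV with a header row; dates are ISO `YYYY-MM-DD`.
`tractprev simulate` writes the full set; real extracts with the same columns
can be substituted anywhere.

## Per-system EHR extracts

`persons_<system>.csv` — one row per (person, system)

| column | type | notes |
|---|---|---|
| identity_hash | str | salted hash shared by the same person across systems |
| system_id | str | e.g. `S03` |
| birth_date | date | |
| death_date | date | empty if alive |
| sex | str | `female` / `male` |
| race_ethnicity | str | `hispanic`, `nh_american_indian`, `nh_asian_pacific_islander`, `nh_black`, `nh_white`, `nh_other` |
| tract_id | str | empty when the address did not geocode |
| zip_code | str | always present |
| address_date | date | date of the address record (used for recency) |

`encounters_<system>.csv` — `identity_hash`, `system_id`, `encounter_date`.

`conditions_<system>.csv` — `identity_hash`, `system_id`, `condition`
(`HTN` / `DM` token), `condition_date`.

`bp_<system>.csv` — `identity_hash`, `system_id`, `measurement_date`,
`systolic` (mm Hg), `diastolic` (mm Hg), `outpatient` (bool).

`a1c_<system>.csv` — `identity_hash`, `system_id`, `measurement_date`,
`a1c_pct` (percent).

## Population and geography

`census.csv` — `tract_id`, `age_group` (`0-17`, `18-44`, `45-64`, `65+`),
`sex`, `race_ethnicity`, `count`, `county_id`.

`places.csv` — `tract_id`, `adult_population`,
`hypertension_prev_pct`, `diabetes_prev_pct` (percent, 0–100).

`crosswalk.csv` — `zip_code`, `tract_id`, `weight`; weights within a zip sum
to 1 (population-ratio semantics of the HUD zip–tract crosswalk).

`tract_covariates.csv` — `tract_id`, `pct_over_65`, `pct_black`, `pct_aian`,
`pct_asian_hpi`, `svi_continuous` (0–1), `urbanicity`
(`urban`/`exurban`/`rural`/`small_town`), `pct_below_poverty`,
`pct_hs_or_ged`. An `svi_quartile` column (1–4) may be supplied directly;
otherwise it is derived from `svi_continuous`.

## Ground truth (synthetic runs only)

`truth.csv` — per-person truth: `person_id`, `identity_hash`, stratum
columns, `age`, `birth_date`, `tract_id`, `zip_code`, `hypertension`,
`diabetes` indicators.

`tract_truth.csv` — `tract_id`, `county_id`, `zip_code`, `population`,
`adult_population`, `<condition>_true_prev_pct`, `<condition>_true_cases`.

## Analysis outputs

`tractprev compare` writes `ratio_table.csv` (stratum, `ehr_n`, `census_n`,
`ratio`, `ratio_2dp`, `undefined`), `concordance.csv` (per condition:
`n_tracts`, within-band counts and shares), `bland_altman.csv`
(`mean_difference`, `sd_difference`, `loa_low`, `loa_high`),
`per_tract_<condition>.csv` (per-tract estimate, reference, relative
difference, Bland-Altman components) and `summary.txt`.

`tractprev model` writes one row per (source, condition, term): `estimate`,
`ci_low`, `ci_high`, `p`, `r_squared`.
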