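# Methods

## The surveillance model

`tractprev` treats a statewide, multi-system EHR network as a population
measurement instrument. The estimand chain is:

1. **Denominator.** Persons are deduplicated across systems by exact match on
   a hashed identity key, assigned to one reporting system by frequency of
   care, and included for index year *y* if alive on December 31 of *y*, of
   qualifying age on that date, and seen in the assigned system during
   calendar years [*y*−2, *y*]. The result is a health-care-seeking
   population, not the census population; the comparison of the two is the
   first analysis output (stratum ratios, coverage percentage).
2. **Numerator.** Computable phenotypes on structured data:
   hypertension = condition code in [*y*−4, *y*] OR outpatient
   SBP ≥ 140 / DBP ≥ 90 mm Hg (evaluated within a single reading) on ≥ 2
   distinct days in [*y*−2, *y*]; diabetes = code in [*y*−4, *y*] OR
   HbA1c ≥ 6.5% in [*y*−2, *y*]. Thresholds inclusive.
3. **Small areas.** Persons resolve to census tracts; addresses that did not
   geocode are allocated by zip→tract population-ratio crosswalk weights.
   Tract prevalence is compared with model-based small-area estimates by
   relative difference, within-10%/25% concordance and Bland-Altman limits,
   and both sources are regressed on tract covariates by OLS.

### Assumptions

* Identity hashing is collision-free at the scales used (exact-match
  linkage; probabilistic linkage is out of scope).
* "Last N years" means N whole calendar years ending December 31 of the
  index year: the 3-year window for 2020 is 2018–2020. Lookbacks are
  anchored to December 31, not to encounter dates.
* A1c values arrive in percent, pre-harmonized.
* OLS inference assumes independence across tracts. Tracts are spatially
  correlated in reality, so the reported CIs understate uncertainty; no
  spatial correction is attempted.

## Interpretation rules fixed by this package

Several reporting conventions are under-determined in the field and are fixed
here, deterministically:

* **Frequency of care** counts *distinct encounter days*, not encounter
  rows, making assignment robust to duplicate same-day records. Ties on the
  day count break to the lexicographically smallest system id, so assignment
  is order-invariant and reproducible.
* **Demographic conflicts** across systems resolve to the assigned system's
  value, falling back to the most recent non-missing value by address-record
  date. **Geography** uses the most recent address record across all systems
  (ties prefer the smallest system id).
* **"Within X%"** concordance means |relative difference| ≤ X/100, boundary
  inclusive, with the model-based source as the reference denominator.
* **Crosswalk allocation** defaults to *fractional* mode: an un-geocoded
  person contributes the crosswalk weights as fractional counts, which is
  variance-free and conserves totals exactly. *Sampled* mode (one tract per
  person, drawn with the crosswalk weights from a per-person seed derived
  from the identity hash) exists for person-level outputs and is
  order-invariant by construction.
* **SVI quartiles** cut the continuous index at the within-dataset 25/50/75
  percentiles (linear interpolation); values tied with a boundary go to the
  lower quartile; quartile 1 is the least vulnerable. Constant input
  degenerates to quartile 1 everywhere, with a warning.
* **Display rounding** is decimal half-up: ratios at 2 decimals, percentages
  at 1. Machine outputs always retain the unrounded values.
* **Rank-deficient designs** are rejected with an error naming the collinear
  terms (pivoted-QR diagnosis) rather than silently dropped.

## The synthetic-data generator

The generator emulates the data regime the analysis assumes, with every
stochastic choice driven by one root seed (identical config + seed gives
byte-identical CSV output).

* **Demographic structure.** Default joint (age group, sex, race/ethnicity)
  proportions are built from published 2020 Minnesota census marginals,
  taking sex and race independent within age group — the finest structure the
  marginals determine. Age groups: 0–17, 18–44, 45–64, 65+; race/ethnicity
  uses the six mutually exclusive categories (Hispanic; non-Hispanic American
  Indian; Asian or Pacific Islander; Black; White; other).
* **Care seeking.** Default per-stratum probabilities are the observed
  statewide EHR-to-census ratios for those marginals, composed
  multiplicatively and clipped to [0, 1]. Observed ratios above 1 (e.g. for
  Black residents) cannot be care-seeking probabilities; they arise from
  census undercount, which the generator exposes as a separate per-stratum
  multiplicative factor defaulting to 1.0 (census = truth exactly). With
  stratum-varying care seeking, downstream stratum ratios converge to the
  configured probabilities within binomial error — the qualitative ratio
  structure of real EHR-to-census comparisons.
* **Systems.** Eleven systems by default. Market shares are uniform and a
  care-seeker visits a second system with probability 0.25; both are
  arbitrary, since real per-system shares and overlap rates are not
  published. Primary-system encounter days are 1 + Poisson(2), secondary
  1 + Poisson(0.7), uniform within the 3-year window, so assignment usually
  (not always) recovers the primary system.
* **Clinical signal.** True tract prevalence is a linear function of the
  tract covariates (coefficients chosen to give ≈30% adult hypertension and
  ≈10% diabetes with positive age/SVI/rurality and negative education
  gradients), realized per adult as a Bernoulli draw; minors are never cases,
  and the recorded per-tract truth is the exact realized mean among the
  tract's adults. True cases emit a condition code with probability
  `dx_sensitivity` (default 0.85) and a qualifying vitals/lab signature with
  the per-measurement capture probability; qualifying BP readings occur on
  exactly 2 distinct days (SBP 141–180), isolating the distinct-day rule.
  Non-cases only ever emit strictly sub-threshold values (SBP ≤ 139,
  DBP ≤ 88, A1c ≤ 6.4), so false positives cannot occur by construction.
* **Geocoding and geography.** Tracts group into zips of 1–3 consecutive
  tracts; crosswalk weights are the tracts' realized population shares within
  the zip. A fraction 1 − `geocode_success_prob` of persons carry only the
  zip.
* **Model-based reference estimates.** The survey small-area estimator is
  consumed, never re-implemented: its output is emulated as
  clip(truth + bias + N(0, σ), 0, 100) per tract with configurable bias and
  noise (defaults 0 and 1 percentage point).

### What the generator does **not** emulate

Realistic clinical longitudinality, ICD/SNOMED code dictionaries (one token
per condition suffices for the phenotype logic), hash collisions,
out-migration, undiagnosed disease beyond the sensitivity knob, spatially
correlated covariates, or the survey instrument behind the reference
estimates. Passing recovery tests therefore shows the *pipeline arithmetic*
is correct under the assumed regime — not that real EHR data meet the
regime's assumptions.

## Numerical choices

* Quantiles (county IQRs, SVI boundaries) use numpy's linear-interpolation
  percentile definition.
* Bland-Altman limits use the sample SD (ddof = 1) and ±1.96.
* Fractional allocation sums are exact up to float addition (weights per zip
  validated to sum to 1 within 1e-9).
* OLS is fit by statsmodels with normal-theory (non-robust) standard errors.
* Zero census counts make a ratio undefined (flagged, not NaN-propagated
  into summaries); zero or missing reference prevalence excludes a tract
  from concordance into a separately reported bucket, as do tracts present
  in only one source.

## Problem sizes

Default generator runs use 20,000 persons over 150 tracts; the test suite
exercises 4,000–8,000-person studies end to end, a 100,000-person run for
stratum-ratio recovery, 200 replicates of a 300-tract model fit for CI
coverage, and 10,000 crosswalk draws for the sampled-mode binomial check.
These sizes put every binomial/Monte-Carlo tolerance comfortably inside its
sampling error while keeping a full run in seconds.

## Known limitations

* Exact-match linkage only; any hash disagreement splits a person.
* The same-day SBP/DBP pairing rule (disjunction within one reading row)
  means separately-recorded same-day systolic and diastolic values are not
  combined before thresholding.
* The fractional-allocation default means person-level tract assignments are
  not materialized unless sampled mode is requested.
* Real covariate tables (true RUCA codes, observed SVI) can be supplied in
  place of the generated ones, but no derivation of RUCA from commuting data
  is provided.
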