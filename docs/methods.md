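# Methods

## Scope and model

`comorbibench` re-implements, as a tested pipeline, the comparative
validation of five claims-based comorbidity measures for predicting
one-year death and hospitalization: the count of distinct diagnoses, the
Charlson index, the Elixhauser condition indicators, the count of distinct
dispensed drug classes, and the Chronic Disease Score (CDS). Measures are
built from one fiscal year of claims (April 1 to March 31, the
"comorbidity year"); outcomes are assessed over the following fiscal year.

For each cohort and outcome, a *base* logistic model adjusts for age, a
quadratic age effect, sex, region of residence (urban/rural, with an
explicit missing category) and income quintile (five levels plus an
explicit missing category; quintile 1, rural and male are the reference
levels). Five *full* models each add one comorbidity measure. All measures
enter as a single continuous column except the Elixhauser index, which
enters as 31 separate indicator columns. Discrimination is quantified by
the c-statistic (area under the ROC curve) with a nonparametric
placement-value (DeLong) variance for confidence intervals and for the
paired test of the full model's c against the base model's; calibration by
the Brier score and the Hosmer–Lemeshow decile test.

## Measure definitions and numerical choices

* **Diagnosis count.** Distinct (coding system, 3-character rubric) pairs
  across hospital and physician sources. ICD-9 and ICD-10 rubrics never
  collapse onto each other — no cross-walk is attempted, so the same
  disease coded in both systems counts twice. Diagnoses flagged as
  in-hospital complications are *retained* here (the complication exclusion
  is specific to the index measures) but the policy is a function argument.
* **Charlson index.** 17 conditions matched by code prefix using the
  ICD-9/ICD-10 coding algorithm bundled as `data/charlson.csv`, weights in
  {1, 2, 3, 6}. Three hierarchies prevent double counting: complicated
  diabetes suppresses uncomplicated diabetes, moderate/severe liver disease
  suppresses mild liver disease, metastatic solid tumor suppresses
  non-metastatic malignancy. With all 17 conditions flagged the resolved
  maximum is **29** (the unhierarchied weight total is 33); the literature
  sometimes quotes a 0–32 range for this index, which corresponds to a
  different hierarchy subset — we document our attainable maximum rather
  than forcing that figure.
* **Elixhauser indicators.** 31 conditions, present/absent, no summary
  weights. Indicator order is fixed by the bundled table
  (`data/elixhauser.csv`, ordered by descending general-population
  prevalence) and preserved everywhere downstream (profile columns
  `elix_*`, design-matrix columns).
* **Drug count.** Distinct two-level ("four-digit") AHFS
  pharmacologic–therapeutic classes, e.g. `08:12`; deeper codes are
  truncated to two levels. Capped at 125. Records without a two-level
  class are rejected with a warning.
* **CDS.** Drug classes map to 17 chronic conditions; each condition
  contributes once, with a tier score that escalates with the number of
  distinct matched classes (capped at tier 3+) and never exceeds 5; the
  per-condition maxima sum to 35. The published description of this score
  fixes only those constants (17 conditions, scores 1–5, total 0–35); the
  full class-to-condition table and tier rules bundled in `data/cds.csv`
  are this package's own encoding, constructed to satisfy exactly those
  constants, and are validated against them at load time. Analyses using
  the CDS on real data should replace this table with a formulary-specific
  one; the file format (CSV) is the interface.
* **Exclusions.** Diagnoses related to pregnancy, childbirth or abortion
  (ICD-9 630–679 and V27; ICD-10 O00–O99 and Z37; editable in
  `data/pregnancy_exclusions.csv`) are excluded from every measure, and
  hospital stays whose *most responsible* diagnosis falls in this set are
  excluded from the hospitalization outcomes. Secondary pregnancy codes do
  not exclude a stay.

## Cohorts

* **General:** all registered persons aged 20+ (completed years) at the
  reference date (the first day of the outcome year), alive on that date,
  with uninterrupted coverage over the comorbidity and outcome years.
* **Diabetes:** one hospital diagnosis (ICD-9 250, ICD-10 E10–E14) or two
  physician claims with such codes at most 730 days apart, within the
  six-year case-finding window; the 730-day rule slides over claim dates
  (any qualifying pair suffices; consecutive sorted dates are sufficient to
  check). Index date = earliest qualifying diagnosis.
* **Osteoporosis:** age 50+, one hospital or physician diagnosis (ICD-9
  733, ICD-10 M80/M81) or one dispensation of an osteoprotective drug
  (recognized by ingredient label when present, by a bundled AHFS-class
  fallback otherwise); persons with any Paget's disease diagnosis (ICD-9
  731.0, ICD-10 M88.0/.8/.9) are excluded.

Uninterrupted coverage is satisfied by coverage up to the death date for
persons dying inside the coverage period — otherwise no decedent could
contribute the death outcome. Adjacent coverage intervals (gap of zero
days) merge; any true gap disqualifies. Age is computed in completed years
at a single reference date so the 65+ restriction is deterministic.

## Estimation and inference

Logistic models are fitted by iteratively reweighted least squares
(statsmodels GLM, binomial family, logit link), convergence on deviance
change below 1e-8 within 100 iterations. Zero-variance columns are pruned
with a logged warning before fitting; remaining collinear columns are
removed greedily in first-come order. Complete separation (the model
classifies every person exactly) raises an error naming the offending
column. Outcomes with fewer than 10 events are still fitted but flagged
unstable.

The c-statistic is computed from midranks and equals the brute-force
concordant-pair count with ties worth one half. Its variance uses
placement values with midrank tie handling; CIs are normal-approximation,
truncated to [0, 1]. The paired test uses the placement-value covariance;
two identical score vectors have zero difference variance and return p = 1.
The "SD of the Brier score" is the sample standard deviation of the
per-person squared errors — the only per-person quantity available.
Hosmer–Lemeshow groups are formed by a stable sort on predicted risk with
boundary ties falling to the lower group; the statistic is
sum((O−E)²/(E(1−E/n_g))) with df = groups − 2. McNemar's test uses the
uncorrected chi-square with an exact binomial fallback below 25 discordant
pairs.

## The synthetic-claims generator

The generator emulates a linked provincial claims system: population
registry (demographics, coverage intervals, deaths), hospital discharge
abstracts (up to 25 coded diagnoses with a diagnosis-type field), physician
billing claims (single 3-digit ICD-9 rubric), and outpatient drug
dispensations (AHFS class, optional ingredient label). Defaults are
anchored to a general adult population of a western Canadian province:
1.3% one-year mortality as the intercept-only calibration anchor, ~17%
with at least one hospitalization, mean 3.9 distinct diagnoses and 1.8
distinct drug classes per person-year, 51.3% female, 58.2% urban, and the
observed Elixhauser condition prevalences (e.g. uncomplicated hypertension
16.7%, chronic pulmonary disease 8.4%, CHF 2.0%).

Per person, latent chronic-condition flags are drawn independently per
condition. Every flagged condition emits at least one mapped code in the
comorbidity year — through the physician channel (70%) where the condition
has a 3-digit ICD-9 rubric, through a hospital abstract otherwise — and
emits cohort-qualifying codes in the case-finding window with probability
0.9 (diabetes emits either one hospital code or a physician claim pair
within 730 days; osteoporosis uses the drug pathway half the time).
Incidental acute diagnoses (Poisson, rate 3.4/person-year, from a pool of
rubrics matching no bundled condition map) add diagnosis burden without
mortality signal. Dispensations combine condition-linked classes
(probability 0.7 given the condition) and background classes.

Death is Bernoulli on an inverse-logit linear predictor over age and the
latent condition flags with deliberately heterogeneous coefficients
(largest for metastatic cancer, weight loss, CHF, renal and liver disease)
that are *not* proportional to any summary weight; hospitalization counts
are Poisson on a log-linear predictor driven by total diagnosis burden
(conditions + incidental rubrics). One count process induces both the >=1
and >=2 outcomes. Decedents' events are truncated at the death date, and
coverage always extends past it, so decedents stay cohort-eligible. All
randomness flows from `numpy.random.default_rng([seed, stage])`; identical
configurations produce byte-identical bundles.

**What the generator does not emulate.** Conditions are independent across
persons and across conditions — real comorbidities cluster strongly.
There is no secular trend, no regional or socioeconomic gradient in
disease or outcomes, no miscoding, no episode structure linking transfers,
and the ICD-9/ICD-10 era switch is optional and off by default. Passing
tests therefore demonstrate that the *pipeline* recovers known generating
structure (rates, coefficients, measure rankings), not that any clinical
conclusion transfers to real claims data.

## Problem sizes used in the test suite

Printed-constant and oracle-equivalence checks run on constructed
fixtures and a 200-person bundle. Statistical-validity checks use 2,000
null replicates at n = 200 (DeLong type-I error and CI coverage) and one
n = 50,000 parameter-recovery fit. Ranking recovery uses 20 replicates at
n = 50,000: a replicate succeeds when the Elixhauser model attains the
highest full-model c for death and the diagnosis-count model the highest c
for both hospitalization outcomes; at least 90% must succeed. End-to-end
determinism compares output checksums of two n = 50,000 runs.

## Known limitations

* The bundled CDS table is an own encoding (see above), not a transcription
  of a published formulary mapping.
* The Charlson/Elixhauser pattern tables cover the standard coding
  algorithms at prefix granularity; site-specific ICD-10-CA dialect codes
  beyond those prefixes are out of scope.
* Income quintiles are generated directly; no census linkage or imputation
  of suppressed areas is modelled.
* Hospitalizations are counted by admission date; episode linkage of
  transfers is not attempted.
* The independence-across-conditions simplification understates the
  correlation between the five measures relative to real data.
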