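# Methods

This note records the models behind `pdprog`, the defaults that matter, and
the design choices made where more than one reasonable reading existed.

## The synthetic generator

The generator's purpose is validation: it produces longitudinal EHR/claims
data whose generating parameters are known exactly, so every downstream
stage (phenotyping, extraction, event detection, estimation) can be checked
by parameter recovery.  Each source archetype fixes a parameter set
(`pdprog.archetypes`); the values shared by progression analyses are the
population contrasts the pipeline must recover — ages at diagnosis
60.4/72.2 y, UPDRS 28.25 + 1.54 t vs 18.93 + 3.87 t, MMSE 28.7 − 0.11 t vs
25.8 − 0.28 t, RWD median time to H&Y ≥ 3 of 5.6 y, and a PD-therapy delay
2.3 y longer in RWD.

Per patient, the model is:

* **Age at diagnosis**: normal(mean, sd 10 y) truncated to [30, 95].  The
  sd reproduces realistic interquartile spans (~56–70 y research, ~66–81 y
  RWD); truncation shifts the RWD mean down by ≈ 0.3 y, which recovery
  tests allow for.
* **Follow-up**: exponential with the archetype mean (6.2 / 1.0 / 3.8 /
  3.1 y), floored at 0.25 y and capped at 15 y.  The exponential matches
  both the mean and roughly the quartile spread reported for EMR/claims
  follow-up; its memoryless tail supplies the late at-risk patients the KM
  estimator needs.
* **Encounters**: a homogeneous Poisson process (8/y for RWD archetypes —
  elderly patients in routine care — 1–2/y for research) over the follow-up
  window; research archetypes add structured annual study visits at which
  scores are always recorded.  Pre-diagnosis history exists with
  probability 0.9 (RWD) over a uniform 2.2–6 y span, so the 730-day
  quiescence rule removes a realistic ~10% of patients.  The claims
  archetype carries coverage intervals instead, with a 30–180-day gap
  inserted at probability 0.1 somewhere in the pre-diagnosis span (a gap
  inside the 730-day window fails the coverage quiescence variant).
* **Diagnosis-date resolution**: research sources record only the year of
  diagnosis.  Rather than truncating a day-resolution truth to January 1
  (which would bias every time-since-diagnosis by about +half a year, and
  would force an arbitrary mid-year back-conversion in the analysis), the
  generator draws research diagnosis dates *at* year granularity: recorded
  and true dates coincide and all trajectory clocks anchor there.
* **Score trajectories**: linear in years since diagnosis with Gaussian
  measurement noise (sd 4 UPDRS points, 1 MMSE point, 0 H&Y stages),
  clamped to the valid range.  UPDRS/MMSE values are recorded to two
  decimals rather than integer-rounded so that noiseless configurations
  reproduce the line exactly; MMSE's ceiling at 30 introduces a small
  (< 0.05-point) intercept shrinkage for the research archetype.  H&Y is
  quantized onto half stages by *flooring*, so a stage boundary counts only
  once truly crossed.  The H&Y trajectory is built from the event side:
  the patient's time T to stage 3 is Weibull (shape 1.5, a mildly rising
  hazard; scale solved from the configured median, since only medians are
  available to calibrate against), and the per-patient slope is
  (3 − intercept)/T, making the recorded-score crossing coincide exactly
  with T.  Covariate effects on trajectories (sex) default to zero and are
  exposed as config knobs.
* **Score recording**: a per-patient Bernoulli with the archetype marginal
  (0.912 research, 0.081 EMR, 0 for survey/claims), tilted by a
  specialist-care flag at odds ratio 1.5 (the marginal is preserved by
  solving the mixing equation).  This builds in the weak, barely
  learnable missingness signal that the audit is meant to find.
* **Events**: PD-therapy delay ~ normal(mean, sd 0.5 y) floored at 0.1 y
  (the small sd keeps follow-up truncation from distorting the mean delay
  contrast by more than ~0.03 y); levodopa start is the later of the
  therapy start and its own normal draw; cognitive decline and H&Y ≥ 3
  times are Weibull; falls/fractures and depression are exponential with
  the configured yearly hazards.  Each realized event is materialized as
  the evidence the detectors look for: monthly-then-quarterly fill
  sequences whose first fill links to a PD-coded encounter; an MCI code
  plus same-day cognitive-medication fill at a PD-coded encounter (70%) or
  a neurology referral (30%); an inpatient encounter with the event code
  as primary and admitting diagnosis.  Pre-diagnosis mimic and adverse
  codes are seeded at small probabilities to exercise the exclusion rules.

What the generator does **not** model: comorbidity correlation structure,
mortality and competing risks, costs, genetics, non-linear trajectories,
informative censoring, or informative score-missingness beyond the
specialist flag.  Recovery tests passing here therefore show that the
pipeline's rules and estimators are correct under the stated observation
process — not that real EHR data satisfy that process.

## Phenotyping

Boundary semantics follow the inclusive "at least" reading throughout: an
encounter exactly 730 days before the initial diagnosis passes quiescence,
and a confirmatory code exactly 30 days after passes confirmation; both are
pinned by tests.  Code matching is dot-insensitive and uppercase; the PD
set matches by prefix (so ICD-9 "332" captures "332.0") and the coverage
variant merges intervals with a configurable gap tolerance defaulting to 0
(no published gap rule exists to calibrate against).  Filters are
conjunctive, so the included set is order-invariant; attrition is
attributed in the documented order (no PD code → quiescence → confirmation
→ mimic exclusion).  Research archetypes state their diagnosis dates and
bypass the filters, which is controlled by the per-archetype `phenotyping`
field rather than by the cohort builder guessing.

## Extraction protocol

The "fewer than 9 of 10 matching outputs" rule is applied *per polarity
set*, plus the requirement that the two sets' modal values agree — the
reading consistent with reporting two separate per-set agreement counts
(e.g. 4/10 and 5/10) for a flagged note.  A pooled 18-of-20 variant is
available behind `mode="pooled"`.  Modal ties flag the note.  Raw outputs
are normalized before voting (decimal commas, roman stage numerals,
whitespace).  Flagged notes yield no value until `apply_corrections` merges
a human annotation; correcting an unflagged note is an error, because the
protocol only licenses overriding values the consensus itself rejected.
Under the deterministic reference backend and independent per-run
corruption at probability p, the flag rate has the closed form
1 − [(1−p)¹⁰ + 10p(1−p)⁹]², which the noisy-mock tests verify by
simulation at p = 0.05 and 0.2.

## Event definitions

The cognitive-decline proxy's and/or grouping is implemented as
(MCI code AND cognitive medication at a PD-coded encounter, dated at the
later of the two) OR (neurology referral); a laxer any-of-three reading
sits behind `any_of_three=True`.  "Linked to an encounter" means the fill
carries the encounter id of a same-day PD-coded encounter.  The therapy
rule counts days of supply within the 180-day window from the candidate
first fill (the windowed reading of "> 90 total days"); it is monotone in
rule laxity, which is property-tested.  The ϕ validation between the RWD
proxy and the MMSE threshold is computed at visit level (patient-level is
available); because the generator draws the proxy's event time and the
MMSE trajectory independently — coupling them would distort the calibrated
MMSE intercept — the synthetic ϕ is structural (near zero), and ϕ
correctness is instead verified against closed-form 2×2 tables.  Censoring
is the last encounter date for EMR-style data and the coverage end for
claims.

## Statistics

* KM medians that never reach S ≤ 0.5 are reported as "not reached" paired
  with the follow-up horizon, matching the convention of reporting
  "> horizon" for slow-progressing cohorts.
* Routing uses α = 0.05 for Shapiro–Wilk and (median-centred) Levene; the
  route is a pure function of the three sub-test p-values, which is
  property-tested.  No multiple-testing correction is applied; p-values
  are reported raw.
* The progression model is per-visit OLS — repeated measures within a
  patient violate independence, so a cluster-robust (by patient)
  covariance is available via `cluster_col`; point estimates are
  unaffected.  Continuous covariates and the sex indicator are centred at
  their sample means, making the reported intercept the expected score at
  diagnosis for an average cohort member (with zero-mean synthetic
  covariate effects this equals the generator intercept).  Rank-deficient
  designs raise an error naming the collinear columns; VIFs are attached
  and the fit is flagged at VIF ≥ 10.
* Slope comparison fits a pooled model with a source×time interaction and
  Wald-tests the interaction; the delta of separately fitted slopes is
  reported alongside (the two coincide for balanced designs without
  shared covariates, which is checked numerically).
* The missingness audit is an L2-regularized logistic regression on
  standardized features under stratified 5-fold cross-validation,
  reporting mean out-of-fold AUC.

## Problem sizes and reproducibility

Calibration-recovery runs use 2,000 patients per archetype for regression
targets and 5,000 for the KM and demographic targets — large enough that
2-standard-error recovery bands are a few percent of each target, small
enough to run in seconds.  The KM median for H&Y ≥ 3 in the EMR archetype
deserves a caveat: with 8.1% score recording, 5,000 patients yield only
~340 analyzable patients, so that estimate carries a standard error of
roughly half a year — the same sparsity penalty the corresponding
real-world analysis pays — and its recovery test therefore asserts
coverage by the KM median's 95% confidence interval rather than a point
tolerance.  Every stage derives its seed from one master seed via
`derive_seed` (SHA-256 of `"{seed}:{stage}"`, reduced below 2³¹), so runs
are reproducible end to end; generated datasets are byte-identical across
repeated runs of the same configuration.

## Known limitations

Linear trajectories cannot capture floor/ceiling-driven curvature in real
rating scales; the generator's observation process is stationary (no
disease-severity-driven encounter intensification); the extraction
reference backend parses templates and therefore exercises the protocol,
not language understanding; and the claims archetype models coverage gaps
but not plan switching or partial capture.  The pipeline's estimates on
real data would inherit whatever biases those simplifications hide.
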