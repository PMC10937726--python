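# pdprog

Comparing Parkinson's disease (PD) progression between *research* cohorts
(actively assessed longitudinal studies with structured visits) and
*real-world data* (RWD: hospital EMR and insurance-claims populations,
observed only through routine care) requires a chain of methods that each
introduce their own biases: incident-cohort phenotyping from diagnosis
codes, extraction of clinical rating scores from free-text notes, rule-based
detection of clinical events, and survival/regression modelling on
irregularly sampled visits.  `pdprog` implements that full chain as a
tested, reusable pipeline, together with a synthetic EHR/claims generator
whose source archetypes are calibrated so that every analysis step can be
validated by parameter recovery against known ground truth.

The package is aimed at methodologists working with EHR/claims phenotyping
and at trialists who want to understand how estimates of PD progression
shift between research and real-world populations.

## What it implements

**Synthetic source archetypes** (`pdprog.generator`).  Four archetypes —
`research`, `research_survey`, `rwd_emr`, `rwd_claims` — emulate the
statistical structure of the corresponding real source types: truncated
normal age at diagnosis (research mean 60.4 y vs RWD 72.2 y), exponential
follow-up, Poisson encounters plus annual study visits (research),
coverage intervals with gaps (claims), linear score trajectories with noise
(UPDRS total 28.25 + 1.54 t vs 18.93 + 3.87 t points; MMSE 28.7 − 0.11 t vs
25.8 − 0.28 t), Weibull times to H&Y ≥ 3 (RWD median 5.6 y; research beyond
follow-up), PD-therapy initiation 2.3 y later in RWD, and source-specific
score-recording sparsity (91.2% vs 8.1% of patients).

**Incident-cohort phenotyping** (`pdprog.cohort`).  First PD code
(ICD-9 332/332.0, ICD-10 G20) as the initial diagnosis; a 730-day
quiescence rule (an encounter ≥ 730 days prior, or continuous claims
coverage over the window); a confirmatory PD code ≥ 30 days later; and
exclusion of parkinsonism-mimic codes in the quiescence window — with full
attrition accounting.

**Score extraction with self-consistency voting** (`pdprog.extraction`).
A pluggable extractor interface run 10 times with positive and 10 times
with negative exemplars per note; notes with fewer than 9/10 matching
outputs in either set (or disagreeing modal values) are flagged and
resolved only by manual correction.  Stratified audit sampling, accuracy
scoring and correction merging are included.  A deterministic template
parser and a noisy mock stand in for the LLM, which is out of scope.

**Clinical-event detection** (`pdprog.events`).  Medication-initiation
episodes (first fill linked to a PD encounter, > 90 days of supply, 2+
fills with one 90–180 days after the first), the RWD cognitive-decline
proxy (MCI code + cognitive medication at a PD encounter, or neurology
referral), MMSE ≤ 25, H&Y ≥ 3 crossings, adverse events
(primary/admitting code at an inpatient or treated visit), and the ϕ
coefficient for agreement between binary event definitions.

**Statistics** (`pdprog.stats`).  Kaplan–Meier curves with Greenwood bands
and log-rank tests (via `lifelines`); Shapiro–Wilk/Levene-routed group
comparisons (pooled t / Welch t / Mann–Whitney U); per-year score
summaries; covariate-adjusted OLS progression fits with VIF and residual
diagnostics plus optional cluster-robust errors (via `statsmodels`); slope
comparison through a source×time interaction; and a cross-validated
missingness audit (via `scikit-learn`).

## Worked example

```python
from pdprog import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(archetypes=("research", "rwd_emr"),
                                n=1000, master_seed=7))
```

Printing the headline quantities of that bundle gives:

```
research: included 1000/1000, mean age at dx 60.2 y, scored 89.2%
  KM median to H&Y>=3: not reached (> 15.0) (n=892)
  UPDRS: 28.22 + 1.54/yr
  MMSE:  28.69 -0.11/yr
rwd_emr: included 841/1000, mean age at dx 72.2 y, scored 8.1%
  KM median to H&Y>=3: 7.9 (n=68)
  UPDRS: 18.69 + 3.89/yr
  MMSE:  25.86 -0.30/yr
therapy delay difference: 2.33 y
UPDRS slope difference: 2.36 (p=0.00e+00)
log-rank H&Y>=3 p=2.51e-07
```

Reading this: the research archetype keeps every patient (diagnosis dates
are stated), records scores for ~90% of them, and its H&Y ≥ 3 median lies
beyond follow-up; the EMR archetype loses ~16% of patients to the
quiescence/confirmation/mimic filters, has scores for only 8% — so its KM
median rests on 68 patients and is correspondingly noisy at this n — and
shows the faster motor (3.9 vs 1.5 UPDRS points/yr) and cognitive (0.30 vs
0.11 MMSE points/yr) decline it was calibrated to.  The same run is
available from the shell:

```bash
pdprog run-all --archetypes research,rwd_emr --n 1000 --seed 7 --out out/
```

which writes `results.json`, a cohort-characteristics table, and per-source
data, cohort, attrition and event files.

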