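"""Synthetic longitudinal EHR/claims generator.

Emulates the statistical structure of four source archetypes (research
cohort, survey cohort, hospital EMR, linked claims-EHR) for an incident
Parkinson's population:

* demographics: truncated-normal age at diagnosis, configured sex split;
* an observation process: per-patient exponential follow-up, homogeneous
  Poisson encounters (plus annual structured study visits for the research
  archetype), optional pre-diagnosis history and insurance coverage
  intervals with gaps;
* linear score trajectories (UPDRS total, MMSE, H&Y) with per-patient
  random intercepts and measurement noise, recorded in free-text notes for
  the configured fraction of patients;
* clinical event times (H&Y >= 3 crossing, cognitive decline, PD-therapy
  and levodopa initiation, falls/fractures, depression) realised as codes,
  prescription-fill sequences, referrals and inpatient encounters that the
  downstream rule-based detectors can recover.

The H&Y trajectory is constructed from the event side: the patient's time
to stage 3 is drawn from a Weibull distribution whose median is the
configured ``hy3_median_years``, and the per-patient H&Y slope is set so
the linear stage trajectory crosses 3.0 exactly at that time.
"""

from __future__ import annotations

import math
from datetime import date, timedelta

import numpy as np
from scipy.optimize import brentq

from .archetypes import ArchetypeConfig
from .records import (DAYS_PER_YEAR, ClinicalNote, EHRDataset, Encounter,
                      GroundTruth, PatientRecord, PatientTruth,
                      PrescriptionFill, Referral, add_years)
from .scales import SCALES, get_scale
from . import vocab

_DX_YEARS = (2008, 2016)        # calendar window for diagnosis dates
_MAX_FOLLOWUP = 15.0            # years
_INPATIENT_FRAC = 0.05
QUIESCENCE_YEARS = 2.0          # mimic/adverse lookback used at generation

_DISTRACTORS = [
    "Patient seen in clinic for routine follow-up.",
    "Blood pressure 128/76, heart rate 72.",
    "Patient reports sleeping 7 hours per night.",
    "Medication list reviewed, no changes today.",
    "Weight 81 kg, stable from last visit.",
    "Gait slow but steady with no assistive device.",
    "MMSE not assessed today.",
    "Labs from 3/12 reviewed and within normal limits.",
    "Follow up in 6 months or sooner if symptoms worsen.",
    "Discussed exercise program, 30 minutes daily.",
]


def trajectory_value(truth: PatientTruth, scale: str, t: float) -> float:
    """Evaluate a patient's true score trajectory at ``t`` years post-dx.

    Linear in time, clamped to the scale's valid range; H&Y additionally
    quantized onto half stages (snapping down, so stage 3 is reached exactly
    at the patient's true crossing time).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    sc = get_scale(scale)
    b0, b1 = truth.trajectories[scale]
    x = b0 + b1 * t
    return sc.quantize(x) if scale == "hy" else sc.clamp(x)


def render_note(scores: dict, distractor_seed: int = 0) -> str:
    """Render a synthetic clinical note.

    ``scores`` maps scale name to a value, to None (scale absent from the
    note), or to a list of two conflicting values (the ambiguous variant
    used to exercise consensus flagging).  Each present score appears in its
    scale's template phrase exactly once, interleaved with distractor
    sentences that contain other numbers.
    """
    rng = np.random.default_rng(distractor_seed if distractor_seed >= 0
                                else -distractor_seed)
    sentences = list(rng.choice(_DISTRACTORS, size=4, replace=False))
    score_sents = []
    for name, value in scores.items():
        sc = get_scale(name)
        if value is None:
            continue
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            if not sc.lo <= float(v) <= sc.hi:
                raise ValueError(f"{name} value {v} outside [{sc.lo}, {sc.hi}]")
            score_sents.append(sc.render(float(v)))
    # deterministic interleaving: scores at seeded positions
    for s in score_sents:
        sentences.insert(int(rng.integers(0, len(sentences) + 1)), s)
    return " ".join(sentences)


def _recording_probs(cfg: ArchetypeConfig) -> tuple[float, float]:
    """Per-patient score-recording probabilities (specialist, non-specialist)
    matching the configured marginal and specialist odds ratio."""
    p, s, orr = cfg.score_recording_prob, cfg.specialist_prob, cfg.specialist_score_or
    if p in (0.0, 1.0) or orr == 1.0 or s in (0.0, 1.0):
        return p, p

    def marginal(pn: float) -> float:
        ps = orr * pn / (1 - pn + orr * pn)
        return s * ps + (1 - s) * pn - p

    pn = brentq(marginal, 1e-9, min(1 - 1e-9, p / (1 - s)))
    ps = orr * pn / (1 - pn + orr * pn)
    return ps, pn


def _weibull_time(rng: np.random.Generator, median: float, shape: float) -> float:
    scale = median / math.log(2.0) ** (1.0 / shape)
    return float(scale * rng.weibull(shape))


def generate_dataset(config: ArchetypeConfig, n: int, seed: int
                     ) -> tuple[EHRDataset, GroundTruth]:
    """Generate ``n`` synthetic patients under one archetype.

    Deterministic for fixed ``(config, n, seed)``.  Returns the observable
    dataset and the hidden ground truth used for parameter-recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_spec, p_nonspec = _recording_probs(config)
    year_res = config.dx_resolution == "year"
    patients: list[PatientRecord] = []
    truths: dict[str, PatientTruth] = {}
    noise = dict(config.score_noise_sd)

    for i in range(n):
        pid = f"{config.name}-{i:06d}"
        sex = "M" if rng.random() < config.pct_male else "F"
        while True:
            age = rng.normal(config.age_at_dx_mean, config.age_at_dx_sd)
            if config.age_at_dx_sd == 0 or 30.0 <= age <= 95.0:
                break
        year = int(rng.integers(_DX_YEARS[0], _DX_YEARS[1] + 1))
        if year_res:
            dx = date(year, 1, 1)
        else:
            dx = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        birth = add_years(dx, -age)
        followup = min(_MAX_FOLLOWUP,
                       max(config.followup_min,
                           rng.exponential(config.followup_mean)))
        specialist = rng.random() < config.specialist_prob
        has_scores = rng.random() < (p_spec if specialist else p_nonspec)

        # trajectories
        re_b0 = rng.normal(0.0, config.intercept_re_sd) if config.intercept_re_sd else 0.0
        sex_eff = config.sex_effect if sex == "M" else 0.0
        t_hy3 = _weibull_time(rng, config.hy3_median_years, config.event_shape)
        traj = {
            "updrs_total": (config.updrs_intercept + re_b0 + sex_eff,
                            config.updrs_slope),
            "mmse": (config.mmse_intercept + re_b0 * 0.25 - sex_eff * 0.0,
                     config.mmse_slope),
            "hy": (config.hy_intercept, (3.0 - config.hy_intercept) / t_hy3),
        }

        # event times (years from diagnosis)
        therapy = max(0.1, rng.normal(config.therapy_delay_mean,
                                      config.therapy_delay_sd))
        levodopa = max(therapy, rng.normal(config.levodopa_delay_mean,
                                           config.therapy_delay_sd))
        t_cog = _weibull_time(rng, config.cogdecline_median_years,
                              config.event_shape)
        adverse: dict[str, float | None] = {}
        for ev, rate in config.adverse_event_rates.items():
            adverse[ev] = float(rng.exponential(1.0 / rate)) if rate > 0 else None

        truth = PatientTruth(
            patient_id=pid, age_at_dx=age, sex=sex, specialist=specialist,
            has_scores=has_scores, censor_years=followup, trajectories=traj,
            event_years={"hy3": t_hy3, "cognitive_decline": t_cog,
                         "therapy_start": therapy, "levodopa_start": levodopa,
                         **adverse})
        p = PatientRecord(patient_id=pid, sex=sex, birth_date=birth,
                          true_dx_date=dx)

        # ---- encounters -------------------------------------------------
        enc_times: list[float] = [0.0]
        n_enc = rng.poisson(config.encounter_rate * followup)
        enc_times += list(rng.uniform(0.0, followup, size=n_enc))
        if year_res:  # annual structured study visits
            enc_times += [float(k) for k in range(1, int(followup) + 1)]
        enc_times = sorted(set(round(t, 6) for t in enc_times))
        study_times = ({round(float(k), 6) for k in range(0, int(followup) + 1)}
                       if year_res else set())

        pre_span = 0.0
        if rng.random() < config.pre_dx_history_prob:
            pre_span = float(rng.uniform(2.2, 6.0))
            n_pre = rng.poisson(config.encounter_rate * pre_span)
            pre_times = [-pre_span] + list(rng.uniform(-pre_span, 0.0,
                                                       size=n_pre))
            pre_times = [t for t in pre_times if t < -1e-9]
            enc_times = sorted(set(round(t, 6) for t in pre_times)) + enc_times

        eid = 0
        enc_by_time: dict[float, Encounter] = {}
        for t in enc_times:
            eid += 1
            d = add_years(dx, t)
            setting = "inpatient" if rng.random() < _INPATIENT_FRAC else "outpatient"
            codes: list[tuple[str, str]] = []
            if t < 0:
                codes.append(vocab.BACKGROUND_CODES[
                    int(rng.integers(0, len(vocab.BACKGROUND_CODES)))])
            else:
                u = rng.random()
                pd_code = (("G20", "ICD10") if u < 0.8 else
                           ("332.0", "ICD9") if u < 0.95 else ("332", "ICD9"))
                if t == 0.0 or rng.random() < config.post_dx_pd_code_prob:
                    codes.append(pd_code)
                if rng.random() < 0.5:
                    codes.append(vocab.BACKGROUND_CODES[
                        int(rng.integers(0, len(vocab.BACKGROUND_CODES)))])
            e = Encounter(encounter_id=f"{pid}-e{eid:04d}", date=d,
                          setting=setting, diagnosis_codes=codes,
                          primary_code=codes[0][0] if codes else None,
                          is_study_visit=t in study_times and t >= 0)
            p.encounters.append(e)
            enc_by_time[t] = e

        def _post_dx_enc_at_or_after(t_ev: float) -> Encounter | None:
            cands = [t for t in enc_by_time if t >= t_ev - 1e-9]
            return enc_by_time[min(cands)] if cands else None

        def _ensure_pd_code(e: Encounter) -> None:
            if not vocab.PD_CODES.matches_encounter(e):
                e.diagnosis_codes.append(("G20", "ICD10"))
                if e.primary_code is None:
                    e.primary_code = "G20"

        # mimic codes in the quiescence window (drives exclusion attrition)
        pre_window = [t for t in enc_by_time
                      if -QUIESCENCE_YEARS <= t < 0]
        if pre_window and rng.random() < config.mimic_code_prob:
            cs = vocab.MIMIC_SETS[int(rng.integers(0, len(vocab.MIMIC_SETS)))]
            code = (cs.icd10[0], "ICD10") if cs.icd10 else (cs.icd9[0], "ICD9")
            enc_by_time[pre_window[int(rng.integers(0, len(pre_window)))]] \
                .diagnosis_codes.append(code)

        # prior adverse diagnoses in the quiescence window (drives the
        # adverse-event eligibility exclusion)
        for ev, cs in vocab.ADVERSE_EVENT_SETS.items():
            if pre_window and rng.random() < config.prior_adverse_prob:
                code = (cs.icd10[0], "ICD10")
                enc_by_time[pre_window[int(rng.integers(0, len(pre_window)))]] \
                    .diagnosis_codes.append(code)

        # ---- coverage (claims archetype) --------------------------------
        if config.phenotyping == "coverage":
            start = add_years(dx, -(pre_span if pre_span > 0 else 1.0))
            end = add_years(dx, followup)
            ivs = [(start, end)]
            if pre_span > 0 and rng.random() < config.coverage_gap_prob:
                gap_at = float(rng.uniform(-pre_span + 0.1, -0.1))
                gap_len = float(rng.uniform(30, 180)) / DAYS_PER_YEAR
                g0, g1 = add_years(dx, gap_at), add_years(dx, gap_at + gap_len)
                g1 = min(g1, end)
                ivs = [(start, g0), (g1, end)]
            p.coverage_intervals = [(s, e2) for s, e2 in ivs if s < e2]

        # ---- therapy fill sequences -------------------------------------
        def _fill_sequence(start_years: float, drug_class: str, drug: str) -> None:
            e = _post_dx_enc_at_or_after(start_years)
            start_t = start_years
            if e is None or (e.date - add_years(dx, start_years)).days > 14:
                eid_ = f"{pid}-rx{drug_class[:2]}"
                e = Encounter(encounter_id=eid_, date=add_years(dx, start_years),
                              setting="outpatient",
                              diagnosis_codes=[("G20", "ICD10")],
                              primary_code="G20")
                p.encounters.append(e)
            else:
                _ensure_pd_code(e)
                start_t = (e.date - dx).days / DAYS_PER_YEAR
            first = e.date
            t_days = 0
            while start_t + t_days / DAYS_PER_YEAR <= followup:
                supply = 30 if t_days < 180 else 90
                p.fills.append(PrescriptionFill(
                    date=first + timedelta(days=t_days), drug_code=drug,
                    drug_class=drug_class, days_supply=supply,
                    linked_encounter_id=e.encounter_id if t_days == 0 else None))
                t_days += supply
                if t_days > 10 * 365:
                    break

        if therapy <= followup:
            if levodopa <= therapy + 0.05:
                truth.event_years["levodopa_start"] = therapy
                _fill_sequence(therapy, "levodopa", vocab.LEVODOPA_DRUGS[0])
            else:
                _fill_sequence(therapy, "other_pd", vocab.OTHER_PD_DRUGS[
                    int(rng.integers(0, len(vocab.OTHER_PD_DRUGS)))])
                if levodopa <= followup:
                    _fill_sequence(levodopa, "levodopa", vocab.LEVODOPA_DRUGS[0])

        # ---- cognitive decline evidence ---------------------------------
        if t_cog <= followup:
            e = _post_dx_enc_at_or_after(t_cog)
            if e is not None:
                if rng.random() < 0.3:
                    p.referrals.append(Referral(date=e.date,
                                                code=vocab.COGNITIVE_REFERRAL_CODE))
                else:
                    _ensure_pd_code(e)
                    mci = ("G31.84", "ICD10") if rng.random() < 0.8 else ("331.83", "ICD9")
                    e.diagnosis_codes.append(mci)
                    p.fills.append(PrescriptionFill(
                        date=e.date,
                        drug_code=vocab.COGNITIVE_DRUGS[
                            int(rng.integers(0, len(vocab.COGNITIVE_DRUGS)))],
                        drug_class="cognitive", days_supply=30,
                        linked_encounter_id=e.encounter_id))

        # ---- adverse events ---------------------------------------------
        for ev, cs in vocab.ADVERSE_EVENT_SETS.items():
            t_ev = truth.event_years.get(ev)
            if t_ev is not None and t_ev <= followup:
                eid += 1
                code = cs.icd10[0]
                e = Encounter(encounter_id=f"{pid}-adv{eid:04d}",
                              date=add_years(dx, t_ev), setting="inpatient",
                              diagnosis_codes=[(code, "ICD10")],
                              primary_code=code, admitting_code=code)
                p.encounters.append(e)

        # ---- notes -------------------------------------------------------
        if has_scores:
            note_times = (sorted(study_times) if year_res
                          else [t for t in enc_by_time if t >= 0])
            for t in sorted(note_times):
                if t > followup:
                    continue
                scores: dict[str, float | None] = {}
                for name in SCALES:
                    if rng.random() >= config.score_in_note_prob:
                        scores[name] = None
                        continue
                    val = trajectory_value(truth, name, t)
                    sd = noise.get(name, 0.0)
                    if sd > 0:
                        val = get_scale(name).clamp(val + rng.normal(0.0, sd))
                    if name == "hy":
                        val = get_scale(name).quantize(val)
                    else:
                        val = round(float(val), 2)
                    scores[name] = val
                d = enc_by_time[t].date if t in enc_by_time else add_years(dx, t)
                nid = f"{pid}-n{len(p.notes):04d}"
                p.notes.append(ClinicalNote(
                    note_id=nid, patient_id=pid, date=d,
                    text=render_note(scores, int(rng.integers(0, 2**31 - 1))),
                    true_scores=scores))
        else:
            post = sorted(t for t in enc_by_time if t >= 0)
            for t in post[:2]:
                nid = f"{pid}-n{len(p.notes):04d}"
                scores = {name: None for name in SCALES}
                p.notes.append(ClinicalNote(
                    note_id=nid, patient_id=pid, date=enc_by_time[t].date,
                    text=render_note(scores, int(rng.integers(0, 2**31 - 1))),
                    true_scores=scores))

        p.sort()
        patients.append(p)
        truths[pid] = truth

    return (EHRDataset(source=config.name, patients=patients),
            GroundTruth(source=config.name, patients=truths))
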