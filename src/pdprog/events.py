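"""Rule-based detection of dated clinical events.

Implements the operational definitions used with claims/EMR data:

* **PD-therapy / levodopa initiation** — the first date of a fill sequence
  whose first fill is linked to a PD-coded encounter, whose fills total
  more than 90 days of supply within 180 days of the first fill, and which
  contains 2+ fills with at least one falling more than 90 but at most 180
  days after the first.  The three criteria filter evaluation-only
  prescribing and single 90-day fills.
* **Cognitive decline (RWD proxy)** — an MCI diagnosis code together with a
  fill for a cognitive-impairment medication at a PD-coded encounter, or a
  neurology referral for cognitive decline.
* **Cognitive decline (MMSE)** — first MMSE <= 25.
* **H&Y threshold** — first recorded stage >= 3.
* **Adverse events** — first post-diagnosis encounter where the event code
  is the primary or admitting code and the visit includes an inpatient stay
  or a treatment; patients with the event's codes during the pre-diagnosis
  quiescence window are ineligible.

Detected dates are converted to years since initial diagnosis, censored at
the last encounter (EMR) or coverage end (claims).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CodeSet, QUIESCENCE_DAYS
from .records import DAYS_PER_YEAR
from . import vocab

EVENT_TYPES = ("pd_therapy", "levodopa", "hy3", "cogdecline_rwd",
               "cogdecline_mmse", "falls_fractures", "depression")


@dataclass(frozen=True)
class TherapyRuleConfig:
    """Fill-sequence rule thresholds (days)."""

    min_total_days: int = 90        # exclusive: total supply must exceed this
    span_min_days: int = 90         # exclusive lower bound on the late fill
    span_max_days: int = 180        # inclusive upper bound
    require_pd_linked_first_fill: bool = True


@dataclass
class EventRecord:
    patient_id: str
    event_type: str
    time: float                     # years since initial diagnosis
    observed: bool
    eligible: bool = True

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event/censoring time must be >= 0")


def detect_therapy_initiation(fills: Sequence, encounters: Sequence,
                              pd_codes: CodeSet = vocab.PD_CODES,
                              drug_classes: frozenset | set = frozenset(
                                  vocab.PD_DRUG_CLASSES),
                              rule: TherapyRuleConfig = TherapyRuleConfig()
                              ) -> date | None:
    """Earliest qualifying first-fill date of a PD-medication sequence.

    Candidate first fills are scanned in date order; the first one whose
    sequence satisfies all three rule criteria is returned.
    """
    seq = [f for f in fills if f.drug_class in drug_classes]
    if [f.date for f in seq] != sorted(f.date for f in seq):
        raise ValueError("fills must be date-sorted")
    enc_by_id = {e.encounter_id: e for e in encounters}
    for i, first in enumerate(seq):
        if rule.require_pd_linked_first_fill:
            enc = enc_by_id.get(first.linked_encounter_id)
            if enc is None or not pd_codes.matches_encounter(enc):
                continue
        window_end = first.date + timedelta(days=rule.span_max_days)
        window = [f for f in seq[i:] if f.date <= window_end]
        total_supply = sum(f.days_supply for f in window)
        if total_supply <= rule.min_total_days:
            continue
        if len(window) < 2:
            continue
        offsets = [(f.date - first.date).days for f in window]
        if not any(rule.span_min_days < off <= rule.span_max_days
                   for off in offsets):
            continue
        return first.date
    return None


def detect_cognitive_decline_rwd(patient,
                                 initial_dx: date,
                                 mci_codes: CodeSet = vocab.MCI_CODES,
                                 pd_codes: CodeSet = vocab.PD_CODES,
                                 referral_code: str = vocab.COGNITIVE_REFERRAL_CODE,
                                 any_of_three: bool = False) -> date | None:
    """RWD cognitive-decline proxy date.

    Default grouping: (first MCI code AND first cognitive-medication fill at
    a PD-coded encounter — the event dates at the later of the two) OR a
    qualifying referral.  ``any_of_three`` switches to the laxer reading
    where any single criterion qualifies on its own date.
    """
    mci_dates = [e.date for e in patient.encounters
                 if e.date >= initial_dx and mci_codes.matches_encounter(e)]
    enc_by_id = {e.encounter_id: e for e in patient.encounters}
    cogfill_dates = []
    for f in patient.fills:
        if f.drug_class != "cognitive" or f.date < initial_dx:
            continue
        enc = enc_by_id.get(f.linked_encounter_id)
        if enc is not None and pd_codes.matches_encounter(enc):
            cogfill_dates.append(f.date)
    referral_dates = [r.date for r in patient.referrals
                      if r.date >= initial_dx and r.code == referral_code]
    candidates: list[date] = []
    if any_of_three:
        candidates = mci_dates + cogfill_dates + referral_dates
    else:
        if mci_dates and cogfill_dates:
            candidates.append(max(min(mci_dates), min(cogfill_dates)))
        candidates.extend(referral_dates)
    return min(candidates) if candidates else None


def detect_cognitive_decline_mmse(scores: Sequence[tuple[date, float]],
                                  cutoff: float = 25.0) -> date | None:
    """First date with an MMSE score at or below the cutoff (<= 25)."""
    qualifying = [d for d, v in scores if v <= cutoff]
    return min(qualifying) if qualifying else None


def detect_score_threshold_event(scores: Sequence[tuple[date, float]],
                                 threshold: float = 3.0) -> date | None:
    """First date with a recorded score at or above the threshold."""
    qualifying = [d for d, v in scores if v >= threshold]
    return min(qualifying) if qualifying else None


def detect_adverse_event(patient, event_codes: CodeSet, initial_dx: date,
                         quiescence_days: int = QUIESCENCE_DAYS
                         ) -> tuple[date | None, bool]:
    """Adverse-event date and eligibility flag.

    Ineligible (flag False) when any event code appears in the quiescence
    window before diagnosis.  Otherwise the event date is the first
    post-diagnosis encounter where an event code is the primary or admitting
    code and the visit is an inpatient stay or records a treatment.
    """
    lo = initial_dx - timedelta(days=quiescence_days)
    for e in patient.encounters:
        if lo <= e.date <= initial_dx and event_codes.matches_encounter(e):
            return None, False
    fill_dates = {f.date for f in patient.fills}
    for e in patient.encounters:
        if e.date <= initial_dx:
            continue
        prim_adm = [c for c in (e.primary_code, e.admitting_code) if c]
        if not any(event_codes.matches(c, v)
                   for c, v in e.diagnosis_codes
                   if c in prim_adm):
            continue
        treated = bool(e.procedure_codes) or e.date in fill_dates
        if e.setting == "inpatient" or treated:
            return e.date, True
    return None, True


def phi_coefficient(a: Sequence[int], b: Sequence[int]) -> float:
    """Phi coefficient (Pearson correlation of two binary variables).

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0), from the 2x2
    table of the two indicators.  Undefined (raises) for constant vectors.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length binary vectors of length >= 2")
    if not (set(np.unique(a)) <= {0, 1} and set(np.unique(b)) <= {0, 1}):
        raise ValueError("vectors must be binary (0/1)")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("phi undefined for constant vectors")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    num = n11 * n00 - n10 * n01
    den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    return num / np.sqrt(den)


# ---------------------------------------------------------------------------
# patient-level assembly

def _censor_date(patient, claims: bool) -> date:
    if claims and patient.coverage_intervals:
        return max(e for _, e in patient.coverage_intervals)
    return max((e.date for e in patient.encounters),
               default=patient.true_dx_date)


def note_scores(patient, scale: str, extracted: Mapping[str, float | None]
                ) -> list[tuple[date, float]]:
    """Dated extracted scores of one scale for one patient."""
    out = []
    for n in patient.notes:
        v = extracted.get(n.note_id)
        if v is not None:
            out.append((n.date, v))
    return sorted(out)


def detect_events(dataset, cohort, extracted: Mapping[str, Mapping[str, float | None]]
                  | None = None,
                  events: Sequence[str] = EVENT_TYPES,
                  rule: TherapyRuleConfig = TherapyRuleConfig(),
                  mmse_cutoff: float = 25.0, hy_threshold: float = 3.0
                  ) -> pd.DataFrame:
    """Per-patient time-to-event table for the included cohort.

    ``extracted`` maps scale -> note_id -> value (output of the extraction
    stage); score-based events are skipped for patients with no extracted
    scores of that scale (no observation process to detect them).  Returns
    a frame with columns patient_id, event_type, time (years), observed,
    eligible.
    """
    extracted = extracted or {}
    claims = any(p.coverage_intervals for p in dataset.patients)
    dx_by_id = dict(zip(cohort.rows["patient_id"], cohort.rows["initial_dx_date"]))
    included = set(cohort.included_ids)
    rows: list[EventRecord] = []
    for p in dataset.patients:
        if p.patient_id not in included:
            continue
        dx = dx_by_id[p.patient_id]
        censor = _censor_date(p, claims)
        horizon = max(0.0, (censor - dx).days / DAYS_PER_YEAR)

        def emit(ev: str, d: date | None, eligible: bool = True) -> None:
            if not eligible:
                return
            if d is not None and d >= dx:
                rows.append(EventRecord(p.patient_id, ev,
                                        (d - dx).days / DAYS_PER_YEAR, True))
            else:
                rows.append(EventRecord(p.patient_id, ev, horizon, False))

        if "pd_therapy" in events:
            emit("pd_therapy", detect_therapy_initiation(
                p.fills, p.encounters, rule=rule))
        if "levodopa" in events:
            emit("levodopa", detect_therapy_initiation(
                p.fills, p.encounters, drug_classes={"levodopa"}, rule=rule))
        if "cogdecline_rwd" in events:
            emit("cogdecline_rwd", detect_cognitive_decline_rwd(p, dx))
        if "hy3" in events and extracted.get("hy"):
            scores = note_scores(p, "hy", extracted["hy"])
            if scores:
                emit("hy3", detect_score_threshold_event(scores, hy_threshold))
        if "cogdecline_mmse" in events and extracted.get("mmse"):
            scores = note_scores(p, "mmse", extracted["mmse"])
            if scores:
                emit("cogdecline_mmse",
                     detect_cognitive_decline_mmse(scores, mmse_cutoff))
        for ev in ("falls_fractures", "depression"):
            if ev in events:
                d, eligible = detect_adverse_event(
                    p, vocab.ADVERSE_EVENT_SETS[ev], dx)
                emit(ev, d, eligible)
    return pd.DataFrame([{"patient_id": r.patient_id, "event_type": r.event_type,
                          "time": r.time, "observed": r.observed,
                          "eligible": r.eligible} for r in rows])
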