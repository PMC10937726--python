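"""Incident-cohort phenotyping.

Real-world sources do not state the date of first diagnosis; it must be
derived.  The rules implemented here phenotype an *incident* (de novo)
Parkinson's cohort from longitudinal codes:

1. initial diagnosis = earliest encounter carrying a PD code;
2. a quiescence period: 730 days of prior engagement — either at least one
   encounter >= 730 days before the initial diagnosis (EMR reading) or
   continuous insurance coverage over the whole 730-day window (claims
   reading);
3. a confirmatory PD code at least 30 days after the initial one (filters
   referral / rule-out codes);
4. exclusion of patients carrying codes for conditions that mimic
   parkinsonism during the quiescence window.

Boundary semantics follow the inclusive "at least" reading: an encounter
exactly 730 days prior passes quiescence, a confirmatory code exactly 30
days after passes confirmation.  Research-style sources state the diagnosis
date directly and bypass rules 1-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

QUIESCENCE_DAYS = 730
CONFIRMATION_DAYS = 30


def normalize_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """A named diagnosis-code set over ICD-9 and ICD-10 vocabularies."""

    name: str
    icd9: Sequence[str] = ()
    icd10: Sequence[str] = ()
    match_mode: str = "exact"    # "exact" | "prefix"

    def __post_init__(self) -> None:
        if not (list(self.icd9) + list(self.icd10)):
            raise ValueError(f"code set {self.name!r} is empty")
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError("match_mode must be 'exact' or 'prefix'")
        object.__setattr__(self, "icd9", tuple(normalize_code(c) for c in self.icd9))
        object.__setattr__(self, "icd10", tuple(normalize_code(c) for c in self.icd10))

    def matches(self, code: str, vocabulary: str) -> bool:
        code = normalize_code(code)
        pool = self.icd9 if vocabulary.upper() == "ICD9" else self.icd10
        if self.match_mode == "exact":
            return code in pool
        return any(code.startswith(c) for c in pool)

    def matches_encounter(self, encounter) -> bool:
        return any(self.matches(c, v) for c, v in encounter.diagnosis_codes)


def find_initial_diagnosis(encounters: Sequence, pd_codes: CodeSet) -> date | None:
    """Earliest encounter date carrying any PD code; None if absent."""
    dates = [e.date for e in encounters]
    if dates != sorted(dates):
        raise ValueError("encounters must be date-sorted")
    for e in encounters:
        if pd_codes.matches_encounter(e):
            return e.date
    return None


def merge_intervals(intervals: Iterable[tuple[date, date]],
                    gap_tolerance_days: int = 0) -> list[tuple[date, date]]:
    """Merge coverage intervals, bridging gaps of at most the tolerance."""
    ivs = sorted(intervals)
    merged: list[list[date]] = []
    for s, e in ivs:
        if merged and (s - merged[-1][1]).days <= gap_tolerance_days:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def passes_quiescence(patient, initial_dx: date, mode: str,
                      window: int = QUIESCENCE_DAYS,
                      gap_tolerance_days: int = 0) -> bool:
    """730-day quiescence rule, encounter- or coverage-based.

    ``encounter`` mode: some encounter at least ``window`` days before the
    initial diagnosis.  ``coverage`` mode: merged coverage intervals fully
    contain ``[initial_dx - window, initial_dx]``.
    """
    if mode == "encounter":
        cut = initial_dx - timedelta(days=window)
        return any(e.date <= cut for e in patient.encounters)
    if mode == "coverage":
        lo = initial_dx - timedelta(days=window)
        merged = merge_intervals(patient.coverage_intervals, gap_tolerance_days)
        return any(s <= lo and e >= initial_dx for s, e in merged)
    raise ValueError(f"unknown quiescence mode {mode!r}")


def has_confirmatory_diagnosis(encounters: Sequence, pd_codes: CodeSet,
                               initial_dx: date,
                               min_days: int = CONFIRMATION_DAYS) -> bool:
    """A second PD code at least ``min_days`` after the initial diagnosis."""
    cut = initial_dx + timedelta(days=min_days)
    return any(e.date >= cut and pd_codes.matches_encounter(e)
               for e in encounters)


def apply_exclusions(patient, exclusion_sets: Sequence[CodeSet],
                     initial_dx: date,
                     window: int = QUIESCENCE_DAYS) -> str | None:
    """First matching mimic-exclusion set (config order) in the quiescence
    window ``[initial_dx - window, initial_dx]``; None when clean."""
    lo = initial_dx - timedelta(days=window)
    in_window = [e for e in patient.encounters if lo <= e.date <= initial_dx]
    for cs in exclusion_sets:
        if any(cs.matches_encounter(e) for e in in_window):
            return cs.name
    return None


@dataclass
class CohortConfig:
    pd_codes: CodeSet = None  # type: ignore[assignment]
    exclusion_sets: Sequence[CodeSet] = ()
    mode: str = "encounter"             # encounter | coverage | stated
    quiescence_days: int = QUIESCENCE_DAYS
    confirmation_days: int = CONFIRMATION_DAYS
    coverage_gap_tolerance_days: int = 0

    def __post_init__(self) -> None:
        if self.pd_codes is None:
            from . import vocab
            self.pd_codes = vocab.PD_CODES
            if not self.exclusion_sets:
                self.exclusion_sets = tuple(vocab.MIMIC_SETS)
        if self.mode not in ("encounter", "coverage", "stated"):
            raise ValueError("mode must be encounter|coverage|stated")


@dataclass
class CohortTable:
    """Per-patient phenotyping outcome plus stage-by-stage attrition."""

    rows: pd.DataFrame                  # patient_id, initial_dx_date, flags
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def included_ids(self) -> list[str]:
        return list(self.rows.loc[self.rows["included"], "patient_id"])

    def initial_dx(self, patient_id: str):
        row = self.rows.loc[self.rows["patient_id"] == patient_id]
        return None if row.empty else row["initial_dx_date"].iloc[0]


def build_cohort(dataset, config: CohortConfig | None = None) -> CohortTable:
    """Phenotype every patient; returns per-patient outcomes and attrition.

    Filters are applied in a fixed order (initial diagnosis -> quiescence ->
    confirmation -> mimic exclusions); the final included set is
    order-invariant because the filters are conjunctive, but the attrition
    bookkeeping attributes each removal to the first failing stage.
    ``stated`` mode (research sources) takes the recorded diagnosis date and
    applies no filters.
    """
    if not len(dataset.patients):
        raise ValueError("empty dataset")
    config = config or CohortConfig()
    rows = []
    attrition = {"input": len(dataset.patients), "no_pd_diagnosis": 0,
                 "failed_quiescence": 0, "no_confirmation": 0, "excluded_mimic": 0,
                 "included": 0}
    for p in dataset.patients:
        rec = {"patient_id": p.patient_id, "initial_dx_date": None,
               "quiescence_pass": False, "confirmation_pass": False,
               "excluded_reason": None, "included": False}
        if config.mode == "stated":
            rec.update(initial_dx_date=p.true_dx_date, quiescence_pass=True,
                       confirmation_pass=True, included=True)
            attrition["included"] += 1
            rows.append(rec)
            continue
        dx = find_initial_diagnosis(p.encounters, config.pd_codes)
        if dx is None:
            attrition["no_pd_diagnosis"] += 1
            rows.append(rec)
            continue
        rec["initial_dx_date"] = dx
        rec["quiescence_pass"] = passes_quiescence(
            p, dx, config.mode, config.quiescence_days,
            config.coverage_gap_tolerance_days)
        if not rec["quiescence_pass"]:
            attrition["failed_quiescence"] += 1
            rows.append(rec)
            continue
        rec["confirmation_pass"] = has_confirmatory_diagnosis(
            p.encounters, config.pd_codes, dx, config.confirmation_days)
        if not rec["confirmation_pass"]:
            attrition["no_confirmation"] += 1
            rows.append(rec)
            continue
        reason = apply_exclusions(p, config.exclusion_sets, dx,
                                  config.quiescence_days)
        rec["excluded_reason"] = reason
        if reason is not None:
            attrition["excluded_mimic"] += 1
            rows.append(rec)
            continue
        rec["included"] = True
        attrition["included"] += 1
        rows.append(rec)
    table = pd.DataFrame(rows)
    removed = sum(v for k, v in attrition.items() if k not in ("input", "included"))
    assert removed + attrition["included"] == attrition["input"]
    return CohortTable(rows=table, attrition=attrition)
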