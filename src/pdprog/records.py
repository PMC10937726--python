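"""In-memory containers for synthetic longitudinal EHR/claims data.

A dataset is a collection of :class:`PatientRecord` objects plus the
generator's hidden :class:`GroundTruth`.  On disk the same content is a set
of plain-text tables (``patients.csv``, ``encounters.csv``, ``diagnoses.csv``,
``fills.csv``, ``referrals.csv``, ``coverage.csv``, ``ground_truth.csv``) and
a ``notes.jsonl`` file, all ISO-8601 dated and UTF-8 encoded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DAYS_PER_YEAR = 365.25


def years_between(start: date, end: date) -> float:
    return (end - start).days / DAYS_PER_YEAR


def add_years(d: date, years: float) -> date:
    return d + timedelta(days=round(years * DAYS_PER_YEAR))


@dataclass
class Encounter:
    encounter_id: str
    date: date
    setting: str                      # "outpatient" | "inpatient"
    diagnosis_codes: list[tuple[str, str]] = field(default_factory=list)
    # each code is (code, vocabulary) with vocabulary in {"ICD9", "ICD10"}
    primary_code: str | None = None
    admitting_code: str | None = None
    procedure_codes: list[str] = field(default_factory=list)
    is_study_visit: bool = False

    def __post_init__(self) -> None:
        codes = {c for c, _ in self.diagnosis_codes}
        if self.primary_code is not None and self.primary_code not in codes:
            raise ValueError("primary_code must be among diagnosis_codes")


@dataclass
class PrescriptionFill:
    date: date
    drug_code: str
    drug_class: str                   # levodopa | other_pd | cognitive | other
    days_supply: int
    linked_encounter_id: str | None = None

    def __post_init__(self) -> None:
        if self.days_supply <= 0:
            raise ValueError("days_supply must be > 0")


@dataclass
class Referral:
    date: date
    code: str                         # synthetic referral vocabulary


@dataclass
class ClinicalNote:
    note_id: str
    patient_id: str
    date: date
    text: str
    true_scores: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str                          # "M" | "F"
    birth_date: date
    true_dx_date: date
    coverage_intervals: list[tuple[date, date]] = field(default_factory=list)
    encounters: list[Encounter] = field(default_factory=list)
    fills: list[PrescriptionFill] = field(default_factory=list)
    referrals: list[Referral] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)

    def sort(self) -> None:
        self.encounters.sort(key=lambda e: (e.date, e.encounter_id))
        self.fills.sort(key=lambda f: f.date)
        self.referrals.sort(key=lambda r: r.date)
        self.notes.sort(key=lambda n: (n.date, n.note_id))
        self.coverage_intervals.sort()


@dataclass
class PatientTruth:
    """Generator-internal truth for one patient; hidden from the analysis."""

    patient_id: str
    age_at_dx: float
    sex: str
    specialist: bool
    has_scores: bool
    censor_years: float               # follow-up from diagnosis
    trajectories: dict[str, tuple[float, float]]   # scale -> (intercept, slope)
    event_years: dict[str, float | None]
    # keys: hy3, cognitive_decline, therapy_start, levodopa_start,
    #       falls_fractures, depression  (None = never)


@dataclass
class EHRDataset:
    source: str
    patients: list[PatientRecord]

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterable[PatientRecord]:
        return iter(self.patients)


@dataclass
class GroundTruth:
    source: str
    patients: dict[str, PatientTruth]

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.patients.values():
            row = {
                "patient_id": t.patient_id,
                "age_at_dx": t.age_at_dx,
                "sex": t.sex,
                "specialist": t.specialist,
                "has_scores": t.has_scores,
                "censor_years": t.censor_years,
            }
            for scale, (b0, b1) in t.trajectories.items():
                row[f"{scale}_intercept"] = b0
                row[f"{scale}_slope"] = b1
            for ev, yrs in t.event_years.items():
                row[f"t_{ev}"] = yrs
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk round-trip

def write_dataset(ds: EHRDataset, truth: GroundTruth | None, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pats, encs, dxs, fills, refs, cov = [], [], [], [], [], []
    notes_path = out / "notes.jsonl"
    with open(notes_path, "w", encoding="utf-8") as nf:
        for p in ds.patients:
            pats.append({"patient_id": p.patient_id, "sex": p.sex,
                         "birth_date": p.birth_date.isoformat(),
                         "dx_date": p.true_dx_date.isoformat()})
            for e in p.encounters:
                encs.append({"patient_id": p.patient_id,
                             "encounter_id": e.encounter_id,
                             "date": e.date.isoformat(), "setting": e.setting,
                             "primary_code": e.primary_code or "",
                             "admitting_code": e.admitting_code or "",
                             "procedure_codes": ";".join(e.procedure_codes),
                             "is_study_visit": e.is_study_visit})
                for code, vocab in e.diagnosis_codes:
                    dxs.append({"patient_id": p.patient_id,
                                "encounter_id": e.encounter_id,
                                "date": e.date.isoformat(),
                                "code": code, "vocabulary": vocab})
            for f in p.fills:
                fills.append({"patient_id": p.patient_id,
                              "date": f.date.isoformat(),
                              "drug_code": f.drug_code,
                              "drug_class": f.drug_class,
                              "days_supply": f.days_supply,
                              "linked_encounter_id": f.linked_encounter_id or ""})
            for r in p.referrals:
                refs.append({"patient_id": p.patient_id,
                             "date": r.date.isoformat(), "code": r.code})
            for s, e2 in p.coverage_intervals:
                cov.append({"patient_id": p.patient_id,
                            "start": s.isoformat(), "end": e2.isoformat()})
            for n in p.notes:
                nf.write(json.dumps({"note_id": n.note_id,
                                     "patient_id": n.patient_id,
                                     "date": n.date.isoformat(),
                                     "text": n.text}) + "\n")
    pd.DataFrame(pats).to_csv(out / "patients.csv", index=False)
    pd.DataFrame(encs).to_csv(out / "encounters.csv", index=False)
    pd.DataFrame(dxs).to_csv(out / "diagnoses.csv", index=False)
    pd.DataFrame(fills).to_csv(out / "fills.csv", index=False)
    pd.DataFrame(refs).to_csv(out / "referrals.csv", index=False)
    pd.DataFrame(cov).to_csv(out / "coverage.csv", index=False)
    if truth is not None:
        truth.frame().to_csv(out / "ground_truth.csv", index=False)


def read_dataset(in_dir, source: str = "unknown") -> EHRDataset:
    src = Path(in_dir)

    def _load(name: str) -> pd.DataFrame:
        f = src / name
        if not f.exists():
            return pd.DataFrame()
        try:
            return pd.read_csv(f, dtype=str).fillna("")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    pats = _load("patients.csv")
    encs = _load("encounters.csv")
    dxs = _load("diagnoses.csv")
    fills = _load("fills.csv")
    refs = _load("referrals.csv")
    cov = _load("coverage.csv")

    dx_by_enc: dict[str, list[tuple[str, str]]] = {}
    if not dxs.empty:
        for r in dxs.itertuples(index=False):
            dx_by_enc.setdefault(r.encounter_id, []).append((r.code, r.vocabulary))

    patients: dict[str, PatientRecord] = {}
    for r in pats.itertuples(index=False):
        patients[r.patient_id] = PatientRecord(
            patient_id=r.patient_id, sex=r.sex,
            birth_date=date.fromisoformat(r.birth_date),
            true_dx_date=date.fromisoformat(r.dx_date))
    if not encs.empty:
        for r in encs.itertuples(index=False):
            patients[r.patient_id].encounters.append(Encounter(
                encounter_id=r.encounter_id, date=date.fromisoformat(r.date),
                setting=r.setting,
                diagnosis_codes=dx_by_enc.get(r.encounter_id, []),
                primary_code=r.primary_code or None,
                admitting_code=r.admitting_code or None,
                procedure_codes=[c for c in r.procedure_codes.split(";") if c],
                is_study_visit=str(r.is_study_visit) == "True"))
    if not fills.empty:
        for r in fills.itertuples(index=False):
            patients[r.patient_id].fills.append(PrescriptionFill(
                date=date.fromisoformat(r.date), drug_code=r.drug_code,
                drug_class=r.drug_class, days_supply=int(r.days_supply),
                linked_encounter_id=r.linked_encounter_id or None))
    if not refs.empty:
        for r in refs.itertuples(index=False):
            patients[r.patient_id].referrals.append(
                Referral(date=date.fromisoformat(r.date), code=r.code))
    if not cov.empty:
        for r in cov.itertuples(index=False):
            patients[r.patient_id].coverage_intervals.append(
                (date.fromisoformat(r.start), date.fromisoformat(r.end)))
    notes_path = src / "notes.jsonl"
    if notes_path.exists():
        with open(notes_path, encoding="utf-8") as nf:
            for line in nf:
                d = json.loads(line)
                patients[d["patient_id"]].notes.append(ClinicalNote(
                    note_id=d["note_id"], patient_id=d["patient_id"],
                    date=date.fromisoformat(d["date"]), text=d["text"]))
    ds = EHRDataset(source=source, patients=list(patients.values()))
    for p in ds.patients:
        p.sort()
    return ds
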