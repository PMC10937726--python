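"""Shared fixtures: hand-constructed patients and small generated datasets."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from pdprog import CohortConfig, build_cohort, generate_dataset, make_archetype_config
from pdprog.records import Encounter, PatientRecord, PrescriptionFill

DX = date(2012, 6, 15)


def enc(days_from_dx: int, codes=(), setting="outpatient", primary=None,
        admitting=None, procedures=(), eid=None) -> Encounter:
    """Encounter helper: codes as (code, vocab) pairs, offset in days."""
    codes = list(codes)
    return Encounter(
        encounter_id=eid or f"e{days_from_dx}",
        date=DX + timedelta(days=days_from_dx),
        setting=setting, diagnosis_codes=codes,
        primary_code=primary, admitting_code=admitting,
        procedure_codes=list(procedures))


def fill(days_from_dx: int, supply: int, drug_class="other_pd",
         linked=None) -> PrescriptionFill:
    return PrescriptionFill(date=DX + timedelta(days=days_from_dx),
                            drug_code="RX", drug_class=drug_class,
                            days_supply=supply, linked_encounter_id=linked)


def patient(encounters=(), fills=(), referrals=(), coverage=(),
            pid="p1", sex="F") -> PatientRecord:
    p = PatientRecord(patient_id=pid, sex=sex, birth_date=date(1945, 1, 1),
                      true_dx_date=DX, coverage_intervals=list(coverage),
                      encounters=list(encounters), fills=list(fills),
                      referrals=list(referrals))
    p.sort()
    return p


@pytest.fixture(scope="session")
def rwd_small():
    """A small real-world-archetype dataset with ground truth."""
    cfg = make_archetype_config("rwd_emr", {"score_recording_prob": 0.5})
    return generate_dataset(cfg, 200, seed=42)


@pytest.fixture(scope="session")
def rwd_small_cohort(rwd_small):
    ds, _ = rwd_small
    return build_cohort(ds, CohortConfig(mode="encounter"))


@pytest.fixture(scope="session")
def research_small():
    cfg = make_archetype_config("research")
    return generate_dataset(cfg, 200, seed=42)
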