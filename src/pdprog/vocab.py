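"""Synthetic code vocabularies.

Small stand-in diagnosis, drug and referral vocabularies used by the
generator and the phenotyping/event rules.  PD and mild-cognitive-impairment
codes are the real ICD codes the rules are defined on; every other set is a
synthetic reduction of the much larger operational code lists used with real
claims/EMR data.
"""

from __future__ import annotations

from .cohort import CodeSet

# Parkinson's disease diagnosis codes (ICD9: 332, 332.0; ICD10: G20).
PD_CODES = CodeSet(name="parkinson_disease",
                   icd9=["332", "332.0"], icd10=["G20"],
                   match_mode="prefix")

# Mild cognitive impairment (ICD9: 331.83, ICD10: G31.84).
MCI_CODES = CodeSet(name="mild_cognitive_impairment",
                    icd9=["331.83"], icd10=["G31.84"],
                    match_mode="exact")

# Synthetic PD-mimic exclusion sets (conditions producing clinical
# parkinsonism: dementias, psychotic disorders, atypical parkinsonisms,
# metabolic neurogenic anomalies).
MIMIC_SETS = [
    CodeSet(name="mimic_dementia", icd9=["331.0"], icd10=["G30.9", "G31.84"],
            match_mode="exact"),
    CodeSet(name="mimic_psychosis", icd9=["295.9"], icd10=["F20.9"],
            match_mode="exact"),
    CodeSet(name="mimic_atypical_parkinsonism", icd9=["333.0"],
            icd10=["G23.1", "G90.3"], match_mode="exact"),
    CodeSet(name="mimic_metabolic", icd9=["275.1"], icd10=["E83.01"],
            match_mode="exact"),
]

# Adverse clinical events (synthetic reductions).
FALLS_FRACTURES_CODES = CodeSet(name="falls_fractures",
                                icd9=["E888", "820.8"],
                                icd10=["W19", "S72.0"],
                                match_mode="prefix")
DEPRESSION_CODES = CodeSet(name="depression",
                           icd9=["296.2", "311"],
                           icd10=["F32.9", "F33.9"],
                           match_mode="exact")
ADVERSE_EVENT_SETS = {"falls_fractures": FALLS_FRACTURES_CODES,
                      "depression": DEPRESSION_CODES}

# Drug codes (synthetic identifiers, field `drug_class` is authoritative).
LEVODOPA_DRUGS = ["LEVO-CARB-25-100"]
OTHER_PD_DRUGS = ["PRAMIPEXOLE-0.5", "ROPINIROLE-1", "RASAGILINE-1"]
COGNITIVE_DRUGS = ["DONEPEZIL-10", "RIVASTIGMINE-4.6",
                   "MEMANTINE-10", "GALANTAMINE-8"]
PD_DRUG_CLASSES = {"levodopa", "other_pd"}

# Referral vocabulary (synthetic): neurology referral for cognitive decline.
COGNITIVE_REFERRAL_CODE = "REF-NEURO-COG"

# Background (distractor) diagnosis codes carried by routine encounters.
BACKGROUND_CODES = [("I10", "ICD10"), ("E11.9", "ICD10"), ("M19.90", "ICD10"),
                    ("J06.9", "ICD10"), ("401.9", "ICD9"), ("Z00.00", "ICD10")]
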