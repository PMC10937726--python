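"""Source-archetype configuration for the synthetic EHR generator.

Four archetypes emulate the statistical structure of the data sources the
analysis is designed around:

``research``
    An actively assessed longitudinal biomarkers cohort: annual structured
    study visits, near-complete clinical-scale recording, diagnosis dates
    known (at year resolution), younger patients, slow progression.
``research_survey``
    An online self-survey research study: year-resolution diagnosis dates,
    short follow-up, no clinician-recorded rating scales.
``rwd_emr``
    A hospital-system EMR: passively collected encounters, sparse scale
    recording in free-text notes, older patients, faster progression.
``rwd_claims``
    Linked claims + EHR: like the EMR archetype but with insurance
    coverage intervals (and possible gaps) and no rating scales.

Every calibration default is expressed in clinical units (years, scale
points, encounters/year); overrides are validated against the same
invariants as the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class ArchetypeConfig:
    """Parameters of one synthetic source archetype.

    Trajectory parameters describe population-mean linear score courses,
    ``score = intercept + slope * years_since_diagnosis`` (MMSE slope is
    negative: cognitive decline).  Event-time parameters give medians or
    means of the time from diagnosis to each clinical event.
    """

    name: str
    # demographics & observation process
    age_at_dx_mean: float = 65.0          # years
    age_at_dx_sd: float = 10.0            # years; truncated to [30, 95]
    pct_male: float = 0.6                 # fraction
    followup_mean: float = 4.0            # years, exponential
    followup_min: float = 0.25            # years, floor on follow-up
    encounter_rate: float = 6.0           # encounters / year (Poisson)
    pre_dx_history_prob: float = 0.9      # P(any pre-diagnosis history)
    pre_dx_history_years: float = 4.0     # mean span of pre-dx history
    dx_resolution: str = "day"            # "day" | "year"
    # rating-scale recording
    score_recording_prob: float = 0.5     # fraction of patients with scores
    score_in_note_prob: float = 0.95      # P(scale present | recording note)
    specialist_prob: float = 0.3          # fraction seen by a specialist
    specialist_score_or: float = 1.5      # odds ratio of recording | specialist
    # trajectories (population means, points and points/year)
    updrs_intercept: float = 25.0
    updrs_slope: float = 2.0
    mmse_intercept: float = 27.0
    mmse_slope: float = -0.2
    hy_intercept: float = 2.0             # stage at diagnosis (pre-quantization)
    intercept_re_sd: float = 0.0          # per-patient random intercept sd
    score_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"updrs_total": 4.0, "mmse": 1.0, "hy": 0.0}
    )
    # event-time calibration
    hy3_median_years: float = 8.0         # median years to first H&Y >= 3
    event_shape: float = 1.5              # Weibull shape for event times
    therapy_delay_mean: float = 2.0       # years, diagnosis -> first PD med
    therapy_delay_sd: float = 0.5
    levodopa_delay_mean: float = 2.5      # years, diagnosis -> levodopa
    cogdecline_median_years: float = 9.0
    adverse_event_rates: Mapping[str, float] = field(
        default_factory=lambda: {"falls_fractures": 0.05, "depression": 0.04}
    )
    prior_adverse_prob: float = 0.03      # P(adverse code inside quiescence)
    mimic_code_prob: float = 0.03         # P(PD-mimic code inside quiescence)
    post_dx_pd_code_prob: float = 0.7     # P(PD code at a post-dx encounter)
    # claims structure
    coverage_gap_prob: float = 0.0        # claims archetype only
    # phenotyping behaviour
    phenotyping: str = "encounter"        # "encounter" | "coverage" | "stated"
    # covariate effects on trajectories (default: none)
    sex_effect: float = 0.0               # points, added for male patients

    def __post_init__(self) -> None:
        probs = {
            "pct_male": self.pct_male,
            "score_recording_prob": self.score_recording_prob,
            "score_in_note_prob": self.score_in_note_prob,
            "pre_dx_history_prob": self.pre_dx_history_prob,
            "specialist_prob": self.specialist_prob,
            "coverage_gap_prob": self.coverage_gap_prob,
            "prior_adverse_prob": self.prior_adverse_prob,
            "mimic_code_prob": self.mimic_code_prob,
            "post_dx_pd_code_prob": self.post_dx_pd_code_prob,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        sds = {
            "age_at_dx_sd": self.age_at_dx_sd,
            "therapy_delay_sd": self.therapy_delay_sd,
            "intercept_re_sd": self.intercept_re_sd,
            **{f"score_noise_sd[{k}]": v for k, v in self.score_noise_sd.items()},
        }
        for k, v in sds.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        for k in ("hy3_median_years", "cogdecline_median_years", "followup_mean",
                  "encounter_rate", "event_shape"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be > 0")
        if self.dx_resolution not in ("day", "year"):
            raise ValueError("dx_resolution must be 'day' or 'year'")
        if self.dx_resolution == "year" and not self.name.startswith("research"):
            raise ValueError("year-resolution diagnosis dates are a research-"
                             "archetype feature")
        if self.phenotyping not in ("encounter", "coverage", "stated"):
            raise ValueError("phenotyping must be encounter|coverage|stated")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["score_noise_sd"] = dict(self.score_noise_sd)
        d["adverse_event_rates"] = dict(self.adverse_event_rates)
        return d


# Calibration defaults.  Research and RWD trajectory/event parameters are the
# values the analysis must recover: mean ages at diagnosis 60.4 / 72.2 y,
# UPDRS 28.25 + 1.54 t / 18.93 + 3.87 t, MMSE 28.7 - 0.11 t / 25.8 - 0.28 t,
# RWD median time to H&Y >= 3 of 5.6 y (research set beyond follow-up), and a
# PD-therapy initiation delay 2.3 y longer in RWD than research.
_DEFAULTS: dict[str, dict[str, Any]] = {
    "research": dict(
        age_at_dx_mean=60.4, pct_male=0.67, followup_mean=6.2,
        encounter_rate=1.0, dx_resolution="year", phenotyping="stated",
        pre_dx_history_prob=0.0,
        score_recording_prob=0.912, score_in_note_prob=1.0,
        specialist_prob=1.0, specialist_score_or=1.0,
        updrs_intercept=28.25, updrs_slope=1.54,
        mmse_intercept=28.7, mmse_slope=-0.11, hy_intercept=2.1,
        hy3_median_years=15.0, cogdecline_median_years=12.0,
        therapy_delay_mean=1.0, levodopa_delay_mean=2.5,
        adverse_event_rates={"falls_fractures": 0.03, "depression": 0.03},
        mimic_code_prob=0.0,
    ),
    "research_survey": dict(
        age_at_dx_mean=60.3, pct_male=0.558, followup_mean=1.0,
        followup_min=0.1,
        encounter_rate=2.0, dx_resolution="year", phenotyping="stated",
        pre_dx_history_prob=0.0,
        score_recording_prob=0.0,
        updrs_intercept=28.25, updrs_slope=1.54,
        mmse_intercept=28.7, mmse_slope=-0.11, hy_intercept=2.1,
        hy3_median_years=15.0, cogdecline_median_years=12.0,
        therapy_delay_mean=0.6, levodopa_delay_mean=2.5,
        adverse_event_rates={"falls_fractures": 0.03, "depression": 0.03},
        mimic_code_prob=0.0,
    ),
    "rwd_emr": dict(
        age_at_dx_mean=72.2, pct_male=0.578, followup_mean=3.8,
        encounter_rate=8.0, dx_resolution="day", phenotyping="encounter",
        pre_dx_history_prob=0.9,
        score_recording_prob=0.081,
        updrs_intercept=18.93, updrs_slope=3.87,
        mmse_intercept=25.8, mmse_slope=-0.28, hy_intercept=2.3,
        hy3_median_years=5.6, cogdecline_median_years=7.0,
        therapy_delay_mean=3.3, levodopa_delay_mean=3.5,
        adverse_event_rates={"falls_fractures": 0.05, "depression": 0.04},
    ),
    "rwd_claims": dict(
        age_at_dx_mean=72.1, pct_male=0.567, followup_mean=3.1,
        encounter_rate=8.0, dx_resolution="day", phenotyping="coverage",
        pre_dx_history_prob=0.95, coverage_gap_prob=0.1,
        score_recording_prob=0.0,
        updrs_intercept=18.93, updrs_slope=3.87,
        mmse_intercept=25.8, mmse_slope=-0.28, hy_intercept=2.3,
        hy3_median_years=5.6, cogdecline_median_years=7.0,
        therapy_delay_mean=3.3, levodopa_delay_mean=3.5,
        adverse_event_rates={"falls_fractures": 0.08, "depression": 0.06},
    ),
}

ARCHETYPES = tuple(_DEFAULTS)


def make_archetype_config(name: str,
                          overrides: Mapping[str, Any] | None = None
                          ) -> ArchetypeConfig:
    """Build the configuration for a named archetype, with overrides.

    Raises ``KeyError`` for an unknown archetype and ``ValueError`` when an
    override violates a configuration invariant.
    """
    if name not in _DEFAULTS:
        raise KeyError(f"unknown archetype {name!r}; known: {list(_DEFAULTS)}")
    cfg = ArchetypeConfig(name=name, **_DEFAULTS[name])
    if overrides:
        bad = set(overrides) - set(cfg.to_dict())
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        cfg = replace(cfg, **dict(overrides))
    return cfg


def load_archetype_yaml(path, name: str) -> ArchetypeConfig:
    """Read a YAML file with one block per archetype and build one config."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh) or {}
    return make_archetype_config(name, blocks.get(name, {}))
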