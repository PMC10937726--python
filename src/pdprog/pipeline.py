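"""End-to-end orchestration: generate -> cohort -> extract -> events -> stats.

A single :func:`run_pipeline` call simulates one or more source archetypes,
phenotypes each into an incident cohort, extracts rating scores from the
synthetic notes with the consensus protocol, detects clinical events, and
computes the comparison statistics (cohort characteristics, Kaplan-Meier
summaries with log-rank contrasts, progression fits and slope comparisons,
the visit-level phi validation of the cognitive-decline proxy, and the
missingness audit).  All randomness derives from one master seed via stable
per-stage seeds, so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import events as ev
from . import extraction as ex
from . import stats as st
from .archetypes import make_archetype_config
from .cohort import CohortConfig, build_cohort
from .generator import generate_dataset
from .records import DAYS_PER_YEAR, write_dataset
from .scales import SCALES

log = logging.getLogger("pdprog")

SCHEMA_VERSION = 1


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    archetypes: Sequence[str] = ("research", "rwd_emr")
    n: int = 1000
    master_seed: int = 0
    overrides: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    backend: str = "reference"          # reference | mock
    mock_p: float = 0.05
    out_dir: str | None = None
    scales: Sequence[str] = tuple(SCALES)
    horizon_years: int = 10


def _make_backend(config: RunConfig):
    if config.backend == "reference":
        return ex.ReferenceBackend()
    if config.backend == "mock":
        return ex.NoisyMockBackend(config.mock_p,
                                   derive_seed(config.master_seed, "mock"))
    raise ValueError(f"unknown backend {config.backend!r}")


def _cohort_characteristics(dataset, cohort) -> dict:
    rows = cohort.rows
    inc = rows[rows["included"]]
    dx_by_id = dict(zip(inc["patient_id"], inc["initial_dx_date"]))
    pats = [p for p in dataset.patients if p.patient_id in dx_by_id]
    ages, followups, male, any_score = [], [], 0, 0
    for p in pats:
        dx = dx_by_id[p.patient_id]
        ages.append((dx - p.birth_date).days / DAYS_PER_YEAR)
        last = max((e.date for e in p.encounters), default=dx)
        followups.append(max(0.0, (last - dx).days / DAYS_PER_YEAR))
        male += p.sex == "M"
        any_score += any(ex.reference_extractor(n.text, s) is not None
                         for n in p.notes for s in SCALES)
    n_inc = len(pats)
    return {
        "source": dataset.source,
        "n_total": len(dataset.patients),
        "n_included": n_inc,
        "pct_male": male / n_inc if n_inc else float("nan"),
        "mean_age_at_dx": float(np.mean(ages)) if ages else float("nan"),
        "mean_followup_years": float(np.mean(followups)) if followups else float("nan"),
        "frac_with_scores": any_score / n_inc if n_inc else float("nan"),
    }


def _extract_all(dataset, cohort, scales, backend) -> dict[str, dict[str, float | None]]:
    """scale -> note_id -> final value, over included patients' notes."""
    included = set(cohort.included_ids)
    notes = [n for p in dataset.patients if p.patient_id in included
             for n in p.notes]
    out: dict[str, dict[str, float | None]] = {}
    for scale in scales:
        results = ex.extract_scores(notes, scale, backend)
        out[scale] = {r.note_id: r.final_value for r in results}
        n_flag = sum(r.final_value is None and r.flagged for r in results)
        log.info("extracted %s: %d notes, %d flagged", scale, len(notes), n_flag)
    return out


def _progression_table(dataset, cohort, extracted, scale) -> pd.DataFrame:
    dx_by_id = dict(zip(cohort.rows["patient_id"], cohort.rows["initial_dx_date"]))
    included = set(cohort.included_ids)
    rows = []
    values = extracted.get(scale, {})
    for p in dataset.patients:
        if p.patient_id not in included:
            continue
        dx = dx_by_id[p.patient_id]
        age = (dx - p.birth_date).days / DAYS_PER_YEAR
        for n in p.notes:
            v = values.get(n.note_id)
            if v is None or n.date < dx:
                continue
            rows.append({"patient_id": p.patient_id, "source": dataset.source,
                         "t": (n.date - dx).days / DAYS_PER_YEAR, "value": v,
                         "age_at_dx": age, "sex": p.sex})
    return pd.DataFrame(rows, columns=["patient_id", "source", "t", "value",
                                       "age_at_dx", "sex"])


def _phi_validation(dataset, cohort, extracted) -> dict | None:
    """Visit-level phi between the RWD cognitive-decline proxy and the
    MMSE <= 25 threshold, over visits where an MMSE value was extracted."""
    dx_by_id = dict(zip(cohort.rows["patient_id"], cohort.rows["initial_dx_date"]))
    included = set(cohort.included_ids)
    mmse = extracted.get("mmse", {})
    a, b, n_pat = [], [], 0
    for p in dataset.patients:
        if p.patient_id not in included:
            continue
        dx = dx_by_id[p.patient_id]
        proxy_date = ev.detect_cognitive_decline_rwd(p, dx)
        visits = [(n.date, mmse[n.note_id]) for n in p.notes
                  if mmse.get(n.note_id) is not None and n.date >= dx]
        if not visits:
            continue
        n_pat += 1
        for d, v in visits:
            a.append(int(v <= 25.0))
            b.append(int(proxy_date is not None and proxy_date <= d))
    try:
        phi = ev.phi_coefficient(a, b)
    except ValueError:
        return None
    return {"phi": float(phi), "n_visits": len(a), "n_patients": n_pat}


def _missingness_table(dataset, cohort, truth) -> tuple[pd.DataFrame, list[int]]:
    dx_by_id = dict(zip(cohort.rows["patient_id"], cohort.rows["initial_dx_date"]))
    included = set(cohort.included_ids)
    rows, y = [], []
    for p in dataset.patients:
        if p.patient_id not in included:
            continue
        t = truth.patients[p.patient_id]
        dx = dx_by_id[p.patient_id]
        rows.append({"age_at_dx": (dx - p.birth_date).days / DAYS_PER_YEAR,
                     "sex": 1.0 if p.sex == "M" else 0.0,
                     "n_encounters": float(len(p.encounters)),
                     "specialist": 1.0 if t.specialist else 0.0})
        y.append(int(t.has_scores))
    return pd.DataFrame(rows), y


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured archetype; returns the bundle.

    The bundle is a JSON-serializable mapping with per-source attrition,
    cohort characteristics, KM summaries and pairwise log-rank p-values per
    event, progression fits and slope comparisons per scale, the phi
    validation, and the missingness audit.
    """
    backend = _make_backend(config)
    bundle: dict[str, Any] = {"schema_version": SCHEMA_VERSION,
                              "config": {"archetypes": list(config.archetypes),
                                         "n": config.n,
                                         "master_seed": config.master_seed,
                                         "backend": config.backend},
                              "sources": {}}
    per_source: dict[str, dict[str, Any]] = {}
    for name in config.archetypes:
        acfg = make_archetype_config(name, config.overrides.get(name, {}))
        seed = derive_seed(config.master_seed, f"generate:{name}")
        log.info("stage=generate source=%s n=%d seed=%d", name, config.n, seed)
        ds, truth = generate_dataset(acfg, config.n, seed)
        cohort = build_cohort(ds, CohortConfig(mode=acfg.phenotyping))
        log.info("stage=cohort source=%s attrition=%s", name, cohort.attrition)
        extracted = _extract_all(ds, cohort, config.scales, backend)
        events = ev.detect_events(ds, cohort, extracted)
        per_source[name] = {"dataset": ds, "truth": truth, "cohort": cohort,
                            "extracted": extracted, "events": events,
                            "config": acfg}
        src: dict[str, Any] = {
            "attrition": cohort.attrition,
            "characteristics": _cohort_characteristics(ds, cohort),
            "km": {}, "progression": {}, "therapy_delay_mean": None,
        }
        for etype, g in events.groupby("event_type"):
            curve = st.km_fit(g["time"], g["observed"])
            src["km"][etype] = {"median": curve.median,
                                "median_ci": list(curve.median_ci),
                                "median_label": curve.median_label,
                                "n": int(len(g)),
                                "n_events": int(g["observed"].sum())}
        obs = events[(events["event_type"] == "pd_therapy") & events["observed"]]
        if len(obs):
            src["therapy_delay_mean"] = float(obs["time"].mean())
        for scale in config.scales:
            tab = _progression_table(ds, cohort, extracted, scale)
            if len(tab) >= 30 and tab["t"].nunique() > 2:
                fit = st.fit_progression_model(tab, scale)
                src["progression"][scale] = fit.summary_dict()
        phi = _phi_validation(ds, cohort, extracted)
        if phi:
            src["phi_validation"] = phi
        feats, y = _missingness_table(ds, cohort, truth)
        if 0 < sum(y) < len(y):
            src["missingness_audit"] = st.missingness_audit(
                feats, y, seed=derive_seed(config.master_seed, f"miss:{name}"))
        bundle["sources"][name] = src

    # pairwise contrasts (first source is the reference)
    names = list(config.archetypes)
    bundle["contrasts"] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pair: dict[str, Any] = {}
            ea, eb = per_source[a]["events"], per_source[b]["events"]
            for etype in sorted(set(ea["event_type"]) & set(eb["event_type"])):
                ga = ea[ea["event_type"] == etype]
                gb = eb[eb["event_type"] == etype]
                stat, p = st.logrank_test(ga["time"], ga["observed"],
                                          gb["time"], gb["observed"])
                pair[f"logrank_{etype}"] = {"statistic": stat, "p": p}
            ta = bundle["sources"][a]["therapy_delay_mean"]
            tb = bundle["sources"][b]["therapy_delay_mean"]
            if ta is not None and tb is not None:
                pair["therapy_delay_difference"] = tb - ta
            for scale in config.scales:
                pa = _progression_table(per_source[a]["dataset"],
                                        per_source[a]["cohort"],
                                        per_source[a]["extracted"], scale)
                pb = _progression_table(per_source[b]["dataset"],
                                        per_source[b]["cohort"],
                                        per_source[b]["extracted"], scale)
                if len(pa) >= 30 and len(pb) >= 30:
                    comp = st.compare_progression_slopes(pd.concat([pa, pb]))
                    pair[f"slope_comparison_{scale}"] = {
                        "difference": comp.difference,
                        "std_error": comp.std_error, "p": comp.p_value,
                        "separate_fit_difference": comp.separate_fit_difference}
            bundle["contrasts"][f"{a}_vs_{b}"] = pair

    if config.out_dir:
        write_report(bundle, per_source, config.out_dir)
    bundle["_state"] = per_source
    return bundle


def _json_default(o):
    import datetime

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (datetime.date,)):
        return o.isoformat()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(bundle: dict, per_source: dict | None, out_dir,
                 figures: bool = False) -> None:
    """Persist the bundle: results.json, per-source tables, optional figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = {k: v for k, v in bundle.items() if k != "_state"}
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(clean, fh, indent=2, default=_json_default)
    chars = [s["characteristics"] for s in clean["sources"].values()]
    pd.DataFrame(chars).to_csv(out / "table1_characteristics.csv", index=False)
    if per_source:
        for name, state in per_source.items():
            sdir = out / name
            sdir.mkdir(exist_ok=True)
            write_dataset(state["dataset"], state["truth"], sdir / "data")
            state["cohort"].rows.to_csv(sdir / "cohort.csv", index=False)
            with open(sdir / "attrition.json", "w") as fh:
                json.dump(state["cohort"].attrition, fh, indent=2)
            state["events"].to_csv(sdir / "events.csv", index=False)
            if figures:
                _write_figures(state, sdir)
    log.info("report written to %s", out)


def _write_figures(state, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    events = state["events"]
    if len(events):
        fig, ax = plt.subplots(figsize=(7, 5))
        for etype, g in events.groupby("event_type"):
            kmf = KaplanMeierFitter()
            kmf.fit(g["time"], g["observed"], label=etype)
            kmf.plot_survival_function(ax=ax, ci_show=True)
        ax.set_xlabel("years since initial diagnosis")
        ax.set_ylabel("event-free proportion")
        fig.savefig(out_dir / "km_curves.png", dpi=120)
        plt.close(fig)
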