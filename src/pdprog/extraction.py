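"""Clinical-score extraction with self-consistency voting and audit tooling.

The extraction protocol mirrors a few-shot LLM pipeline audited by chart
review: each note is queried 20 times per scale — 10 runs prompted with
positive exemplars (exemplar notes that contain a score) and 10 with
negative exemplars — and a note is *flagged* unless, within each polarity
set, at least 9 of the 10 runs agree on a single modal output and the two
polarity modal outputs coincide.  Flagged notes yield no value until a
manual correction is merged.  A ``pooled`` mode (18 of 20 across both sets)
is available behind a switch.

The actual LLM is out of scope; any callable satisfying
:class:`ExtractorBackend` can be plugged in.  Two reference backends ship
with the package: a deterministic template parser (the oracle for synthetic
notes) and a noisy mock that corrupts runs independently, used to exercise
the flagging statistics.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .scales import get_scale

AMBIGUOUS = "ambiguous"

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}

_PATTERNS = {
    "hy": re.compile(r"Hoehn and Yahr stage:\s*([0-9IViv]+(?:[.,]5)?)[\s.]"),
    "updrs_total": re.compile(r"UPDRS total:\s*([0-9]+(?:[.,][0-9]+)?)[\s.]"),
    "mmse": re.compile(r"MMSE:\s*([0-9]+(?:[.,][0-9]+)?)/30"),
}


def normalize_value(raw: str) -> float | None:
    """Normalize a raw extracted token to a numeric score.

    Dialects handled: decimal comma ("2,5"), roman stage numerals
    ("II", "II.5"), surrounding whitespace.  Returns None when the token is
    not interpretable as a number.
    """
    tok = raw.strip().replace(",", ".")
    m = re.fullmatch(r"([IVXivx]+)(\.5)?", tok)
    if m:
        base = _ROMAN.get(m.group(1).upper())
        if base is None:
            return None
        return base + (0.5 if m.group(2) else 0.0)
    try:
        return float(tok)
    except ValueError:
        return None


def reference_extractor(text: str, scale: str) -> float | str | None:
    """Deterministic template parser for synthetic notes.

    Returns the score when the scale's template phrase occurs once, None
    when absent, and the sentinel ``"ambiguous"`` when the phrase occurs
    with conflicting values.
    """
    pat = _PATTERNS[get_scale(scale).name]
    values = [normalize_value(m) for m in pat.findall(text)]
    values = [v for v in values if v is not None]
    if not values:
        return None
    if len(set(values)) > 1:
        return AMBIGUOUS
    return values[0]


class ExtractorBackend(Protocol):
    """Contract for pluggable extractors.

    Must be pure given ``(text, scale, polarity, run_index)`` — repeated
    calls with the same arguments return the same output.
    """

    def __call__(self, text: str, scale: str, polarity: str,
                 run_index: int) -> float | None: ...


def _stable_u32(*parts) -> int:
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big")


class ReferenceBackend:
    """Backend wrapping :func:`reference_extractor`.

    On ambiguous notes it behaves like an inconsistent reader: each run
    deterministically picks one of the conflicting values (keyed on text,
    polarity and run index), which yields split votes and a flagged
    consensus — the behaviour observed for real multi-score notes.
    """

    def __call__(self, text: str, scale: str, polarity: str,
                 run_index: int) -> float | None:
        out = reference_extractor(text, scale)
        if out != AMBIGUOUS:
            return out
        pat = _PATTERNS[get_scale(scale).name]
        vals = sorted({normalize_value(m) for m in pat.findall(text)}
                      - {None})
        pick = _stable_u32(text, scale, polarity, run_index) % len(vals)
        return vals[pick]


class NoisyMockBackend:
    """Reference backend corrupted independently per run with probability p.

    A corrupted run returns either a wrong value from the scale's grid or
    None.  Deterministic given the constructor seed (run outcomes are keyed
    on note text, scale, polarity and run index).
    """

    def __init__(self, p: float, seed: int = 0):
        if not 0 <= p <= 1:
            raise ValueError("p must be in [0, 1]")
        self.p = p
        self.seed = seed
        self._ref = ReferenceBackend()

    def __call__(self, text: str, scale: str, polarity: str,
                 run_index: int) -> float | None:
        truth = self._ref(text, scale, polarity, run_index)
        rng = np.random.default_rng(
            _stable_u32(self.seed, text, scale, polarity, run_index))
        if rng.random() >= self.p:
            return truth
        sc = get_scale(scale)
        grid = np.arange(sc.lo, sc.hi + 1e-9, sc.step or 1.0)
        wrong = [float(v) for v in grid if v != truth][:20] + [None]
        return wrong[int(rng.integers(0, len(wrong)))]


@dataclass
class ConsensusResult:
    note_id: str
    scale: str
    runs: list = field(default_factory=list)      # 20 outputs, pos then neg
    modal_value: float | None = None
    per_polarity_agreement: tuple[int, int] = (0, 0)
    flagged: bool = False
    final_value: float | None = None
    provenance: str = "consensus"                 # consensus | manual_correction | error


def _modal(outputs: Sequence) -> tuple[float | None, int, bool]:
    """Modal output, its count, and whether the mode is tied."""
    counts = Counter(outputs)
    (top, c1), *rest = counts.most_common()
    tied = bool(rest) and rest[0][1] == c1
    return top, c1, tied


def run_consensus(note, scale: str, backend, n_pos: int = 10, n_neg: int = 10,
                  threshold: int = 9, mode: str = "per_polarity"
                  ) -> ConsensusResult:
    """Execute the self-consistency protocol on one note.

    ``per_polarity`` mode (default): flag when either polarity set's modal
    count is below ``threshold`` (out of its 10 runs), when a modal value is
    tied, or when the two polarity modes differ.  ``pooled`` mode: flag when
    the pooled modal count over all runs is below ``threshold * 2``.
    """
    if threshold > min(n_pos, n_neg):
        raise ValueError("threshold cannot exceed the per-polarity run count")
    if mode not in ("per_polarity", "pooled"):
        raise ValueError("mode must be 'per_polarity' or 'pooled'")
    res = ConsensusResult(note_id=note.note_id, scale=scale)
    try:
        pos = [backend(note.text, scale, "positive", i) for i in range(n_pos)]
        neg = [backend(note.text, scale, "negative", i) for i in range(n_neg)]
    except Exception:
        res.flagged = True
        res.provenance = "error"
        return res
    res.runs = pos + neg
    m_pos, c_pos, tie_pos = _modal(pos)
    m_neg, c_neg, tie_neg = _modal(neg)
    res.per_polarity_agreement = (c_pos, c_neg)
    if mode == "per_polarity":
        ok = (c_pos >= threshold and c_neg >= threshold
              and not tie_pos and not tie_neg and m_pos == m_neg)
        modal = m_pos if ok else _modal(pos + neg)[0]
    else:
        modal, c_all, tie_all = _modal(pos + neg)
        ok = c_all >= 2 * threshold and not tie_all
    res.modal_value = modal
    res.flagged = not ok
    res.final_value = modal if ok else None
    return res


def extract_scores(notes, scale: str, backend, **kw) -> list[ConsensusResult]:
    """Run the consensus protocol over a collection of notes."""
    return [run_consensus(n, scale, backend, **kw) for n in notes]


@dataclass
class AuditSample:
    strata: dict[str, list[str]]

    @property
    def note_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.strata.values():
            out.extend(ids)
        return out


def audit_sample(results: Sequence[ConsensusResult],
                 gold_labels: Mapping[str, float | None],
                 strata_sizes: Mapping[str, int], seed: int) -> AuditSample:
    """Stratified audit sampling for manual review.

    Strata: ``gold_positive`` / ``gold_negative`` (reviewer did / did not
    identify a score) and ``model_positive`` / ``model_negative`` (the
    consensus did / did not yield a value).  Sampling is seeded and without
    replacement within each stratum; an exhausted stratum returns all its
    members with a warning.
    """
    pools = {
        "gold_positive": [r.note_id for r in results
                          if gold_labels.get(r.note_id) is not None],
        "gold_negative": [r.note_id for r in results
                          if gold_labels.get(r.note_id) is None],
        "model_positive": [r.note_id for r in results if r.final_value is not None],
        "model_negative": [r.note_id for r in results if r.final_value is None],
    }
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for name, size in strata_sizes.items():
        pool = pools[name]
        if len(pool) < size:
            warnings.warn(f"stratum {name!r} has only {len(pool)} notes "
                          f"(requested {size}); taking all")
            strata[name] = list(pool)
        else:
            idx = rng.choice(len(pool), size=size, replace=False)
            strata[name] = [pool[i] for i in sorted(idx)]
    return AuditSample(strata=strata)


def score_accuracy(results: Sequence[ConsensusResult],
                   gold: Mapping[str, float | None]
                   ) -> tuple[float, list[str]]:
    """Value-for-value accuracy over an audited set.

    A result is correct when its final value equals the gold value (both
    None counts as correct).  Returns the accuracy fraction and the ids of
    incorrect notes.
    """
    if not results:
        raise ValueError("no results to audit")
    errors = [r.note_id for r in results
              if r.final_value != gold.get(r.note_id)]
    return 1.0 - len(errors) / len(results), errors


def apply_corrections(results: Sequence[ConsensusResult],
                      corrections: Mapping[str, float | None]
                      ) -> list[ConsensusResult]:
    """Merge human-annotated values into flagged results.

    Only flagged notes may be overwritten (corrections are the resolution
    step of the flagging protocol); correcting an unflagged note raises.
    """
    by_id = {r.note_id: r for r in results}
    for nid, value in corrections.items():
        r = by_id.get(nid)
        if r is None:
            raise KeyError(f"no consensus result for note {nid!r}")
        if not r.flagged:
            raise ValueError(f"note {nid!r} is not flagged; refusing to "
                             "overwrite a consensus value")
        r.final_value = value
        r.provenance = "manual_correction"
    return list(results)
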