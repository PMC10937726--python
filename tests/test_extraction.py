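"""Consensus-voting protocol, audit sampling, accuracy and corrections."""

import math
from dataclasses import dataclass

import numpy as np
import pytest

from pdprog import (NoisyMockBackend, ReferenceBackend, apply_corrections,
                    audit_sample, generate_dataset, make_archetype_config,
                    run_consensus, score_accuracy)
from pdprog.extraction import (AMBIGUOUS, ConsensusResult, extract_scores,
                               normalize_value, reference_extractor)
from pdprog.generator import render_note


@dataclass
class Note:
    note_id: str
    text: str


class ScriptedBackend:
    """Returns pre-scripted outputs per (polarity, run_index)."""

    def __init__(self, pos, neg):
        self.outputs = {"positive": pos, "negative": neg}

    def __call__(self, text, scale, polarity, run_index):
        return self.outputs[polarity][run_index]


class FailingBackend:
    def __call__(self, *a):
        raise RuntimeError("backend down")


class TestReferenceExtractor:
    def test_template_parse(self):
        assert reference_extractor(
            "Exam stable. Hoehn and Yahr stage: 2.5. Continue meds.",
            "hy") == 2.5

    def test_distractor_only_text(self):
        assert reference_extractor(
            "Blood pressure 120/80. Seen for 30 minutes.", "hy") is None

    def test_conflicting_values_give_sentinel(self):
        text = ("Hoehn and Yahr stage: 2. Later in visit "
                "Hoehn and Yahr stage: 3.")
        assert reference_extractor(text, "hy") == AMBIGUOUS

    @pytest.mark.parametrize("raw,expected", [
        ("2,5", 2.5), ("2.5", 2.5), ("II.5", 2.5), ("III", 3.0),
        (" 3 ", 3.0), ("27.46", 27.46), ("NA-ish", None),
    ])
    def test_numeric_dialect_normalization(self, raw, expected):
        assert normalize_value(raw) == expected


class TestRunConsensus:
    def test_unanimous_runs_accepted(self):
        res = run_consensus(Note("n", ""), "hy",
                            ScriptedBackend([3.0] * 10, [3.0] * 10))
        assert not res.flagged
        assert res.final_value == 3.0
        assert res.per_polarity_agreement == (10, 10)

    def test_4_of_10_and_5_of_10_flagged(self):
        # the observed failure mode for multi-score notes: splintered votes
        pos = [2.0] * 4 + [3.0] * 3 + [1.0, 4.0, 5.0]
        neg = [3.0] * 5 + [2.0] * 3 + [1.0, None]
        res = run_consensus(Note("n", ""), "hy", ScriptedBackend(pos, neg))
        assert res.flagged
        assert res.final_value is None
        assert res.per_polarity_agreement == (4, 5)

    def test_9_and_10_agreement_on_same_value_accepted(self):
        pos = [3.0] * 9 + [2.0]
        res = run_consensus(Note("n", ""), "hy",
                            ScriptedBackend(pos, [3.0] * 10))
        assert not res.flagged
        assert res.final_value == 3.0

    def test_cross_polarity_disagreement_flagged(self):
        res = run_consensus(Note("n", ""), "hy",
                            ScriptedBackend([3.0] * 10, [2.0] * 10))
        assert res.flagged

    def test_modal_tie_flagged(self):
        pos = [3.0] * 5 + [2.0] * 5
        res = run_consensus(Note("n", ""), "hy",
                            ScriptedBackend(pos, [3.0] * 10), threshold=5)
        assert res.flagged

    def test_none_consensus_is_a_valid_outcome(self):
        res = run_consensus(Note("n", ""), "hy",
                            ScriptedBackend([None] * 10, [None] * 10))
        assert not res.flagged
        assert res.final_value is None

    def test_pooled_mode(self):
        pos = [3.0] * 8 + [2.0] * 2
        neg = [3.0] * 10
        per = run_consensus(Note("n", ""), "hy", ScriptedBackend(pos, neg))
        pooled = run_consensus(Note("n", ""), "hy", ScriptedBackend(pos, neg),
                               mode="pooled")
        assert per.flagged            # 8/10 in the positive set
        assert not pooled.flagged     # 18/20 pooled

    def test_threshold_monotonicity(self):
        """Raising the threshold never unflags a note."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            pos = list(rng.choice([1.0, 2.0, 3.0], size=10,
                                  p=[0.1, 0.1, 0.8]))
            neg = list(rng.choice([1.0, 3.0], size=10, p=[0.15, 0.85]))
            flagged = [run_consensus(Note("n", ""), "hy",
                                     ScriptedBackend(pos, neg), threshold=k
                                     ).flagged
                       for k in (6, 7, 8, 9, 10)]
            assert flagged == sorted(flagged)  # False...True, never back

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            run_consensus(Note("n", ""), "hy",
                          ScriptedBackend([3.0] * 10, [3.0] * 10), threshold=11)

    def test_backend_failure_marks_error(self):
        res = run_consensus(Note("n", ""), "hy", FailingBackend())
        assert res.flagged and res.provenance == "error"


def test_reference_round_trip_on_generated_notes():
    """100% unflagged agreement with ground truth on non-ambiguous notes."""
    cfg = make_archetype_config("research")
    ds, _ = generate_dataset(cfg, 60, seed=8)
    backend = ReferenceBackend()
    n_checked = 0
    for p in ds.patients:
        for note in p.notes:
            for scale, true_v in note.true_scores.items():
                res = run_consensus(note, scale, backend)
                assert not res.flagged
                if true_v is None:
                    assert res.final_value is None
                else:
                    assert res.final_value == pytest.approx(true_v)
                n_checked += 1
    assert n_checked > 300


def _expected_flag_rate(p: float) -> float:
    """Closed-form per-polarity flag rate under independent corruption.

    A set of 10 runs keeps the true modal value with >= 9 agreements iff at
    least 9 runs are uncorrupted; the note is unflagged iff both sets do
    (corrupted runs almost surely cannot assemble a 9-run false mode)."""
    ok = (1 - p) ** 10 + 10 * p * (1 - p) ** 9
    return 1 - ok**2


@pytest.mark.parametrize("p", [0.05, 0.2])
def test_mock_backend_flag_rate_matches_binomial(p):
    notes = [Note(f"n{i}", render_note({"hy": 2.0 + (i % 3) * 0.5},
                                       distractor_seed=i))
             for i in range(400)]
    backend = NoisyMockBackend(p, seed=5)
    results = extract_scores(notes, "hy", backend)
    rate = np.mean([r.flagged for r in results])
    expected = _expected_flag_rate(p)
    tol = 3 * math.sqrt(expected * (1 - expected) / len(notes))
    assert abs(rate - expected) < tol


class TestAuditAndCorrections:
    def _results(self, n=1000, pos_frac=0.5, flagged_every=50):
        out, gold = [], {}
        for i in range(n):
            has = i < n * pos_frac
            r = ConsensusResult(note_id=f"n{i}", scale="hy",
                                final_value=2.0 if has else None)
            if flagged_every and i % flagged_every == 0:
                r.flagged, r.final_value = True, None
            out.append(r)
            gold[f"n{i}"] = 2.0 if has else None
        return out, gold

    def test_four_strata_of_200_give_800(self):
        results, gold = self._results()
        sample = audit_sample(results, gold,
                              {"gold_positive": 200, "model_positive": 200,
                               "model_negative": 200, "gold_negative": 200},
                              seed=3)
        assert len(sample.note_ids) == 800
        assert all(len(v) == 200 for v in sample.strata.values())

    def test_sampling_is_seeded_and_without_replacement(self):
        results, gold = self._results()
        sizes = {"gold_positive": 100, "model_negative": 100}
        a = audit_sample(results, gold, sizes, seed=3)
        b = audit_sample(results, gold, sizes, seed=3)
        c = audit_sample(results, gold, sizes, seed=4)
        assert a.strata == b.strata
        assert a.strata != c.strata
        for ids in a.strata.values():
            assert len(set(ids)) == len(ids)

    def test_exhausted_stratum_warns_and_returns_all(self):
        results, gold = self._results(n=60, pos_frac=0.5)
        with pytest.warns(UserWarning):
            s = audit_sample(results, gold, {"gold_positive": 200}, seed=1)
        assert len(s.strata["gold_positive"]) == 30

    def test_accuracy_counting(self):
        results, gold = self._results(n=800, pos_frac=1.0, flagged_every=0)
        acc, errors = score_accuracy(results, gold)
        assert acc == 1.0 and not errors
        # 2 wrong of 800 -> 99.75%
        gold2 = dict(gold)
        gold2["n0"] = 3.0
        gold2["n1"] = None
        acc2, errors2 = score_accuracy(results, gold2)
        assert acc2 == pytest.approx(0.9975)
        assert set(errors2) == {"n0", "n1"}

    def test_accuracy_all_none_vs_half_positive(self):
        results, gold = self._results(n=100, pos_frac=0.5, flagged_every=0)
        for r in results:
            r.final_value = None
        acc, _ = score_accuracy(results, gold)
        assert acc == 0.5

    def test_corrections_only_touch_flagged_notes(self):
        results, _ = self._results(n=100)
        flagged = next(r for r in results if r.flagged)
        ok = next(r for r in results if not r.flagged)
        out = apply_corrections(results, {flagged.note_id: 4.0})
        fixed = next(r for r in out if r.note_id == flagged.note_id)
        assert fixed.final_value == 4.0
        assert fixed.provenance == "manual_correction"
        with pytest.raises(ValueError):
            apply_corrections(results, {ok.note_id: 4.0})

    def test_empty_corrections_identity(self):
        results, _ = self._results(n=10)
        before = [(r.note_id, r.final_value, r.provenance) for r in results]
        apply_corrections(results, {})
        after = [(r.note_id, r.final_value, r.provenance) for r in results]
        assert before == after
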