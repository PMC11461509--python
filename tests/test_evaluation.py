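"""Strict/partial entity alignment, scoring, IAA — with a brute-force oracle."""

import random

import numpy as np
import pytest

from pkner.corpus import Corpus, EntitySpan, Sentence, ValidationError
from pkner.evaluation import (
    MatchCounts,
    align_spans,
    evaluate_corpus,
    pairwise_iaa,
    score,
)

from conftest import random_span_list


def brute_force_counts(gold, pred):
    """Enumerate injective gold<->pred matchings, maximizing exact-boundary
    matches first and overlap matches second, then tally the categories.
    Independent of the greedy implementation."""
    overlapping = [
        [j for j, p in enumerate(pred) if p.start < g.end and g.start < p.end]
        for g in gold
    ]

    best = (-1, -1)
    best_counts = None

    def recurse(i, used, n_exact, n_overlap, pairs):
        nonlocal best, best_counts
        if i == len(gold):
            key = (n_exact, n_overlap)
            if key > best:
                best = key
                cor = inc = par = 0
                for gi, pj in pairs:
                    g, p = gold[gi], pred[pj]
                    if (g.start, g.end) == (p.start, p.end):
                        if g.label == p.label:
                            cor += 1
                        else:
                            inc += 1
                    else:
                        par += 1
                best_counts = MatchCounts(
                    COR=cor,
                    INC=inc,
                    PAR=par,
                    MIS=len(gold) - len(pairs),
                    SPU=len(pred) - len(pairs),
                )
            return
        recurse(i + 1, used, n_exact, n_overlap, pairs)
        g = gold[i]
        for j in overlapping[i]:
            if j in used:
                continue
            exact = (g.start, g.end) == (pred[j].start, pred[j].end)
            recurse(
                i + 1,
                used | {j},
                n_exact + (1 if exact else 0),
                n_overlap + 1,
                pairs + [(i, j)],
            )

    recurse(0, frozenset(), 0, 0, [])
    return best_counts


class TestAlignSpans:
    def test_identical_spans_all_correct(self):
        g = [EntitySpan(0, 9), EntitySpan(20, 25)]
        assert align_spans(g, list(g)) == MatchCounts(COR=2)

    def test_worked_mixture(self):
        gold = [EntitySpan(0, 9), EntitySpan(20, 25)]
        pred = [EntitySpan(0, 9), EntitySpan(21, 25), EntitySpan(30, 33)]
        assert align_spans(gold, pred) == MatchCounts(COR=1, PAR=1, MIS=0, SPU=1)

    def test_empty_gold_only_spurious(self):
        assert align_spans([], [EntitySpan(0, 3)]) == MatchCounts(SPU=1)

    def test_boundary_match_wrong_label_is_incorrect(self):
        counts = align_spans([EntitySpan(0, 5, "PK")], [EntitySpan(0, 5, "OTHER")])
        assert counts == MatchCounts(INC=1)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            align_spans([EntitySpan(0, 5), EntitySpan(3, 8)], [])

    def test_conservation_and_oracle_agreement(self):
        """On 1,000 random gold/pred pairs the greedy alignment satisfies
        the count conservation invariants and matches the brute-force
        matching oracle; strict and partial scores agree too."""
        rng = random.Random(20240901)
        try:
            import nervaluate  # noqa: F401

            have_nerv = True
        except ImportError:
            have_nerv = False
        for _ in range(1000):
            gold = random_span_list(rng)
            pred = random_span_list(rng)
            counts = align_spans(gold, pred)
            assert counts.n_gold == len(gold)
            assert counts.n_pred == len(pred)
            oracle = brute_force_counts(gold, pred)
            assert counts == oracle, (gold, pred)
            s, p = score(counts, "strict"), score(counts, "partial")
            assert p.f1 >= s.f1
            if have_nerv:
                from nervaluate import Evaluator

                g = [[{"start": x.start, "end": x.end - 1, "label": x.label} for x in gold]]
                q = [[{"start": x.start, "end": x.end - 1, "label": x.label} for x in pred]]
                res = Evaluator(g, q, tags=["PK", "OTHER"]).evaluate()[0]
                assert round(100 * res["strict"]["f1"], 2) == s.f1
                assert round(100 * res["partial"]["f1"], 2) == p.f1


class TestScore:
    def test_worked_example_strict_and_partial(self):
        counts = MatchCounts(COR=1, PAR=1, SPU=1, MIS=0)
        s = score(counts, "strict")
        assert (s.precision, s.recall, s.f1) == (33.33, 50.0, 40.0)
        p = score(counts, "partial")
        assert (p.precision, p.recall, p.f1) == (50.0, 75.0, 60.0)

    def test_all_zero_counts_flagged(self):
        s = score(MatchCounts())
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0) and s.empty_input

    def test_perfect(self):
        s = score(MatchCounts(COR=7))
        assert (s.precision, s.recall, s.f1) == (100.0, 100.0, 100.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            MatchCounts(COR=-1)


class TestEvaluateCorpus:
    def _corpus(self, spans_by_id):
        return Corpus(
            sentences=[
                Sentence(id=i, text="x" * 60, spans=sp) for i, sp in spans_by_id.items()
            ]
        )

    def test_identity_is_perfect(self, synth_1k):
        rep = evaluate_corpus(synth_1k, synth_1k)
        assert rep.strict.f1 == 100.0

    def test_shifted_spans_zero_strict_positive_partial(self):
        gold = self._corpus({"a": [EntitySpan(0, 9), EntitySpan(20, 25)]})
        pred = self._corpus({"a": [EntitySpan(1, 10), EntitySpan(21, 26)]})
        rep = evaluate_corpus(gold, pred)
        assert rep.strict.f1 == 0.0 and rep.partial.f1 > 0.0

    def test_empty_pred_zero_recall_flagged_precision(self):
        gold = self._corpus({"a": [EntitySpan(0, 9)]})
        pred = self._corpus({"a": []})
        rep = evaluate_corpus(gold, pred)
        assert rep.strict.recall == 0.0 and rep.strict.empty_input

    def test_id_mismatch_lists_ids(self):
        with pytest.raises(ValidationError, match="zzz"):
            evaluate_corpus(self._corpus({"a": []}), self._corpus({"zzz": []}))

    def test_micro_average_equals_concatenation(self):
        """Summing per-sentence counts then scoring equals scoring one big
        concatenated sentence."""
        rng = random.Random(5)
        per_sentence = [
            (random_span_list(rng), random_span_list(rng)) for _ in range(30)
        ]
        total = MatchCounts()
        for g, p in per_sentence:
            total = total + align_spans(g, p)
        width = 50
        big_gold, big_pred = [], []
        for k, (g, p) in enumerate(per_sentence):
            off = k * width
            big_gold += [EntitySpan(s.start + off, s.end + off, s.label) for s in g]
            big_pred += [EntitySpan(s.start + off, s.end + off, s.label) for s in p]
        assert align_spans(big_gold, big_pred) == total


class TestIAA:
    def _ann(self, spans_lists):
        return Corpus(
            sentences=[
                Sentence(id=f"s{i}", text="y" * 60, spans=sp)
                for i, sp in enumerate(spans_lists)
            ]
        )

    def test_identical_annotators_agree_fully(self):
        a = self._ann([[EntitySpan(0, 9)], []])
        m = pairwise_iaa({"a": a, "b": a})
        assert np.all(m.f1 == 100.0) and m.mean_pairwise_f1 == 100.0

    def test_symmetry_under_gold_pred_swap(self):
        rng = random.Random(11)
        a = self._ann([random_span_list(rng) for _ in range(20)])
        b = self._ann([random_span_list(rng) for _ in range(20)])
        m = pairwise_iaa({"a": a, "b": b})
        assert m.f1[0, 1] == m.f1[1, 0]
        assert np.all(np.diag(m.f1) == 100.0)

    def test_total_disagreement_zero(self):
        a = self._ann([[EntitySpan(0, 9)]])
        b = self._ann([[]])
        assert pairwise_iaa({"a": a, "b": b}).mean_pairwise_f1 == 0.0

    def test_mismatched_sentence_sets_rejected(self):
        a = self._ann([[], []])
        b = Corpus(sentences=[Sentence(id="other", text="t")])
        with pytest.raises(ValidationError):
            pairwise_iaa({"a": a, "b": b})
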