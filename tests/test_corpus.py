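"""Corpus model: types, tokenizer, BIO codec, I/O, statistics."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkner.corpus import (
    Corpus,
    CorpusFormatError,
    EntitySpan,
    Sentence,
    Token,
    ValidationError,
    bio_to_spans,
    corpus_stats,
    read_corpus,
    spans_to_bio,
    tokenize,
    write_corpus,
)


# ---------------------------------------------------------------------------
# invariants of the data types
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_span_rejects_inverted_boundaries(self):
        with pytest.raises(ValidationError):
            EntitySpan(5, 5)
        with pytest.raises(ValidationError):
            EntitySpan(-1, 3)

    def test_span_beyond_text_rejected(self):
        with pytest.raises(ValidationError, match="beyond"):
            Sentence(id="s", text="short", spans=[EntitySpan(0, 99)])

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            Sentence(
                id="s",
                text="abcdefghij",
                spans=[EntitySpan(0, 5), EntitySpan(3, 8)],
            )

    def test_cached_surface_must_match_slice(self):
        with pytest.raises(ValidationError, match="surface"):
            Sentence(
                id="s", text="clearance", spans=[EntitySpan(0, 5, surface="xxxxx")]
            )

    def test_duplicate_sentence_ids_rejected(self):
        s = Sentence(id="dup", text="x y z")
        with pytest.raises(ValidationError, match="duplicate"):
            Corpus(sentences=[s, Sentence(id="dup", text="other")])


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

class TestTokenizer:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("AUC0-24 was 4.2 mg·h/L", ["AUC0-24", "was", "4.2", "mg·h/L"]),
            ("", []),
            ("t1/2", ["t1/2"]),
            ("AUC0-∞ (F)", ["AUC0-∞", "(", "F", ")"]),
            ("total body clearance", ["total", "body", "clearance"]),
        ],
    )
    def test_examples(self, text, expected):
        assert [t.text for t in tokenize(text)] == expected

    def test_offsets_are_slices(self):
        text = "The Cmax of ibuprofen was 52.1 ng/mL."
        for tok in tokenize(text):
            assert text[tok.start : tok.end] == tok.text

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_no_nonspace_char_lost(self, text):
        """Joining token slices and the gaps between them reconstructs the
        input, and gaps contain only whitespace."""
        toks = tokenize(text)
        pos = 0
        rebuilt = []
        for t in toks:
            assert text[pos : t.start].strip() == ""
            rebuilt.append(text[pos : t.start])
            rebuilt.append(t.text)
            pos = t.end
        rebuilt.append(text[pos:])
        assert "".join(rebuilt) == text


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

class TestBioCodec:
    def test_single_token_span(self):
        text = "The clearance was high"
        toks = tokenize(text)
        tags = spans_to_bio(toks, [EntitySpan(4, 13)])
        assert tags == ["O", "B-PK", "O", "O"]

    def test_no_spans_all_outside(self):
        assert spans_to_bio(tokenize("a b c"), []) == ["O", "O", "O"]

    def test_multi_token_span(self):
        text = "The total body clearance fell"
        tags = spans_to_bio(tokenize(text), [EntitySpan(4, 24)])
        assert tags == ["O", "B-PK", "I-PK", "I-PK", "O"]

    def test_strict_policy_rejects_intra_token_boundary(self):
        toks = tokenize("clearance was")
        with pytest.raises(ValidationError, match="strict"):
            spans_to_bio(toks, [EntitySpan(0, 5)], policy="strict")

    def test_snap_policy_expands_to_token(self):
        toks = tokenize("clearance was")
        assert spans_to_bio(toks, [EntitySpan(0, 5)], policy="snap")[0] == "B-PK"

    def test_decode_simple_and_leading_I_repair(self):
        toks = tokenize("a clearance value here")
        assert bio_to_spans(toks, ["O", "B-PK", "I-PK", "O"]) == bio_to_spans(
            toks, ["O", "I-PK", "I-PK", "O"]
        )

    def test_decode_label_switch_starts_new_span(self):
        toks = tokenize("a b")
        spans = bio_to_spans(toks, ["B-PK", "I-OTHER"])
        assert [s.label for s in spans] == ["PK", "OTHER"]

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            bio_to_spans(tokenize("a"), ["X-PK"])

    def test_round_trip_on_synthetic_corpus(self, synth_1k):
        for s in synth_1k:
            toks = tokenize(s.text)
            tags = spans_to_bio(toks, s.spans, policy="snap")
            assert bio_to_spans(toks, tags) == [
                EntitySpan(sp.start, sp.end, sp.label) for sp in s.spans
            ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_single_record(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text(
            '{"text": "CL was 5 L/h", "spans": [{"start": 0, "end": 2, "label": "PK"}]}\n'
        )
        c = read_corpus(p)
        assert len(c) == 1 and len(c[0].spans) == 1
        assert c[0].section == "full_text" and c[0].section_defaulted

    def test_empty_file_is_empty_corpus(self, tmp_path):
        p = tmp_path / "e.jsonl"
        p.write_text("")
        assert len(read_corpus(p)) == 0

    def test_span_beyond_text_is_validation_error_naming_sentence(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"id": "s7", "text": "ab", "spans": [{"start": 0, "end": 9}]}\n')
        with pytest.raises(ValidationError, match="s7"):
            read_corpus(p)

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"text": "ok", "spans": []}\nnot json\n')
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus(p)

    def test_jsonl_round_trip(self, small_corpus, tmp_path):
        p = tmp_path / "rt.jsonl"
        write_corpus(small_corpus, p)
        back = read_corpus(p)
        assert back.ids() == small_corpus.ids()
        for a, b in zip(small_corpus, back):
            assert a.text == b.text and a.spans == b.spans and a.section == b.section

    def test_spanless_sentence_not_omitted(self, small_corpus, tmp_path):
        p = tmp_path / "rt.jsonl"
        write_corpus(small_corpus, p)
        recs = [json.loads(l) for l in p.read_text().splitlines()]
        assert recs[2]["spans"] == []

    def test_conll_round_trips_tokens_and_tags(self, synth_1k, tmp_path):
        sub = Corpus(sentences=list(synth_1k)[:50])
        p = tmp_path / "c.conll"
        write_corpus(sub, p, format="conll")
        back = read_corpus(p, format="conll")
        assert back.ids() == sub.ids()
        for a, b in zip(sub, back):
            assert [t.text for t in tokenize(a.text)] == [
                t.text for t in tokenize(b.text)
            ]
            assert len(a.spans) == len(b.spans)  # offsets re-derived, spans kept

    @given(data=st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_jsonl_round_trip_property(self, tmp_path_factory, data):
        """JSON-Lines round-trip is the identity on randomly built corpora."""
        words = st.sampled_from(["CL", "clearance", "was", "5", "mg", "of", "the"])
        sentences = []
        n = data.draw(st.integers(0, 6))
        for i in range(n):
            toks = data.draw(st.lists(words, min_size=1, max_size=8))
            text = " ".join(toks)
            spans = []
            if data.draw(st.booleans()):
                ti = data.draw(st.integers(0, len(toks) - 1))
                start = len(" ".join(toks[:ti])) + (1 if ti else 0)
                spans = [EntitySpan(start, start + len(toks[ti]))]
            sentences.append(
                Sentence(
                    id=f"s{i}",
                    text=text,
                    spans=spans,
                    section=data.draw(st.sampled_from(["abstract", "full_text"])),
                )
            )
        corpus = Corpus(sentences=sentences)
        p = tmp_path_factory.mktemp("rt") / "c.jsonl"
        write_corpus(corpus, p)
        back = read_corpus(p)
        for a, b in zip(corpus, back):
            assert (a.id, a.text, a.spans, a.section) == (b.id, b.text, b.spans, b.section)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestStats:
    def test_hand_counted(self):
        c = Corpus(
            sentences=[
                Sentence(id="1", text="clearance and Cmax",
                         spans=[EntitySpan(0, 9), EntitySpan(14, 18)]),
                Sentence(id="2", text="nothing"),
            ]
        )
        st_ = corpus_stats(c)
        assert (st_.n_sentences, st_.n_mentions, st_.pct_with_mentions) == (2, 2, 50.0)

    def test_empty_corpus_flagged_not_crashing(self):
        st_ = corpus_stats(Corpus())
        assert st_.undefined_pct and st_.n_sentences == 0

    def test_percentages_recomputed_from_raw_counts(self, synth_1k):
        st_ = corpus_stats(synth_1k)
        n_with = sum(1 for s in synth_1k if s.spans)
        n_ft = sum(1 for s in synth_1k if s.section == "full_text")
        assert abs(st_.pct_with_mentions - 100 * n_with / len(synth_1k)) < 0.01
        assert abs(st_.pct_full_text - 100 * n_ft / len(synth_1k)) < 0.01
        assert st_.n_mentions >= n_with
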