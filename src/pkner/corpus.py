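"""Sentence-level corpus model for PK named-entity recognition.

The universal currency of the toolkit is a sentence with character-offset
entity spans (0-based, half-open).  This module defines the data types,
the deterministic tokenizer, BIO encoding/decoding, corpus I/O in two
dialects (JSON-Lines with offsets; CoNLL-style token/tag) and corpus
statistics.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

DEFAULT_LABEL = "PK"

__all__ = [
    "EntitySpan",
    "Sentence",
    "Corpus",
    "Token",
    "TaggedSentence",
    "CorpusStats",
    "CorpusFormatError",
    "ValidationError",
    "tokenize",
    "spans_to_bio",
    "bio_to_spans",
    "read_corpus",
    "write_corpus",
    "corpus_stats",
]


class CorpusFormatError(ValueError):
    """A corpus file does not parse in the named dialect."""


class ValidationError(ValueError):
    """A sentence or span violates the corpus invariants."""


@dataclass(frozen=True)
class EntitySpan:
    """Character-offset entity mention, 0-based half-open [start, end)."""

    start: int
    end: int
    label: str = DEFAULT_LABEL
    surface: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span boundaries ({self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Token:
    """A tokenizer output unit: substring plus its character offsets."""

    text: str
    start: int
    end: int


@dataclass
class Sentence:
    """One sentence with its gold (or predicted) entity spans.

    ``section`` records whether the sentence came from an abstract or the
    full text of an article; records missing it default to ``full_text``
    and are flagged (``section_defaulted``) so statistics can report how
    many were imputed.
    """

    id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)
    section: str = "full_text"
    doc_id: str | None = None
    section_defaulted: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.section not in ("abstract", "full_text"):
            raise ValidationError(
                f"sentence {self.id!r}: unknown section {self.section!r}"
            )
        prev_end = -1
        for sp in self.spans:
            if sp.end > len(self.text):
                raise ValidationError(
                    f"sentence {self.id!r}: span ({sp.start}, {sp.end}) ends "
                    f"beyond text of length {len(self.text)}"
                )
            if sp.start < prev_end:
                raise ValidationError(
                    f"sentence {self.id!r}: spans overlap or are unsorted "
                    f"at ({sp.start}, {sp.end})"
                )
            if sp.surface is not None and sp.surface != self.text[sp.start : sp.end]:
                raise ValidationError(
                    f"sentence {self.id!r}: cached surface {sp.surface!r} does "
                    f"not equal text slice {self.text[sp.start:sp.end]!r}"
                )
            prev_end = sp.end

    def with_spans(self, spans: Sequence[EntitySpan]) -> "Sentence":
        """Copy of this sentence carrying ``spans`` (sorted, re-validated)."""
        new = replace(self, spans=sorted(spans, key=lambda s: (s.start, s.end)))
        return new

    def surface_of(self, span: EntitySpan) -> str:
        return self.text[span.start : span.end]


@dataclass
class Corpus:
    """Ordered collection of sentences with unique ids."""

    sentences: list[Sentence] = field(default_factory=list)
    split: str = "unsplit"

    _SPLITS = ("train", "dev", "test", "pool", "unsplit")

    def __post_init__(self) -> None:
        if self.split not in self._SPLITS:
            raise ValidationError(f"unknown split {self.split!r}")
        seen: set[str] = set()
        for s in self.sentences:
            if s.id in seen:
                raise ValidationError(f"duplicate sentence id {s.id!r}")
            seen.add(s.id)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]

    def ids(self) -> list[str]:
        return [s.id for s in self.sentences]

    def by_id(self) -> dict[str, Sentence]:
        return {s.id: s for s in self.sentences}


@dataclass(frozen=True)
class TaggedSentence:
    """Tokens with offsets plus one BIO tag per token."""

    sentence: Sentence
    tokens: tuple[Token, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.tokens):
            raise ValidationError(
                f"sentence {self.sentence.id!r}: {len(self.tags)} tags "
                f"for {len(self.tokens)} tokens"
            )


@dataclass(frozen=True)
class CorpusStats:
    n_sentences: int
    n_mentions: int
    pct_with_mentions: float
    pct_full_text: float
    undefined_pct: bool = False
    n_section_defaulted: int = 0


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------
# Word tokens are runs of unicode letters/digits (underscore excluded, the
# infinity sign included so acronyms like "AUC0-∞" survive) optionally glued
# across internal '-', '/', '.', '·'.  Everything else that is not whitespace
# becomes a single-character token.  This keeps PK surface forms such as
# "AUC0-24", "t1/2", "4.2" and "mg·h/L" intact without an external model.
_ALNUM = r"(?:[^\W_]|∞)"
_TOKEN_RE = re.compile(rf"{_ALNUM}+(?:[-/.·]{_ALNUM}+)*|[^\s]", re.UNICODE)


def tokenize(text: str) -> list[Token]:
    """Deterministic regex tokenization with character offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------

def spans_to_bio(
    tokens: Sequence[Token],
    spans: Sequence[EntitySpan],
    policy: str = "snap",
) -> list[str]:
    """Project character spans onto tokens as BIO labels.

    ``policy='strict'`` raises when a span boundary falls strictly inside a
    token; ``policy='snap'`` (default) expands the span to the covering
    tokens and logs a warning when it does so.
    """
    if policy not in ("strict", "snap"):
        raise ValueError(f"unknown policy {policy!r}")
    tags = ["O"] * len(tokens)
    for sp in spans:
        member = [
            i
            for i, t in enumerate(tokens)
            if t.start < sp.end and sp.start < t.end  # any overlap
        ]
        if not member:
            continue
        misaligned = (
            tokens[member[0]].start != sp.start or tokens[member[-1]].end != sp.end
        )
        if misaligned:
            if policy == "strict":
                raise ValidationError(
                    f"span ({sp.start}, {sp.end}) boundary falls inside a token "
                    f"under policy='strict'"
                )
            logger.warning(
                "snapping span (%d, %d) to token boundaries (%d, %d)",
                sp.start,
                sp.end,
                tokens[member[0]].start,
                tokens[member[-1]].end,
            )
        tags[member[0]] = f"B-{sp.label}"
        for i in member[1:]:
            tags[i] = f"I-{sp.label}"
    return tags


_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


def bio_to_spans(tokens: Sequence[Token], tags: Sequence[str]) -> list[EntitySpan]:
    """Decode BIO tags back into character spans.

    Repair rule: an ``I-X`` that does not continue a ``B-X``/``I-X`` run
    (leading, after ``O``, or after a different label) starts a new span,
    i.e. is read as ``B-X``.
    """
    if len(tokens) != len(tags):
        raise ValidationError(f"{len(tags)} tags for {len(tokens)} tokens")
    for tag in tags:
        if not _TAG_RE.match(tag):
            raise ValidationError(f"unknown BIO tag {tag!r}")
    spans: list[EntitySpan] = []
    cur_label: str | None = None
    cur_start = cur_end = 0
    for tok, tag in zip(tokens, tags):
        if tag == "O":
            if cur_label is not None:
                spans.append(EntitySpan(cur_start, cur_end, cur_label))
                cur_label = None
            continue
        prefix, lab = tag.split("-", 1)
        if prefix == "B" or cur_label != lab:
            if cur_label is not None:
                spans.append(EntitySpan(cur_start, cur_end, cur_label))
            cur_label, cur_start = lab, tok.start
        cur_end = tok.end
    if cur_label is not None:
        spans.append(EntitySpan(cur_start, cur_end, cur_label))
    return spans


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sentence_from_record(rec: dict, lineno: int) -> Sentence:
    if "text" not in rec:
        raise CorpusFormatError(f"line {lineno}: record has no 'text' field")
    sid = str(rec.get("id", f"s{lineno}"))
    spans = []
    for raw in rec.get("spans", []):
        try:
            spans.append(
                EntitySpan(
                    start=int(raw["start"]),
                    end=int(raw["end"]),
                    label=str(raw.get("label", DEFAULT_LABEL)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"sentence {sid!r}: {exc}") from None
            raise CorpusFormatError(
                f"line {lineno}: malformed span record {raw!r}"
            ) from None
    spans.sort(key=lambda s: (s.start, s.end))
    section = rec.get("section")
    defaulted = section is None
    try:
        return Sentence(
            id=sid,
            text=rec["text"],
            spans=spans,
            section=section if section is not None else "full_text",
            doc_id=rec.get("doc_id"),
            section_defaulted=defaulted,
        )
    except ValidationError as exc:
        raise ValidationError(str(exc)) from None


def _read_jsonl(path: Path, split: str) -> Corpus:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: not valid JSON ({exc})") from None
            sentences.append(_sentence_from_record(rec, lineno))
    return Corpus(sentences=sentences, split=split)


def _read_conll(path: Path, split: str) -> Corpus:
    """CoNLL dialect: one 'TOKEN<TAB>TAG' per line, blank line between
    sentences, optional '# id = ...' comment.  Offsets are re-derived by
    joining tokens with single spaces (the original offsets are not stored
    in this format)."""
    sentences: list[Sentence] = []
    toks: list[str] = []
    tags: list[str] = []
    sid: str | None = None

    def flush(lineno: int) -> None:
        nonlocal toks, tags, sid
        if not toks:
            sid = None
            return
        text = " ".join(toks)
        tokens = []
        pos = 0
        for t in toks:
            tokens.append(Token(t, pos, pos + len(t)))
            pos += len(t) + 1
        spans = bio_to_spans(tokens, tags)
        sentences.append(
            Sentence(
                id=sid if sid is not None else f"conll-{len(sentences) + 1}",
                text=text,
                spans=spans,
                section_defaulted=True,
            )
        )
        toks, tags, sid = [], [], None

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*id\s*=\s*(\S+)", line)
                if m:
                    sid = m.group(1)
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"line {lineno}: expected 'TOKEN<TAB>TAG', got {line!r}"
                )
            toks.append(parts[0])
            tags.append(parts[1])
        flush(lineno + 1)
    return Corpus(sentences=sentences, split=split)


def read_corpus(path: str | Path, format: str = "jsonl", split: str = "unsplit") -> Corpus:
    """Read a corpus file in the ``jsonl`` or ``conll`` dialect."""
    path = Path(path)
    if format == "jsonl":
        return _read_jsonl(path, split)
    if format == "conll":
        return _read_conll(path, split)
    raise ValueError(f"unknown corpus format {format!r}")


def _sentence_to_record(s: Sentence) -> dict:
    rec: dict = {
        "id": s.id,
        "text": s.text,
        "spans": [{"start": sp.start, "end": sp.end, "label": sp.label} for sp in s.spans],
        "section": s.section,
    }
    if s.doc_id is not None:
        rec["doc_id"] = s.doc_id
    return rec


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus; jsonl round-trips exactly, conll keeps tokens+tags only."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for s in corpus:
                fh.write(json.dumps(_sentence_to_record(s), ensure_ascii=False) + "\n")
    elif format == "conll":
        with open(path, "w", encoding="utf-8") as fh:
            for s in corpus:
                tokens = tokenize(s.text)
                tags = spans_to_bio(tokens, s.spans, policy="snap")
                fh.write(f"# id = {s.id}\n")
                for tok, tag in zip(tokens, tags):
                    fh.write(f"{tok.text}\t{tag}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Sentence/mention counts and percentages (2-decimal convention).

    An empty corpus yields zero counts with ``undefined_pct=True`` rather
    than a division failure.
    """
    n = len(corpus)
    n_mentions = sum(len(s.spans) for s in corpus)
    n_defaulted = sum(1 for s in corpus if s.section_defaulted)
    if n == 0:
        return CorpusStats(0, 0, 0.0, 0.0, undefined_pct=True)
    n_with = sum(1 for s in corpus if s.spans)
    n_ft = sum(1 for s in corpus if s.section == "full_text")
    return CorpusStats(
        n_sentences=n,
        n_mentions=n_mentions,
        pct_with_mentions=round(100.0 * n_with / n, 2),
        pct_full_text=round(100.0 * n_ft / n, 2),
        n_section_defaulted=n_defaulted,
    )
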