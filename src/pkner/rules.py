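"""Declarative rule-based PK matcher.

A :class:`RuleSet` is data — a list of token-pattern rules with optional
lexical-context gates — compiled into a :class:`Matcher` that applies all
rules to a tokenized sentence and resolves overlapping candidates to the
longest match (ties: leftmost, then lowest rule id).  Context gates
replace part-of-speech / dependency constraints with required/forbidden
neighbour terms inside a token window, which is what disambiguates "F"
(bioavailability) from the F statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml
from sklearn.base import BaseEstimator

from .corpus import Corpus, EntitySpan, Sentence, Token, tokenize

__all__ = [
    "PatternRule",
    "RuleSet",
    "Matcher",
    "RuleCompilationError",
    "default_pk_ruleset",
    "compile_rules",
    "match",
    "RuleBasedNER",
]


class RuleCompilationError(ValueError):
    """A ruleset cannot be compiled (bad regex, duplicate/empty rules)."""


_CONSTRAINT_KEYS = ("text", "lower", "lower_in", "regex")


@dataclass(frozen=True)
class TokenConstraint:
    """One token-position constraint; exactly one matching mode is set."""

    text: str | None = None
    lower: str | None = None
    lower_in: tuple[str, ...] | None = None
    regex: str | None = None
    optional: bool = False

    def __post_init__(self) -> None:
        modes = [
            k for k in _CONSTRAINT_KEYS if getattr(self, k) is not None
        ]
        if len(modes) != 1:
            raise RuleCompilationError(
                f"constraint must set exactly one of {_CONSTRAINT_KEYS}, got {modes}"
            )

    def matches(self, token: Token, compiled_re: re.Pattern | None) -> bool:
        if self.text is not None:
            return token.text == self.text
        if self.lower is not None:
            return token.text.lower() == self.lower
        if self.lower_in is not None:
            return token.text.lower() in self.lower_in
        assert compiled_re is not None
        return compiled_re.fullmatch(token.text) is not None


@dataclass(frozen=True)
class ContextGate:
    """Lexical window constraint around a candidate match."""

    require: tuple[str, ...] = ()
    forbid: tuple[str, ...] = ()
    window: int = 5

    def __post_init__(self) -> None:
        if self.window < 0:
            raise RuleCompilationError("context window must be >= 0")

    def admits(self, tokens: Sequence[Token], t_start: int, t_end: int) -> bool:
        lo = max(0, t_start - self.window)
        hi = min(len(tokens), t_end + self.window)
        neigh = {
            tokens[i].text.lower()
            for i in range(lo, hi)
            if not (t_start <= i < t_end)
        }
        if self.forbid and neigh & set(self.forbid):
            return False
        if self.require and not neigh & set(self.require):
            return False
        return True


@dataclass(frozen=True)
class PatternRule:
    id: str
    pattern: tuple[TokenConstraint, ...]
    label: str = "PK"
    context: ContextGate | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise RuleCompilationError(f"rule {self.id!r}: empty pattern")


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[PatternRule, ...]
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RuleCompilationError(f"duplicate rule ids: {sorted(dupes)}")


def _parse_constraint(raw: dict, rule_id: str) -> TokenConstraint:
    raw = dict(raw)
    optional = bool(raw.pop("optional", False))
    if len(raw) != 1 or next(iter(raw)) not in _CONSTRAINT_KEYS:
        raise RuleCompilationError(
            f"rule {rule_id!r}: constraint must have one of {_CONSTRAINT_KEYS}"
        )
    key, value = next(iter(raw.items()))
    if key == "lower_in":
        value = tuple(str(v).lower() for v in value)
    else:
        value = str(value)
    return TokenConstraint(**{key: value}, optional=optional)


def ruleset_from_dict(data: dict) -> RuleSet:
    """Build a RuleSet from the documented YAML/JSON schema."""
    rules = []
    for raw in data.get("rules", []):
        rid = str(raw.get("id", ""))
        if not rid:
            raise RuleCompilationError("rule without an id")
        gate = None
        if raw.get("context"):
            c = raw["context"]
            gate = ContextGate(
                require=tuple(str(t).lower() for t in c.get("require", ())),
                forbid=tuple(str(t).lower() for t in c.get("forbid", ())),
                window=int(c.get("window", 5)),
            )
        rules.append(
            PatternRule(
                id=rid,
                pattern=tuple(
                    _parse_constraint(c, rid) for c in raw.get("pattern", ())
                ),
                label=str(raw.get("label", "PK")),
                context=gate,
            )
        )
    return RuleSet(rules=tuple(rules), version=str(data.get("version", "0")))


def load_ruleset(path) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return ruleset_from_dict(yaml.safe_load(fh))


def default_pk_ruleset() -> RuleSet:
    """The shipped PK ruleset (src/pkner/data/pk_rules.yaml)."""
    text = resources.files("pkner").joinpath("data/pk_rules.yaml").read_text("utf-8")
    return ruleset_from_dict(yaml.safe_load(text))


class Matcher:
    """Compiled ruleset; applies all rules with longest-match resolution."""

    def __init__(self, ruleset: RuleSet):
        self.ruleset = ruleset
        self._compiled: list[tuple[PatternRule, list[tuple[TokenConstraint, ...]], dict]] = []
        for rule in ruleset.rules:
            regexes: dict[int, re.Pattern] = {}
            for i, c in enumerate(rule.pattern):
                if c.regex is not None:
                    try:
                        regexes[i] = re.compile(c.regex)
                    except re.error as exc:
                        raise RuleCompilationError(
                            f"rule {rule.id!r}: invalid regex {c.regex!r} ({exc})"
                        ) from None
            self._compiled.append((rule, _expand_optionals(rule.pattern), regexes))

    def match_tokens(
        self, tokens: Sequence[Token]
    ) -> list[tuple[int, int, PatternRule]]:
        """All candidate matches as (token_start, token_end, rule)."""
        candidates: dict[tuple[int, int, str], PatternRule] = {}
        for rule, variants, regexes in self._compiled:
            for variant, positions in variants:
                vlen = len(variant)
                for start in range(0, len(tokens) - vlen + 1):
                    ok = True
                    for j, c in enumerate(variant):
                        if not c.matches(tokens[start + j], regexes.get(positions[j])):
                            ok = False
                            break
                    if not ok:
                        continue
                    if rule.context and not rule.context.admits(
                        tokens, start, start + vlen
                    ):
                        continue
                    key = (start, start + vlen, rule.label)
                    prev = candidates.get(key)
                    if prev is None or rule.id < prev.id:
                        candidates[key] = rule
        return [(s, e, r) for (s, e, _), r in candidates.items()]

    def match(self, sentence: Sentence) -> list[EntitySpan]:
        """Non-overlapping entity spans for one sentence (deterministic)."""
        tokens = tokenize(sentence.text)
        cands = self.match_tokens(tokens)
        # longest span wins; ties broken leftmost, then lowest rule id
        def sort_key(c: tuple[int, int, PatternRule]):
            s, e, r = c
            length = tokens[e - 1].end - tokens[s].start
            return (-length, tokens[s].start, r.id)

        chosen: list[tuple[int, int, PatternRule]] = []
        for s, e, r in sorted(cands, key=sort_key):
            if all(e <= cs or s >= ce for cs, ce, _ in chosen):
                chosen.append((s, e, r))
        spans = [
            EntitySpan(tokens[s].start, tokens[e - 1].end, r.label)
            for s, e, r in chosen
        ]
        return sorted(spans, key=lambda sp: (sp.start, sp.end))


def _expand_optionals(
    pattern: Sequence[TokenConstraint],
) -> list[tuple[tuple[TokenConstraint, ...], tuple[int, ...]]]:
    """Expand optional positions into concrete variants.

    Returns (variant, original-position-indices) pairs so compiled regexes
    can be found by their position in the source pattern.
    """
    variants: list[tuple[tuple[TokenConstraint, ...], tuple[int, ...]]] = [((), ())]
    for i, c in enumerate(pattern):
        nxt = []
        for v, pos in variants:
            nxt.append((v + (c,), pos + (i,)))
            if c.optional:
                nxt.append((v, pos))
        variants = nxt
    return [(v, p) for v, p in variants if v]


def compile_rules(ruleset: RuleSet) -> Matcher:
    """Compile a ruleset into a matcher (errors name the offending rule)."""
    return Matcher(ruleset)


def match(matcher: Matcher, sentence: Sentence) -> list[EntitySpan]:
    return matcher.match(sentence)


class RuleBasedNER(BaseEstimator):
    """Rule-based PK recognizer with an estimator interface.

    ``fit`` only compiles the ruleset (rules are data, not learned);
    ``predict`` maps sentences to entity-span lists.
    """

    def __init__(self, ruleset: RuleSet | None = None):
        self.ruleset = ruleset

    def fit(self, X=None, y=None) -> "RuleBasedNER":
        rs = self.ruleset if self.ruleset is not None else default_pk_ruleset()
        self.matcher_ = compile_rules(rs)
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "matcher_"):
            self.fit()

    def predict(self, X: Iterable[Sentence]) -> list[list[EntitySpan]]:
        self._ensure_fitted()
        return [self.matcher_.match(s) for s in X]

    def predict_corpus(self, corpus: Corpus) -> Corpus:
        """Corpus whose sentences carry predicted instead of gold spans."""
        self._ensure_fitted()
        return Corpus(
            sentences=[s.with_spans(self.matcher_.match(s)) for s in corpus],
            split=corpus.split,
        )
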