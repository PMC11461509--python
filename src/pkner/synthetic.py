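"""Seeded generator of PK-like sentences with gold entity spans.

The generator emulates the statistical structure of a sentence-level PK
NER corpus: a single entity class ("PK"), a configurable fraction of
sentences containing at least one mention (~16.4% under random sampling
of the PK literature, ~64.25% under selective sampling), long multi-token
spans with complementary modifiers ("total body clearance"), a
context-dependent acronym ("F", which denotes bioavailability only in a
dosing context), and pharmacodynamic distractor terms (AUEC, MTD) that
are *not* PK entities.  Sentences are template-based, so gold character
offsets are exact by construction and generation is deterministic for a
fixed seed.

No pharmacological validity is claimed for the numeric values; they are
cosmetic draws from realistic-looking ranges.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Corpus, EntitySpan, Sentence

__all__ = [
    "SurfaceInventory",
    "GeneratorConfig",
    "ConfigurationError",
    "default_inventory",
    "generate_corpus",
    "make_splits",
]


class ConfigurationError(ValueError):
    """Invalid generator or split configuration."""


@dataclass(frozen=True)
class SurfaceInventory:
    """Inventory of surface forms the generator draws from.

    ``long_forms`` and ``acronyms`` are unambiguous PK mentions;
    ``ambiguous_acronyms`` are forms that are PK entities only in a
    suitable context ("F"); ``distractors`` are pharmacodynamic or
    dosing terms that must never be labelled PK.
    """

    long_forms: tuple[str, ...]
    acronyms: tuple[str, ...]
    ambiguous_acronyms: tuple[str, ...]
    distractors: tuple[str, ...]
    # heads whose modifier prefix can be swapped for a "novel" one
    modifiable_heads: tuple[str, ...] = ()
    novel_modifiers: tuple[str, ...] = ()
    # head -> (modifier vocabulary, max modifiers per mention); bare-head
    # mentions compose fresh combinations from these, so span variety is
    # combinatorial rather than a fixed list
    covered_modifiers: dict[str, tuple[tuple[str, ...], int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        pk = set(self.long_forms) | set(self.acronyms) | set(self.ambiguous_acronyms)
        bad = pk & set(self.distractors)
        if bad:
            raise ConfigurationError(f"distractors overlap PK forms: {sorted(bad)}")

    def all_pk_forms(self) -> tuple[str, ...]:
        return self.long_forms + self.acronyms + self.ambiguous_acronyms


def default_inventory() -> SurfaceInventory:
    """The shipped surface-form inventory (42 PK forms, 7 distractors)."""
    return SurfaceInventory(
        long_forms=(
            "clearance",
            "total body clearance",
            "apparent oral clearance",
            "plasma clearance",
            "volume of distribution",
            "apparent volume of distribution",
            "steady-state volume of distribution",
            "half-life",
            "elimination half-life",
            "terminal half-life",
            "terminal elimination half-life",
            "bioavailability",
            "absolute bioavailability",
            "oral bioavailability",
            "area under the concentration-time curve",
            "area under the curve",
            "elimination rate constant",
            "absorption rate constant",
            "peak plasma concentration",
            "maximum plasma concentration",
            # long-tail parameters deliberately outside the shipped rule
            # lexicon: they stress recall of lexicon-based matching
            "mean residence time",
            "accumulation ratio",
            "lag time",
            "fraction unbound",
            "volume of the central compartment",
            "time to peak concentration",
        ),
        acronyms=(
            "CL",
            "CL/F",
            "AUC",
            "AUC0-24",
            "AUC0-t",
            "AUC0-∞",
            "Cmax",
            "Tmax",
            "t1/2",
            "Vd",
            "Vss",
            "ka",
            "ke",
            "kel",
            "MRT",
        ),
        ambiguous_acronyms=("F",),
        distractors=(
            "AUEC",
            "MTD",
            "Emax",
            "EC50",
            "IC50",
            "maximum tolerated dose",
            "area under the effect curve",
        ),
        modifiable_heads=(
            "clearance",
            "half-life",
            "bioavailability",
            "volume of distribution",
        ),
        novel_modifiers=(
            "renal",
            "hepatic",
            "systemic",
            "intrinsic",
            "unbound",
            "intercompartmental",
            "biliary",
        ),
        covered_modifiers={
            "clearance": (("total", "body", "apparent", "oral", "plasma"), 2),
            "half-life": (("terminal", "elimination", "absorption"), 2),
            "bioavailability": (("absolute", "oral"), 1),
            "volume of distribution": (("apparent", "steady-state"), 1),
        },
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic corpus generation.

    ``prevalence`` defaults to 0.164, the fraction of sentences with a PK
    mention under random sampling of PK articles; the selectively sampled
    training regime corresponds to 0.6425.  ``pct_full_text`` defaults to
    0.508 (the randomly sampled evaluation regime).  ``ambiguity_rate``
    is the chance an entity sentence uses the context-dependent acronym
    "F" (and, symmetrically, the chance a filler sentence contains "F" in
    a non-PK context).  ``distractor_rate`` is the chance a non-entity
    sentence carries a pharmacodynamic distractor term.
    ``novel_modifier_rate`` is the chance a modifiable long-form mention
    swaps its modifier prefix for one outside the shipped rule lexicon
    ("renal clearance"), the mechanism that degrades lexicon recall while
    leaving learned taggers unaffected.
    """

    n_sentences: int = 1000
    prevalence: float = 0.164
    ambiguity_rate: float = 0.2
    distractor_rate: float = 0.3
    novel_modifier_rate: float = 0.15
    pct_full_text: float = 0.508
    seed: int = 0
    vocabulary: SurfaceInventory = field(default_factory=default_inventory)

    def __post_init__(self) -> None:
        if self.n_sentences < 0:
            raise ConfigurationError("n_sentences must be >= 0")
        for name in (
            "prevalence",
            "ambiguity_rate",
            "distractor_rate",
            "novel_modifier_rate",
            "pct_full_text",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not self.vocabulary.all_pk_forms():
            raise ConfigurationError("vocabulary has no PK surface forms")


_DRUGS = (
    "midazolam",
    "caffeine",
    "metformin",
    "warfarin",
    "rifampicin",
    "digoxin",
    "ibuprofen",
    "artesunate",
    "tacrolimus",
    "amoxicillin",
)
_UNITS = ("L/h", "mL/min", "mg·h/L", "ng/mL", "h", "L", "1/h")
_POPULATIONS = (
    "healthy volunteers",
    "paediatric patients",
    "elderly subjects",
    "patients with renal impairment",
    "the fasted group",
)

_FILLERS = (
    "Blood samples were collected at predefined time points over {n} hours.",
    "Patients received {drug} twice daily for {n} days.",
    "A total of {n} healthy volunteers completed the study.",
    "Concentrations were quantified with a validated LC-MS/MS assay.",
    "Model parameters were estimated using nonlinear mixed-effects modelling.",
    "The study protocol was approved by the local ethics committee.",
    "Demographic covariates were summarised for each treatment arm.",
)

_F_FILLERS = (
    "The F statistic for the between-group comparison was {val}.",
    "Group F received the reference treatment in period two.",
)

_DISTRACTOR_TEMPLATES = (
    "The {dis} of {drug} was {val} {unit}.",
    "Dose escalation continued until the {dis} was reached.",
    "The {dis} did not differ significantly between treatment arms.",
)


class _SentenceBuilder:
    """Accumulates text fragments, recording spans for entity insertions."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0
        self.spans: list[EntitySpan] = []

    def lit(self, s: str) -> None:
        self._parts.append(s)
        self._len += len(s)

    def ent(self, surface: str, label: str = "PK") -> None:
        self.spans.append(EntitySpan(self._len, self._len + len(surface), label))
        self.lit(surface)

    def text(self) -> str:
        return "".join(self._parts)


def _pick_pk_surface(rng: random.Random, cfg: GeneratorConfig) -> str:
    inv = cfg.vocabulary
    pool = inv.long_forms + inv.acronyms
    form = rng.choice(pool)
    head = next(
        (h for h in inv.modifiable_heads if form == h or form.endswith(" " + h)),
        None,
    )
    if head is None:
        return form
    if inv.novel_modifiers and rng.random() < cfg.novel_modifier_rate:
        return rng.choice(inv.novel_modifiers) + " " + head
    if form == head and head in inv.covered_modifiers and rng.random() < 0.5:
        mods, max_n = inv.covered_modifiers[head]
        k = rng.randint(1, min(max_n, len(mods)))
        return " ".join(rng.sample(mods, k)) + " " + head
    return form


def _val(rng: random.Random) -> str:
    return f"{rng.uniform(0.1, 120.0):.1f}"


def _entity_sentence(rng: random.Random, cfg: GeneratorConfig) -> _SentenceBuilder:
    b = _SentenceBuilder()
    if cfg.vocabulary.ambiguous_acronyms and rng.random() < cfg.ambiguity_rate:
        drug = rng.choice(_DRUGS)
        if rng.random() < 0.5:
            b.lit("The ")
            b.ent("absolute bioavailability")
            b.lit(" (")
            b.ent("F")
            b.lit(f") of {drug} was {_val(rng)}%.")
        else:
            b.lit("Oral ")
            b.ent("F")
            b.lit(f" of {drug} was estimated at {_val(rng)}%.")
        return b
    n_ents = rng.choices((1, 2, 3), weights=(0.6, 0.3, 0.1))[0]
    surfaces = [_pick_pk_surface(rng, cfg) for _ in range(n_ents)]
    drug = rng.choice(_DRUGS)
    vals = [f"{_val(rng)} {rng.choice(_UNITS)}" for _ in range(n_ents)]
    if n_ents == 1:
        variant = rng.randrange(3)
        if variant == 0:
            b.lit("The ")
            b.ent(surfaces[0])
            b.lit(f" of {drug} was {vals[0]} in {rng.choice(_POPULATIONS)}.")
        elif variant == 1:
            b.lit(f"{drug} exhibited a ")
            b.ent(surfaces[0])
            b.lit(f" of {vals[0]}.")
        else:
            b.lit("Following a single dose, the ")
            b.ent(surfaces[0])
            b.lit(f" of {drug} reached {vals[0]}.")
    elif n_ents == 2:
        b.lit("The ")
        b.ent(surfaces[0])
        b.lit(" and ")
        b.ent(surfaces[1])
        b.lit(f" of {drug} were {vals[0]} and {vals[1]}, respectively.")
    else:
        b.lit("The ")
        b.ent(surfaces[0])
        b.lit(", ")
        b.ent(surfaces[1])
        b.lit(" and ")
        b.ent(surfaces[2])
        b.lit(f" of {drug} were {vals[0]}, {vals[1]} and {vals[2]}, respectively.")
    return b


def _non_entity_sentence(rng: random.Random, cfg: GeneratorConfig) -> _SentenceBuilder:
    b = _SentenceBuilder()
    if cfg.vocabulary.distractors and rng.random() < cfg.distractor_rate:
        tpl = rng.choice(_DISTRACTOR_TEMPLATES)
        b.lit(
            tpl.format(
                dis=rng.choice(cfg.vocabulary.distractors),
                drug=rng.choice(_DRUGS),
                val=_val(rng),
                unit=rng.choice(_UNITS),
            )
        )
    elif cfg.vocabulary.ambiguous_acronyms and rng.random() < cfg.ambiguity_rate:
        b.lit(rng.choice(_F_FILLERS).format(val=_val(rng)))
    else:
        b.lit(
            rng.choice(_FILLERS).format(
                drug=rng.choice(_DRUGS), n=rng.randrange(3, 49)
            )
        )
    return b


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a seeded synthetic corpus under ``config``.

    Deterministic: the same config (including seed) yields a byte-identical
    corpus.  Gold spans exactly cover the inserted PK surface forms; the
    realized prevalence is binomial around ``config.prevalence``.
    """
    rng = random.Random(config.seed)
    sentences = []
    for i in range(config.n_sentences):
        has_entity = rng.random() < config.prevalence
        b = (
            _entity_sentence(rng, config)
            if has_entity
            else _non_entity_sentence(rng, config)
        )
        section = "full_text" if rng.random() < config.pct_full_text else "abstract"
        sentences.append(
            Sentence(
                id=f"syn{config.seed}-{i:06d}",
                text=b.text(),
                spans=b.spans,
                section=section,
            )
        )
    return Corpus(sentences=sentences, split="unsplit")


def make_splits(
    corpus: Corpus,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[Corpus, Corpus, Corpus]:
    """Seed-reproducible disjoint, exhaustive train/dev/test partition."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions {fractions} do not sum to 1")
    n = len(corpus)
    idx = list(range(n))
    random.Random(seed).shuffle(idx)
    b1 = round(n * fractions[0])
    b2 = round(n * (fractions[0] + fractions[1]))
    parts = (sorted(idx[:b1]), sorted(idx[b1:b2]), sorted(idx[b2:]))
    names = ("train", "dev", "test")
    return tuple(
        Corpus(sentences=[corpus[i] for i in part], split=name)
        for part, name in zip(parts, names)
    )
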