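"""Model-in-the-loop active-learning simulation.

Emulates the two-stage annotation protocol used to build selectively
sampled NER training sets: a heuristic bootstrap (rule-matched sentences
corrected by an annotator), then an uncertainty-driven loop in which the
tagger proposes spans, a simulated annotator accepts/rejects them and
supplies the corrected gold annotation, and the model is retrained after
every ``update_every`` (default 10) newly labelled sentences.  The
simulated annotator is backed by the hidden gold spans of the synthetic
pool, so the whole protocol runs without humans and is reproducible from
its seeds.

``compare_al_vs_random`` is the machine twin of the AL-vs-random
experiment: per replicate, an uncertainty arm and a random-sampling arm
each label the same number of pool sentences, a fresh tagger is trained
on each arm's labelled set, and both are scored on a held-out synthetic
test set with strict and partial matching.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, EntitySpan, Sentence, corpus_stats
from .rules import RuleBasedNER
from .synthetic import ConfigurationError, GeneratorConfig, generate_corpus
from .tagger import LinearBIOTagger

__all__ = [
    "ALConfig",
    "ALState",
    "ALExperimentConfig",
    "ALComparison",
    "AnnotationOutcome",
    "simulated_annotator",
    "heuristic_bootstrap",
    "run_al",
    "compare_al_vs_random",
]


@dataclass(frozen=True)
class AnnotationOutcome:
    """Bookkeeping for one simulated annotation round."""

    n_proposed: int
    n_accepted: int
    n_rejected: int
    n_boundary_corrections: int
    n_added: int


def simulated_annotator(
    pool_sentence: Sentence, proposed: Sequence[EntitySpan]
) -> tuple[Sentence, AnnotationOutcome]:
    """Two-phase annotator emulation backed by hidden gold.

    Phase 1 gives each proposed span a binary accept/reject by exact gold
    match (boundaries and label).  Phase 2 models the human correction
    round: the final annotation is the full gold span set, so missing
    spans are added and rejected proposals that overlap a gold span are
    logged as boundary corrections.
    """
    gold = {(sp.start, sp.end, sp.label) for sp in pool_sentence.spans}
    accepted = [p for p in proposed if (p.start, p.end, p.label) in gold]
    rejected = [p for p in proposed if (p.start, p.end, p.label) not in gold]
    boundary = sum(
        1
        for p in rejected
        if any(p.start < g.end and g.start < p.end for g in pool_sentence.spans)
    )
    added = len(pool_sentence.spans) - len(accepted)
    outcome = AnnotationOutcome(
        n_proposed=len(proposed),
        n_accepted=len(accepted),
        n_rejected=len(rejected),
        n_boundary_corrections=boundary,
        n_added=added,
    )
    return pool_sentence.with_spans(pool_sentence.spans), outcome


@dataclass(frozen=True)
class ALConfig:
    """Loop configuration.

    ``candidate_pool_size`` ranks a seeded random subset of the remaining
    pool at each update (pool subsampling, standard practice to keep the
    scoring cost proportional to the batch rather than the pool).
    ``train_epochs`` is the in-loop retraining schedule; retraining is a
    full retrain from scratch for determinism.  ``eval_every`` controls
    how often (in updates) the history records dev strict F1 (0 = never).
    """

    budget: int = 500
    update_every: int = 10
    selection: str = "uncertainty"
    seed: int = 0
    initial_set: Corpus | None = None
    train_epochs: int = 5
    candidate_pool_size: int = 500
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.update_every < 1:
            raise ConfigurationError("update_every must be >= 1")
        if self.budget < self.update_every:
            raise ConfigurationError("budget must be >= update_every")
        if self.selection not in ("uncertainty", "random"):
            raise ConfigurationError(f"unknown selection {self.selection!r}")


@dataclass
class ALState:
    labelled: Corpus
    pool: Corpus
    model: LinearBIOTagger | None
    history: list[tuple[int, int, int, float]]  # step, pool, labelled, dev F1
    annotation: AnnotationOutcome


def _sum_outcomes(a: AnnotationOutcome, b: AnnotationOutcome) -> AnnotationOutcome:
    return AnnotationOutcome(
        a.n_proposed + b.n_proposed,
        a.n_accepted + b.n_accepted,
        a.n_rejected + b.n_rejected,
        a.n_boundary_corrections + b.n_boundary_corrections,
        a.n_added + b.n_added,
    )


def heuristic_bootstrap(
    pool: Corpus, n: int, seed: int = 0
) -> Corpus:
    """Rule-matched pool sentences, annotator-corrected, as an initial set.

    Mirrors the heuristic-labelling stage: apply the shipped ruleset to
    the pool, randomly choose ``n`` sentences that contain at least one
    rule match, and pass them through the simulated annotator so they
    carry corrected (gold) spans.
    """
    ner = RuleBasedNER().fit()
    matched = [s for s in pool if ner.matcher_.match(s)]
    if len(matched) < n:
        n = len(matched)
    chosen = random.Random(seed).sample(matched, n)
    chosen.sort(key=lambda s: s.id)
    corrected = [
        simulated_annotator(s, ner.matcher_.match(s))[0] for s in chosen
    ]
    return Corpus(sentences=corrected, split="train")


def _train_tagger(
    labelled: Sequence[Sentence],
    epochs: int,
    seed: int,
    feature_cache: dict | None,
) -> LinearBIOTagger:
    import warnings as _w

    model = LinearBIOTagger(epochs=epochs, seed=seed, feature_cache=feature_cache)
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # all-O batches early in the loop are expected
        model.fit(list(labelled))
    return model


def run_al(
    pool: Corpus,
    dev: Corpus | None,
    config: ALConfig,
    feature_cache: dict | None = None,
) -> ALState:
    """Run one labelling campaign to ``config.budget`` sentences.

    The loop ranks the pool by model uncertainty (or samples randomly),
    takes ``update_every`` sentences, annotates them via the simulated
    annotator and retrains the model from scratch on the labelled set.
    Fully reproducible from the config seed.
    """
    if config.budget > len(pool) + (
        len(config.initial_set) if config.initial_set else 0
    ):
        raise ConfigurationError(
            f"budget {config.budget} exceeds pool size {len(pool)}"
        )
    rng = random.Random(config.seed)
    if feature_cache is None:
        feature_cache = {}

    labelled: list[Sentence] = []
    pool_by_id = pool.by_id()
    if config.initial_set is not None:
        for s in config.initial_set:
            labelled.append(s)
            pool_by_id.pop(s.id, None)
        if len(labelled) > config.budget:
            raise ConfigurationError("initial_set larger than budget")
    remaining = [pool_by_id[k] for k in sorted(pool_by_id)]

    model: LinearBIOTagger | None = None
    if labelled:
        model = _train_tagger(labelled, config.train_epochs, config.seed, feature_cache)

    history: list[tuple[int, int, int, float]] = []
    outcome = AnnotationOutcome(0, 0, 0, 0, 0)
    step = 0
    while len(labelled) < config.budget:
        k = min(config.update_every, config.budget - len(labelled))
        if config.selection == "random" or model is None:
            batch = rng.sample(remaining, k)
        else:
            # The interface being emulated presents candidate *spans*:
            # sentences where the model proposes an entity are annotated
            # first (this is what concentrates entity mentions in the
            # labelled set), ranked by margin uncertainty within each
            # group.  Sentences without proposals queue behind them.
            m = min(config.candidate_pool_size, len(remaining))
            candidates = rng.sample(remaining, m)
            ranked = []
            for s in candidates:
                spans, u = model.propose(s)
                ranked.append((0 if spans else 1, -u, s.id, s))
            ranked.sort(key=lambda r: r[:3])
            batch = [r[3] for r in ranked[:k]]
        batch_ids = {s.id for s in batch}
        remaining = [s for s in remaining if s.id not in batch_ids]
        for s in batch:
            proposals = model.predict_sentence(s) if model is not None else []
            corrected, out = simulated_annotator(s, proposals)
            labelled.append(corrected)
            outcome = _sum_outcomes(outcome, out)
        model = _train_tagger(labelled, config.train_epochs, config.seed, feature_cache)
        step += 1
        dev_f1 = float("nan")
        if dev is not None and len(dev) and config.eval_every and step % config.eval_every == 0:
            dev_f1 = model._dev_f1(list(dev), model.weights_)
        history.append((step, len(remaining), len(labelled), dev_f1))

    return ALState(
        labelled=Corpus(sentences=labelled, split="train"),
        pool=Corpus(sentences=remaining, split="pool"),
        model=model,
        history=history,
        annotation=outcome,
    )


@dataclass(frozen=True)
class ALExperimentConfig:
    """Replicated AL-vs-random comparison.

    Per run: build a fresh pool, label ``n_labelled`` sentences per arm,
    train a fresh tagger on each arm's labelled set for ``train_epochs``
    epochs and score it on a shared held-out synthetic test set.
    """

    n_labelled: int = 500
    runs: int = 10
    seeds: tuple[int, ...] | None = None
    train_epochs: int = 5
    update_every: int = 10
    bootstrap_size: int = 50
    test_size: int = 1000
    candidate_pool_size: int = 500

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ConfigurationError("runs must be >= 1")
        if self.seeds is not None:
            if len(self.seeds) != self.runs:
                raise ConfigurationError("need one seed per run")
            if len(set(self.seeds)) != len(self.seeds):
                raise ConfigurationError("seeds must be distinct")

    def run_seeds(self) -> tuple[int, ...]:
        return self.seeds if self.seeds is not None else tuple(range(1, self.runs + 1))


@dataclass
class ALComparison:
    table: pd.DataFrame  # one row per (run, arm, scheme)
    medians: pd.DataFrame  # median P/R/F1 per (arm, scheme)

    def median_strict_f1(self, arm: str) -> float:
        return float(self.medians.loc[(arm, "strict"), "f1"])


def _derive(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k * 7919) % (2**31 - 1)


def compare_al_vs_random(
    generator_config: GeneratorConfig,
    experiment: ALExperimentConfig,
) -> ALComparison:
    """Paired uncertainty-vs-random experiment on synthetic pools."""
    from .evaluation import evaluate_corpus

    test = generate_corpus(
        replace(
            generator_config,
            n_sentences=experiment.test_size,
            seed=_derive(generator_config.seed, 997),
        )
    )
    rows = []
    for run, rseed in enumerate(experiment.run_seeds()):
        cache: dict = {}
        pool = generate_corpus(
            replace(generator_config, seed=_derive(rseed, 1))
        )
        arms: dict[str, Corpus] = {}
        for arm in ("active_learning", "random"):
            if arm == "active_learning":
                init = heuristic_bootstrap(
                    pool, experiment.bootstrap_size, seed=_derive(rseed, 2)
                )
                cfg = ALConfig(
                    budget=experiment.n_labelled,
                    update_every=experiment.update_every,
                    selection="uncertainty",
                    seed=_derive(rseed, 3),
                    initial_set=init,
                    train_epochs=experiment.train_epochs,
                    candidate_pool_size=experiment.candidate_pool_size,
                    eval_every=0,
                )
            else:
                cfg = ALConfig(
                    budget=experiment.n_labelled,
                    update_every=experiment.n_labelled,  # one-shot sampling
                    selection="random",
                    seed=_derive(rseed, 4),
                    train_epochs=experiment.train_epochs,
                    eval_every=0,
                )
            state = run_al(pool, None, cfg, feature_cache=cache)
            arms[arm] = state.labelled

            final = LinearBIOTagger(
                epochs=experiment.train_epochs,
                seed=_derive(rseed, 5),
                feature_cache=cache,
            ).fit(list(state.labelled))
            report = evaluate_corpus(test, final.predict_corpus(test))
            prevalence = corpus_stats(state.labelled).pct_with_mentions
            for scheme in ("strict", "partial"):
                sc = getattr(report, scheme)
                rows.append(
                    {
                        "run": run,
                        "seed": rseed,
                        "arm": arm,
                        "scheme": scheme,
                        "precision": sc.precision,
                        "recall": sc.recall,
                        "f1": sc.f1,
                        "labelled_prevalence_pct": prevalence,
                    }
                )
        cache.clear()
    table = pd.DataFrame(rows)
    medians = table.groupby(["arm", "scheme"])[["precision", "recall", "f1"]].median()
    return ALComparison(table=table, medians=medians)
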