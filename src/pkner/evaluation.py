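"""Entity-level strict/partial evaluation and inter-annotator agreement.

Alignment follows the MUC/SemEval-style categories: COR (exact boundaries
and label), INC (exact boundaries, wrong label), PAR (partial character
overlap), MIS (gold left unmatched), SPU (prediction left unmatched).
From the tallies:

    strict   P = COR / (COR + INC + PAR + SPU)
    strict   R = COR / (COR + INC + PAR + MIS)
    partial  P = (COR + 0.5 PAR) / (COR + INC + PAR + SPU)
    partial  R = (COR + 0.5 PAR) / (COR + INC + PAR + MIS)

so partial matching gives half credit to overlapping-but-inexact
predictions and partial F1 always dominates strict F1.  Scores are
reported as percentages (0-100, two decimals); zero denominators yield
flagged zeros rather than failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, EntitySpan, ValidationError

__all__ = [
    "MatchCounts",
    "Scores",
    "EvalReport",
    "IAAMatrix",
    "align_spans",
    "score",
    "evaluate_corpus",
    "pairwise_iaa",
]


@dataclass(frozen=True)
class MatchCounts:
    COR: int = 0
    INC: int = 0
    PAR: int = 0
    MIS: int = 0
    SPU: int = 0

    def __post_init__(self) -> None:
        if min(self.COR, self.INC, self.PAR, self.MIS, self.SPU) < 0:
            raise ValidationError("negative match counts")

    @property
    def n_gold(self) -> int:
        return self.COR + self.INC + self.PAR + self.MIS

    @property
    def n_pred(self) -> int:
        return self.COR + self.INC + self.PAR + self.SPU

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.COR + other.COR,
            self.INC + other.INC,
            self.PAR + other.PAR,
            self.MIS + other.MIS,
            self.SPU + other.SPU,
        )


@dataclass(frozen=True)
class Scores:
    precision: float
    recall: float
    f1: float
    empty_input: bool = False


@dataclass(frozen=True)
class EvalReport:
    strict: Scores
    partial: Scores
    counts: MatchCounts
    n_sentences: int

    def to_dict(self) -> dict:
        return {
            "n_sentences": self.n_sentences,
            "counts": {
                "COR": self.counts.COR,
                "INC": self.counts.INC,
                "PAR": self.counts.PAR,
                "MIS": self.counts.MIS,
                "SPU": self.counts.SPU,
            },
            "strict": {
                "precision": self.strict.precision,
                "recall": self.strict.recall,
                "f1": self.strict.f1,
            },
            "partial": {
                "precision": self.partial.precision,
                "recall": self.partial.recall,
                "f1": self.partial.f1,
            },
        }


def _check_disjoint_sorted(spans: list[EntitySpan], side: str) -> None:
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"{side} spans overlap or are unsorted at ({b.start}, {b.end})"
            )


def align_spans(
    gold: list[EntitySpan], pred: list[EntitySpan]
) -> MatchCounts:
    """Greedy in-order alignment, exact matches claimed before partial.

    Each gold span is matched to at most one prediction and vice versa.
    Both lists must be sorted and internally non-overlapping (the span
    invariant), which makes the greedy left-to-right pass on the overlap
    graph a maximum matching.
    """
    gold = sorted(gold, key=lambda s: (s.start, s.end))
    pred = sorted(pred, key=lambda s: (s.start, s.end))
    _check_disjoint_sorted(gold, "gold")
    _check_disjoint_sorted(pred, "pred")

    used_pred: set[int] = set()
    cor = inc = par = 0
    matched_gold: set[int] = set()
    # pass 1: exact boundary matches
    pred_by_bounds = {(p.start, p.end): j for j, p in enumerate(pred)}
    for i, g in enumerate(gold):
        j = pred_by_bounds.get((g.start, g.end))
        if j is not None and j not in used_pred:
            used_pred.add(j)
            matched_gold.add(i)
            if pred[j].label == g.label:
                cor += 1
            else:
                inc += 1
    # pass 2: partial overlaps, in span order
    for i, g in enumerate(gold):
        if i in matched_gold:
            continue
        for j, p in enumerate(pred):
            if j in used_pred:
                continue
            if p.start < g.end and g.start < p.end:
                used_pred.add(j)
                matched_gold.add(i)
                par += 1
                break
    mis = len(gold) - len(matched_gold)
    spu = len(pred) - len(used_pred)
    return MatchCounts(COR=cor, INC=inc, PAR=par, MIS=mis, SPU=spu)


def score(counts: MatchCounts, scheme: str = "strict") -> Scores:
    """Precision/recall/F1 (percentages, 2 decimals) for one scheme."""
    if scheme not in ("strict", "partial"):
        raise ValueError(f"unknown scheme {scheme!r}")
    num = counts.COR + (0.5 * counts.PAR if scheme == "partial" else 0.0)
    denom_p = counts.n_pred
    denom_r = counts.n_gold
    empty = denom_p == 0 or denom_r == 0
    p = num / denom_p if denom_p else 0.0
    r = num / denom_r if denom_r else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return Scores(
        precision=round(100 * p, 2),
        recall=round(100 * r, 2),
        f1=round(100 * f1, 2),
        empty_input=empty,
    )


def evaluate_corpus(gold: Corpus, pred: Corpus) -> EvalReport:
    """Micro-averaged entity-level evaluation over matching sentence ids."""
    gold_by_id = gold.by_id()
    pred_by_id = pred.by_id()
    missing = sorted(set(gold_by_id) ^ set(pred_by_id))
    if missing:
        raise ValidationError(
            f"gold/pred sentence ids differ; unmatched ids: {missing[:10]}"
        )
    total = MatchCounts()
    for sid, g in gold_by_id.items():
        total = total + align_spans(g.spans, pred_by_id[sid].spans)
    return EvalReport(
        strict=score(total, "strict"),
        partial=score(total, "partial"),
        counts=total,
        n_sentences=len(gold),
    )


@dataclass(frozen=True)
class IAAMatrix:
    annotators: tuple[str, ...]
    f1: np.ndarray  # pairwise strict F1, diagonal 100
    mean_pairwise_f1: float

    def to_dict(self) -> dict:
        return {
            "annotators": list(self.annotators),
            "pairwise_f1": self.f1.tolist(),
            "mean_pairwise_f1": self.mean_pairwise_f1,
        }


def pairwise_iaa(annotations: dict[str, Corpus]) -> IAAMatrix:
    """Pairwise strict F1 between annotators over identical sentences.

    Entry (a, b) treats a's spans as gold and b's as the prediction;
    swapping gold and prediction exchanges precision and recall, so the
    matrix is symmetric.  The mean excludes the diagonal.
    """
    if len(annotations) < 2:
        raise ValidationError("need at least 2 annotators")
    names = tuple(sorted(annotations))
    id_sets = {a: set(annotations[a].by_id()) for a in names}
    ref = id_sets[names[0]]
    for a in names[1:]:
        if id_sets[a] != ref:
            raise ValidationError(
                f"annotator {a!r} covers a different sentence set"
            )
    k = len(names)
    mat = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            rep = evaluate_corpus(annotations[names[i]], annotations[names[j]])
            mat[i, j] = mat[j, i] = rep.strict.f1
    off = mat[~np.eye(k, dtype=bool)]
    return IAAMatrix(
        annotators=names,
        f1=mat,
        mean_pairwise_f1=round(float(off.mean()), 2),
    )
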