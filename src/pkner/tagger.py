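"""Trainable BIO sequence tagger.

The reference backend is a linear per-token classifier trained with
averaged structured-perceptron updates over hashed sparse features
(window of neighbouring word identities, word shape, prefixes/suffixes,
digit flags and a PK-lexicon flag), decoded greedily under BIO
transition constraints (no ``I-X`` after ``O`` or after a different
label).  It is CPU-only, trains in seconds at desk scale, and is fully
deterministic for a fixed seed.

A transformer encoder is *not* bundled; instead :class:`EncoderRecipe`
records the fine-tuning configuration a token-classification encoder
should use (20 epochs, batch 16, learning rate 3e-5, weight decay 0.05,
dropout 0.1, maximum sequence length 256, dev-set model selection on
entity-level strict F1, first-subword labelling with continuation pieces
masked from the loss), and :class:`TokenScorer` is the plug-in contract:
anything that maps a token sequence to a per-token label-score matrix
can replace the linear scorer without touching any other module.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.feature_extraction import FeatureHasher

from .corpus import (
    Corpus,
    EntitySpan,
    Sentence,
    Token,
    bio_to_spans,
    spans_to_bio,
    tokenize,
)
from .evaluation import MatchCounts, align_spans, score
from .synthetic import default_inventory

__all__ = [
    "TrainConfig",
    "EncoderRecipe",
    "TokenScorer",
    "LinearBIOTagger",
    "ModelIOError",
    "train",
    "predict",
    "uncertainty",
    "margin_uncertainty",
]

MODEL_FORMAT = "pkner-linear-tagger-v1"


class ModelIOError(IOError):
    """Model archive is missing, truncated, or of an incompatible version."""


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration shared by both backends.

    ``learning_rate``, ``batch_size``, ``weight_decay`` and ``dropout``
    parameterize the encoder backend's optimizer; the linear
    (perceptron) backend has no step size and ignores them.  Model
    selection uses entity-level strict F1 on the development set.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 3e-5
    weight_decay: float = 0.05
    dropout: float = 0.1
    max_sequence_length: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_sequence_length < 8:
            raise ValueError("max_sequence_length must be >= 8")


@dataclass(frozen=True)
class EncoderRecipe(TrainConfig):
    """Fine-tuning recipe for a drop-in transformer token classifier.

    The stated "linear weight decay of 0.05" plausibly conflates a linear
    learning-rate schedule with weight decay, so both knobs are exposed
    rather than guessing intent.
    """

    linear_lr_schedule: bool = True
    subword_strategy: str = "first-piece-labelled; continuation pieces masked from loss"
    head: str = "fully-connected + softmax over BIO labels"


class TokenScorer(Protocol):
    """Contract for pluggable encoders: tokens -> (n_tokens, n_labels) scores."""

    def score_tokens(self, tokens: Sequence[str]) -> np.ndarray: ...


def margin_uncertainty(probs: np.ndarray) -> float:
    """1 minus the mean top-two margin of per-token label distributions.

    One-hot rows give margin 1 (uncertainty 0); uniform rows give margin
    0 (uncertainty 1).  An empty matrix scores 0 (nothing to be uncertain
    about, and empty sentences should not win an uncertainty ranking).
    """
    if probs.size == 0:
        return 0.0
    if probs.shape[1] == 1:
        return 0.0
    part = np.sort(probs, axis=1)
    margins = part[:, -1] - part[:, -2]
    return float(np.clip(1.0 - margins.mean(), 0.0, 1.0))


def _shape(text: str) -> str:
    out = []
    for ch in text[:12]:
        if ch.isdigit():
            out.append("9")
        elif ch.isalpha():
            out.append("X" if ch.isupper() else "x")
        else:
            out.append(ch)
    return "".join(out)


class LinearBIOTagger(BaseEstimator):
    """Averaged-perceptron BIO tagger with transition-constrained decoding.

    Parameters mirror :class:`TrainConfig`; ``window`` is the neighbour
    feature offset range (default ±3: wide enough to separate long-form
    mentions from PD look-alikes such as 'area under the effect curve') and ``lexicon`` an optional frozenset of
    lowercase tokens flagged as PK-lexicon members (defaults to the
    tokens of the shipped surface-form inventory).  ``feature_cache`` may
    be a dict shared between instances to avoid re-hashing sentences in
    simulation loops.

    Fitted attributes: ``labels_``, ``weights_`` (n_features x n_labels),
    ``dev_history_`` (per-epoch dev strict F1), ``best_epoch_``,
    ``provenance_``.
    """

    def __init__(
        self,
        epochs: int = 20,
        batch_size: int = 16,
        learning_rate: float = 3e-5,
        weight_decay: float = 0.05,
        dropout: float = 0.1,
        max_sequence_length: int = 256,
        seed: int = 0,
        window: int = 3,
        n_hash_features: int = 2**18,
        lexicon: frozenset[str] | None = None,
        feature_cache: dict | None = None,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.max_sequence_length = max_sequence_length
        self.seed = seed
        self.window = window
        self.n_hash_features = n_hash_features
        self.lexicon = lexicon
        self.feature_cache = feature_cache

    # ------------------------------------------------------------------
    # features
    # ------------------------------------------------------------------
    def _lexicon(self) -> frozenset[str]:
        if self.lexicon is not None:
            return self.lexicon
        if not hasattr(self, "_default_lexicon"):
            inv = default_inventory()
            toks: set[str] = set()
            for form in inv.all_pk_forms():
                toks.update(t.text.lower() for t in tokenize(form))
            self._default_lexicon = frozenset(toks)
        return self._default_lexicon

    def _token_features(self, tokens: Sequence[Token]) -> list[list[str]]:
        lex = self._lexicon()
        lowers = [t.text.lower() for t in tokens]
        feats = []
        for i, tok in enumerate(tokens):
            f = ["bias", f"w0={lowers[i]}", f"shape={_shape(tok.text)}"]
            for d in range(1, self.window + 1):
                f.append(f"w-{d}=" + (lowers[i - d] if i - d >= 0 else "<s>"))
                f.append(f"w+{d}=" + (lowers[i + d] if i + d < len(tokens) else "</s>"))
            for k in (2, 3, 4):
                if len(tok.text) >= k:
                    f.append(f"pre{k}={lowers[i][:k]}")
                    f.append(f"suf{k}={lowers[i][-k:]}")
            if any(c.isdigit() for c in tok.text):
                f.append("has_digit")
            if tok.text.replace(".", "", 1).isdigit():
                f.append("is_num")
            for d in (-1, 0, 1):
                if 0 <= i + d < len(tokens) and lowers[i + d] in lex:
                    f.append(f"in_lex{d:+d}")
            feats.append(f)
        return feats

    def _hasher(self) -> FeatureHasher:
        return FeatureHasher(
            n_features=self.n_hash_features,
            input_type="string",
            alternate_sign=False,
        )

    def _featurize(self, sentence: Sentence) -> tuple[list[Token], sparse.csr_matrix]:
        cache = self.feature_cache
        key = (sentence.id, hash(sentence.text), self.window, self.n_hash_features)
        if cache is not None and key in cache:
            return cache[key]
        tokens = tokenize(sentence.text)
        if tokens:
            X = self._hasher().transform(self._token_features(tokens)).tocsr()
        else:
            X = sparse.csr_matrix((0, self.n_hash_features))
        if cache is not None:
            cache[key] = (tokens, X)
        return tokens, X

    # ------------------------------------------------------------------
    # decoding
    # ------------------------------------------------------------------
    def _transition_tables(self) -> None:
        labels = self.labels_
        self._label_index = {lab: i for i, lab in enumerate(labels)}
        # continuation_of[i] = entity type X if labels[i] == "I-X"
        self._continuation_of = [
            lab[2:] if lab.startswith("I-") else None for lab in labels
        ]
        self._type_of = [
            lab[2:] if lab != "O" else None for lab in labels
        ]

    def _decode_idx(self, scores: np.ndarray) -> list[int]:
        """Greedy left-to-right argmax under BIO transition constraints.

        Fast path: the unconstrained argmax is kept whenever it is a
        legal transition (ties resolve to the lowest label index either
        way, so the result equals full masked decoding).
        """
        cont = self._continuation_of
        type_of = self._type_of
        top = np.argmax(scores, axis=1)
        out: list[int] = []
        prev_type: str | None = None
        for i in range(scores.shape[0]):
            b = int(top[i])
            if cont[b] is not None and cont[b] != prev_type:
                row = scores[i]
                best_val = -np.inf
                b = 0
                for j in range(scores.shape[1]):
                    if cont[j] is not None and cont[j] != prev_type:
                        continue
                    if row[j] > best_val:
                        best_val = row[j]
                        b = j
            out.append(b)
            prev_type = type_of[b]
        return out

    def _decode(self, scores: np.ndarray) -> list[str]:
        return [self.labels_[i] for i in self._decode_idx(scores)]

    def _scores(self, X: sparse.csr_matrix, weights: np.ndarray) -> np.ndarray:
        # weights are stored feature-major (n_features x n_labels)
        return np.asarray(X @ weights)

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    def fit(
        self,
        X: Corpus | Sequence[Sentence],
        y=None,
        dev: Corpus | Sequence[Sentence] | None = None,
    ) -> "LinearBIOTagger":
        """Train on gold spans; select the epoch maximizing dev strict F1.

        With an empty/absent dev set the last epoch's averaged weights
        are kept (logged in provenance).
        """
        TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            dropout=self.dropout,
            max_sequence_length=self.max_sequence_length,
            seed=self.seed,
        )
        sentences = list(X)
        if not sentences:
            raise ValueError("empty training corpus")
        ent_labels = sorted({sp.label for s in sentences for sp in s.spans})
        if not ent_labels:
            warnings.warn(
                "training corpus contains zero entity mentions; "
                "the tagger will only ever predict O",
                stacklevel=2,
            )
            ent_labels = ["PK"]
        self.labels_ = ["O"] + [f"{p}-{lab}" for lab in ent_labels for p in ("B", "I")]
        self._transition_tables()
        L, D = len(self.labels_), self.n_hash_features

        data = []
        for s in sentences:
            tokens, Xf = self._featurize(s)
            gold = spans_to_bio(tokens, s.spans, policy="snap")
            data.append((Xf, np.array([self._label_index[t] for t in gold])))
        dev_sents = list(dev) if dev is not None else []

        rng = np.random.default_rng(self.seed)
        W = np.zeros((D, L))
        U = np.zeros((D, L))  # step-weighted accumulator for averaging
        step = 1
        best_f1 = -1.0
        best_weights: np.ndarray | None = None
        best_epoch = -1
        history: list[float] = []
        for epoch in range(self.epochs):
            n_updates = 0
            for si in rng.permutation(len(data)):
                Xf, gold_idx = data[si]
                if Xf.shape[0] == 0:
                    continue
                pred_idx = np.asarray(self._decode_idx(self._scores(Xf, W)))
                indptr, indices, vals = Xf.indptr, Xf.indices, Xf.data
                for ti in np.nonzero(pred_idx != gold_idx)[0]:
                    lo, hi = indptr[ti], indptr[ti + 1]
                    idx, v = indices[lo:hi], vals[lo:hi]
                    g, p = int(gold_idx[ti]), int(pred_idx[ti])
                    W[idx, g] += v
                    W[idx, p] -= v
                    U[idx, g] += step * v
                    U[idx, p] -= step * v
                    n_updates += 1
                step += 1
            avg = W - U / step
            if dev_sents:
                f1 = self._dev_f1(dev_sents, avg)
                snapshot = avg
                if n_updates == 0:
                    # converged: the raw weights fit the training set and
                    # are a legitimate selection candidate too
                    raw_f1 = self._dev_f1(dev_sents, W)
                    if raw_f1 > f1:
                        f1, snapshot = raw_f1, W
                history.append(f1)
                if f1 > best_f1:
                    best_f1, best_epoch = f1, epoch
                    best_weights = snapshot.copy()
            else:
                history.append(float("nan"))
                best_weights, best_epoch = avg, epoch
        assert best_weights is not None
        self.weights_ = best_weights
        self.dev_history_ = history
        self.best_epoch_ = best_epoch
        self.provenance_ = {
            "config": {
                k: v for k, v in self.get_params().items()
                if k not in ("lexicon", "feature_cache")
            },
            "seed": self.seed,
            "n_train": len(sentences),
            "n_dev": len(dev_sents),
            "dev_selection": bool(dev_sents),
            "best_epoch": best_epoch,
            "best_dev_f1": best_f1 if dev_sents else None,
        }
        return self

    def _dev_f1(self, dev_sents: Sequence[Sentence], weights: np.ndarray) -> float:
        counts = MatchCounts()
        for s in dev_sents:
            pred = self._predict_with_weights(s, weights)
            counts = counts + align_spans(s.spans, pred)
        return score(counts, "strict").f1

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise ValueError("tagger is not fitted")

    def _tag_tokens(self, Xf: sparse.csr_matrix, weights: np.ndarray) -> list[str]:
        """Tag a (possibly long) token sequence, chunking at the maximum
        sequence length and re-joining.  When a chunk boundary would split
        a predicted entity, the cut shifts to the nearest preceding
        O-predicted token within 10 tokens."""
        n = Xf.shape[0]
        max_len = self.max_sequence_length
        tags: list[str] = []
        start = 0
        while start < n:
            end = min(start + max_len, n)
            chunk_tags = self._decode(self._scores(Xf[start:end], weights))
            if end < n and chunk_tags and chunk_tags[-1] != "O":
                for back in range(1, min(10, len(chunk_tags) - 1) + 1):
                    if chunk_tags[-1 - back] == "O":
                        end -= back
                        chunk_tags = chunk_tags[: len(chunk_tags) - back]
                        break
            tags.extend(chunk_tags)
            start = end
        return tags

    def _predict_with_weights(
        self, sentence: Sentence, weights: np.ndarray
    ) -> list[EntitySpan]:
        tokens, Xf = self._featurize(sentence)
        if not tokens:
            return []
        tags = self._tag_tokens(Xf, weights)
        return bio_to_spans(tokens, tags)

    def predict_sentence(self, sentence: Sentence) -> list[EntitySpan]:
        self._check_fitted()
        return self._predict_with_weights(sentence, self.weights_)

    def predict(self, X: Iterable[Sentence]) -> list[list[EntitySpan]]:
        self._check_fitted()
        return [self._predict_with_weights(s, self.weights_) for s in X]

    def predict_corpus(self, corpus: Corpus) -> Corpus:
        self._check_fitted()
        return Corpus(
            sentences=[s.with_spans(self.predict_sentence(s)) for s in corpus],
            split=corpus.split,
        )

    def uncertainty(self, sentence: Sentence) -> float:
        """Margin-based uncertainty in [0, 1] (1 = maximally uncertain)."""
        self._check_fitted()
        tokens, Xf = self._featurize(sentence)
        if not tokens:
            return 0.0
        scores = self._scores(Xf, self.weights_)
        scores = scores - scores.max(axis=1, keepdims=True)
        probs = np.exp(scores)
        probs /= probs.sum(axis=1, keepdims=True)
        return margin_uncertainty(probs)

    def propose(self, sentence: Sentence) -> tuple[list[EntitySpan], float]:
        """Candidate spans plus margin uncertainty from a single scoring pass.

        This is the model-in-the-loop view an annotation interface needs:
        what the model would suggest, and how unsure it is about the
        sentence overall.
        """
        self._check_fitted()
        tokens, Xf = self._featurize(sentence)
        if not tokens:
            return [], 0.0
        tags = self._tag_tokens(Xf, self.weights_)
        scores = self._scores(Xf, self.weights_)
        scores = scores - scores.max(axis=1, keepdims=True)
        probs = np.exp(scores)
        probs /= probs.sum(axis=1, keepdims=True)
        return bio_to_spans(tokens, tags), margin_uncertainty(probs)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file versioned archive (numpy .npz with a JSON header)."""
        self._check_fitted()
        header = {
            "format": MODEL_FORMAT,
            "labels": self.labels_,
            "params": {
                k: v for k, v in self.get_params().items()
                if k not in ("lexicon", "feature_cache")
            },
            "lexicon": sorted(self._lexicon()),
            "dev_history": self.dev_history_,
            "best_epoch": self.best_epoch_,
            "provenance": self.provenance_,
        }
        with open(path, "wb") as fh:
            np.savez_compressed(
                fh,
                header=np.frombuffer(
                    json.dumps(header).encode("utf-8"), dtype=np.uint8
                ),
                weights=self.weights_,
            )

    @classmethod
    def load(cls, path: str | Path) -> "LinearBIOTagger":
        try:
            with np.load(path, allow_pickle=False) as npz:
                header = json.loads(bytes(npz["header"]).decode("utf-8"))
                weights = npz["weights"]
        except FileNotFoundError:
            raise
        except (zipfile.BadZipFile, ValueError, KeyError, OSError,
                json.JSONDecodeError) as exc:
            raise ModelIOError(f"cannot read model archive {path}: {exc}") from None
        if header.get("format") != MODEL_FORMAT:
            raise ModelIOError(
                f"incompatible model format {header.get('format')!r}; "
                f"expected {MODEL_FORMAT!r}"
            )
        model = cls(**header["params"], lexicon=frozenset(header["lexicon"]))
        model.labels_ = list(header["labels"])
        model._transition_tables()
        model.weights_ = weights
        model.dev_history_ = header["dev_history"]
        model.best_epoch_ = header["best_epoch"]
        model.provenance_ = header["provenance"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train(
    train_corpus: Corpus,
    dev_corpus: Corpus | None = None,
    config: TrainConfig | None = None,
    **kwargs,
) -> LinearBIOTagger:
    cfg = config or TrainConfig()
    model = LinearBIOTagger(**{**asdict(cfg), **kwargs})
    return model.fit(train_corpus, dev=dev_corpus)


def predict(model: LinearBIOTagger, sentence: Sentence) -> list[EntitySpan]:
    return model.predict_sentence(sentence)


def uncertainty(model: LinearBIOTagger, sentence: Sentence) -> float:
    return model.uncertainty(sentence)
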