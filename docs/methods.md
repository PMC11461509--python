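# Methods

This note documents the models, conventions and design decisions behind
`pkner`, and what its synthetic benchmarks do and do not demonstrate.

## Corpus model and offset conventions

The unit of analysis is the sentence. Entity mentions are character
spans, 0-based and half-open, attached to a single entity class (`PK` by
default; the type system is multi-class so a second label can be carried,
which the evaluation tests exercise). Spans within a sentence must be
non-overlapping and sorted; nested or overlapping gold spans are rejected
at load time, since the annotation scheme being modelled is flat.
Sentences carry a `section` tag (`abstract`/`full_text`); records missing
it default to `full_text` and are counted in the statistics output so
imputation is visible.

**Tokenizer.** A deterministic regex: word tokens are runs of Unicode
letters/digits (plus `∞`) optionally glued across internal `-`, `/`, `.`
and `·`; any other non-space character is a single-character token. This
keeps PK surface forms — `AUC0-24`, `AUC0-∞`, `t1/2`, `4.2`, `mg·h/L` —
as single tokens without depending on an external tokenization model,
and it is invertible in the sense tested: joining token slices and the
whitespace gaps reconstructs the input exactly.

**BIO codec.** `spans_to_bio` supports two policies: `strict` (a span
boundary inside a token is an error) and `snap` (default; the span
expands to the covering tokens, with a logged warning), the latter chosen
for robustness against corpora tokenized by other tools. `bio_to_spans`
repairs dangling continuations: an `I-X` that does not continue a
`B-X`/`I-X` run is read as `B-X`. Round-tripping token-aligned spans
through the codec is the identity, property-tested at scale.

**I/O.** JSON-Lines is the canonical dialect and round-trips exactly.
CoNLL (`TOKEN<TAB>TAG`) round-trips tokens and tags but re-derives
offsets by single-space joining; this loss is deliberate and documented
rather than worked around.

## Synthetic corpus generator

Every statistical claim in the test suite is made on corpora from the
template generator, whose defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| `prevalence` | 0.164 | fraction of sentences with ≥1 PK mention (random-sampling regime; the selective regime uses 0.6425) |
| `pct_full_text` | 0.508 | fraction tagged `full_text` (evaluation regime) |
| `ambiguity_rate` | 0.2 | entity sentences using the context-dependent acronym "F"; symmetrically, filler sentences containing non-PK "F" |
| `distractor_rate` | 0.3 | non-entity sentences carrying a PD distractor (AUEC, MTD, Emax, EC50, IC50, …) |
| `novel_modifier_rate` | 0.15 | modifiable long-form mentions whose modifier prefix is swapped for one outside the shipped rule lexicon ("renal clearance") |

The inventory ships 42 PK surface forms (26 long forms, 15 acronyms, the
ambiguous "F") and 7 distractors. Four heads (clearance, half-life,
bioavailability, volume of distribution) compose modifier prefixes
combinatorially from per-head vocabularies, so span variety is larger
than the listed forms; a deliberate subset of long-tail forms ("mean
residence time", "lag time", …) has no rule coverage at all. This
structure reproduces the documented failure modes of lexicon matching —
complementary modifiers clip boundaries (partial-but-not-strict matches)
and uncovered parameter types cost recall — and gives selective sampling
something to find. Numeric values and units are cosmetic draws from
plausible ranges; no pharmacological validity is claimed. Generation is
template-based rather than model-based so gold offsets are exact by
construction and corpora are byte-identical across runs for a fixed seed.

What passing on this data does **not** show: robustness to real prose
(anaphora, tables, nested clauses), to annotation-guideline drift, or to
the true long tail of PK vocabulary. The templates are finite, so a
sufficiently trained tagger can reach strict F1 = 100 on held-out
synthetic data; absolute scores here are not predictions of performance
on real corpora, only the *contrasts* (rules vs learned, selective vs
random sampling) are the object of study.

## Rule-based matcher

Rules are data (`src/pkner/data/pk_rules.yaml`), not code: each rule is a
token-constraint sequence (exact text, lowercase match, membership list,
or full-match regex; positions may be optional) with an optional lexical
context gate. Design choices:

- **Context gates instead of syntax.** Part-of-speech or dependency
  constraints would require an external parser; required/forbidden
  neighbour terms within a 5-token window preserve the disambiguation
  function they served. The "F" rule requires a dosing/bioavailability
  term nearby and forbids statistical contexts.
- **Case sensitivity by length.** Short acronyms (`CL`, `F`, `ka`) match
  case-sensitively — lowercase "f"/"cl" are overwhelmingly non-entities —
  while long forms match case-insensitively.
- **Overlap resolution.** Longest span wins, ties broken leftmost then
  lowest rule id: fully deterministic, and "total body clearance" never
  yields a nested "clearance" match.

The shipped ruleset is a reconstruction of the *coverage described* for
such systems (primary surface forms, acronyms incl. subscripted AUC
variants, modifier slots, a gated "F"), not a copy of any published rule
list; its absolute scores are therefore not comparable to published
rule-based scores.

## Linear BIO tagger

The reference backend is an averaged structured perceptron: per-token
features hashed into 2^18 dimensions (sklearn `FeatureHasher`), one
weight column per BIO label, greedy left-to-right decoding under
transition constraints (no `I-X` after `O` or after a different label),
trained by decoding each sentence and updating on mismatched tokens.
Feature template: word identities in a ±3 window, word shape, 2–4
character prefixes/suffixes, digit flags, and a PK-lexicon membership
flag for the token and its immediate neighbours. The ±3 window is the
smallest that separates long-form mentions from PD look-alikes that share
a 3-token prefix ("area under the *effect* curve" vs "area under the
curve"). Training is CPU-only, deterministic for a fixed seed (a seeded
permutation per epoch), and takes seconds at desk scale.

- **Model selection.** After each epoch the averaged weights are scored
  on the development set (entity-level strict F1) and the best state is
  kept; with no dev set, the last epoch is kept and recorded in
  provenance. When an epoch completes with zero updates the perceptron
  has converged, and the raw (non-averaged) weights — which then fit the
  training data exactly — are also considered as a selection candidate.
- **Long sentences.** Sequences beyond `max_sequence_length` (default
  256) are chunked at token boundaries, tagged per chunk and re-joined;
  if a chunk boundary would split a predicted entity the cut shifts back
  to the nearest O-predicted token within 10 tokens.
- **Uncertainty.** 1 minus the mean top-two margin of the per-token
  softmax-normalized label scores: 0 for one-hot confidence, 1 for
  uniform scores, clipped to [0, 1]. Empty sentences score 0 so they
  never win an uncertainty ranking.
- **Imbalance.** No loss weighting for the O-majority; exposed only
  through the configuration surface.
- **Encoder plug-in.** `TokenScorer` (tokens → per-token score matrix) is
  the contract a transformer backend must satisfy; `EncoderRecipe`
  records its fine-tuning configuration (20 epochs, batch 16, lr 3e-5,
  weight decay 0.05 *and* a linear learning-rate schedule flag — the two
  are exposed separately because "linear weight decay" plausibly
  conflates them — dropout 0.1, max length 256, first-subword labelling
  with continuation pieces masked from the loss). No pretrained weights
  are bundled: the linear backend exists to exercise every downstream
  contract cheaply, not to rival a fine-tuned encoder.

Ignored-parameter note: `batch_size`, `learning_rate`, `weight_decay`
and `dropout` parameterize the encoder recipe; the perceptron backend
accepts and records but does not use them.

## Evaluation

Alignment is greedy and in order, with exact-boundary matches claimed
before partial overlaps; with sorted, non-overlapping span lists this
greedy pass attains the maximum matching, which the test suite pins
against a brute-force oracle enumerating all injective matchings
(lexicographically maximizing exact then overlap matches). With a single
entity class INC is structurally zero; the multi-class path is kept and
tested with a second synthetic label. Scores are percentages rounded to
two decimals at the reporting boundary (fractions internally); zero
denominators yield flagged zeros. Partial F1 ≥ strict F1 on every input
because the partial numerator dominates with identical denominators.
Inter-annotator agreement is the pairwise strict F1 treating one
annotator as gold — symmetric because swapping gold and prediction
exchanges precision and recall — with the mean taken off-diagonal.

## Active-learning simulation

The simulator reproduces a two-stage labelling protocol: (1) *heuristic
bootstrap* — rule-matched pool sentences are corrected by the simulated
annotator and form the initial training set; (2) *uncertainty loop* — the
tagger proposes spans for a candidate subset of the pool, the annotator
accepts/rejects each proposal by exact gold match and then supplies the
corrected annotation (boundary fixes and missed spans are logged), and
the model is fully retrained after every 10 newly labelled sentences.
Full retraining (rather than incremental updates) keeps every state a
pure function of the seed.

**Selection rule.** Candidates are ranked first by whether the model
proposes at least one span, then by margin uncertainty. The span-first
gate models the interface being emulated, which surfaces candidate
*spans* for binary judgement — a sentence with no proposal offers nothing
to judge — and it is the mechanism that concentrates entity mentions in
the labelled set. Token-margin ranking alone demonstrably fails here:
after an entity-rich bootstrap the most uncertain sentences are simply
*unseen filler*, and the labelled set barely enriches. **Candidate
subsampling** (a seeded random subset, default 500, scored per update)
keeps the per-update cost proportional to the batch rather than the pool;
it is standard practice in pool-based active learning.

**The comparison experiment** builds a fresh pool per replicate, labels
the same number of sentences by uncertainty (with bootstrap) and by
one-shot random sampling, trains a fresh tagger per arm (5 epochs, no
dev-set selection, matching the emulated protocol) and scores both arms
on a shared held-out synthetic test set at the natural 16.4% prevalence.
Reported per arm and replicate: strict and partial precision/recall/F1
and the labelled set's entity prevalence. At the full scale used in the
test suite (pool 5000, 500 labelled per arm, 10 replicates) the
uncertainty arm's labelled prevalence lands near the selective-sampling
regime while the random arm stays near the pool's, and the AL arm's F1
advantage is recall-driven — the qualitative signature the simulation is
meant to reproduce. Problem sizes for the scripted run (pool 2000, 200
per arm, 5 replicates) were chosen as comfortable desk-scale defaults
that leave the contrasts clearly visible.

## Numerical and degenerate-input conventions

- Percentages are the external representation (0–100, two decimals);
  fractions are internal. Rounding happens once, at the reporting edge.
- Empty corpora produce zero-count statistics with an
  `undefined_pct` flag, never a division error; empty sentences tokenize
  to empty lists and predict empty span lists.
- Ties everywhere break deterministically (lowest label index in
  decoding, leftmost-then-lowest-rule-id in matching, sentence id in
  uncertainty ranking).
- Seeds: Python `random.Random` drives text generation and sampling;
  NumPy `default_rng` drives training permutations; derived seeds are
  kept below 2^31.

## Known limitations

- The synthetic corpus is template-based; its difficulty is a design
  parameter, not an estimate of real-corpus difficulty, and ceiling
  effects (strict F1 = 100) occur at realistic training sizes.
- The shipped ruleset covers the described *kind* of lexicon, not any
  published rule list verbatim.
- The linear tagger's uncertainty is a documented stand-in for whatever
  scorer a production annotation tool uses; only its ordinal behaviour
  matters to the simulation.
- Discontinuous and nested mentions are out of scope (flat spans only).
- CoNLL interchange loses original character offsets by construction.
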