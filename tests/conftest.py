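import random

import pytest

from pkner.corpus import Corpus, EntitySpan, Sentence
from pkner.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    """Hand-built corpus exercising spans, sections and the empty case."""
    return Corpus(
        sentences=[
            Sentence(
                id="a",
                text="CL was 5 L/h",
                spans=[EntitySpan(0, 2)],
                section="abstract",
            ),
            Sentence(
                id="b",
                text="The clearance and half-life were low.",
                spans=[EntitySpan(4, 13), EntitySpan(18, 27)],
            ),
            Sentence(id="c", text="No entities here.", section="abstract"),
        ]
    )


@pytest.fixture(scope="session")
def synth_1k() -> Corpus:
    return generate_corpus(GeneratorConfig(n_sentences=1000, seed=1234))


def random_span_list(rng: random.Random, max_spans: int = 6, width: int = 40):
    """Random sorted, non-overlapping spans in [0, width) with rare
    second labels (to exercise the multi-class INC path)."""
    spans = []
    pos = rng.randrange(0, 4)
    while len(spans) < max_spans and pos < width - 2:
        length = rng.randrange(1, 6)
        end = min(pos + length, width)
        if rng.random() < 0.8:
            label = "PK" if rng.random() < 0.85 else "OTHER"
            spans.append(EntitySpan(pos, end, label))
        pos = end + rng.randrange(0, 4)
    return spans
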