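import numpy as np
import pytest

from clinevent import (LabeledSentence, SynthConfig, TagSchema,
                       generate_corpus, worked_example)


@pytest.fixture(scope="session")
def schema() -> TagSchema:
    return TagSchema()


@pytest.fixture(scope="session")
def example():
    """The packaged worked augmentation example: (sentence, lexicon)."""
    return worked_example()


@pytest.fixture()
def tiny_corpus() -> list[LabeledSentence]:
    return generate_corpus(SynthConfig(n_sentences=10, seed=7, signal=1.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_span_sets(rng, n_sentences=20, max_len=15):
    """Random sentences of non-overlapping typed spans, for property tests."""
    from clinevent import EVENT_TYPES, EventSpan
    out = []
    lengths = []
    for _ in range(n_sentences):
        length = int(rng.integers(1, max_len + 1))
        spans = []
        pos = 0
        while pos < length:
            if rng.random() < 0.4:
                width = int(rng.integers(1, min(4, length - pos) + 1))
                spans.append(EventSpan(pos, pos + width,
                                       EVENT_TYPES[rng.integers(6)]))
                pos += width + 1
            else:
                pos += 1
        out.append(spans)
        lengths.append(length)
    return out, lengths
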