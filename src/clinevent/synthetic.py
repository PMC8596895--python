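"""Desk-scale synthetic corpora with the structure the tagger assumes.

The real target corpus (de-identified clinical discharge summaries) is
access-restricted, so development and testing run on generated corpora that
keep the method's load-bearing structure:

* six event types with configurable span-share proportions;
* events of 1-3 tokens embedded in filler text, never adjacent to each
  other, so gold BIOES sequences are strictly schema-valid;
* a *word-shape* type signal: an event token carries a type-specific
  character trigram suffix with probability ``signal``.  Event word stems
  are drawn at random, so word identity alone is uninformative about the
  type — the character encoder is what the signal exercises, and zeroing
  it must hurt.
* a synthetic replacement lexicon whose keys are filler words only, so
  augmentation can never touch an event token.

What a green test on this world does NOT establish: performance on real
clinical narratives, robustness to annotation noise, or anything about
pretrained-embedding quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import Lexicon, worked_example_lexicon
from .corpus import EVENT_TYPES, EventSpan, LabeledSentence, TagSchema, encode_spans

__all__ = ["SynthConfig", "generate_corpus", "generate_lexicon", "worked_example",
           "TYPE_AFFIXES"]

#: Type-marking suffix trigrams. "q"-free filler letters guarantee no filler
#: word ever ends in one of these.
TYPE_AFFIXES: dict[str, str] = {
    "problem": "qab",
    "test": "qed",
    "treatment": "qif",
    "evidential": "qog",
    "occurrence": "quh",
    "clinical_department": "qyk",
}

_FILLER_LETTERS = list("abcdefghilmnoprstuvw")  # no q


@dataclass
class SynthConfig:
    """Stated world of the generator; defaults are the documented conditions.

    ``signal`` is the probability that an event token carries its type
    affix; 1.0 gives a fully word-shape-separable corpus.
    """

    n_sentences: int = 500
    vocab_size: int = 150
    min_len: int = 5
    max_len: int = 12
    proportions: dict[str, float] = field(
        default_factory=lambda: {t: 1 / len(EVENT_TYPES) for t in EVENT_TYPES})
    events_per_sentence_mean: float = 1.2
    max_event_len: int = 3
    signal: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if min(self.n_sentences, self.vocab_size, self.min_len) < 1:
            raise ValueError("counts must be positive")
        if self.max_event_len > self.max_len:
            raise ValueError("events longer than the maximum sentence length")
        if not (0.0 <= self.signal <= 1.0):
            raise ValueError("signal must be a probability")


def _random_word(rng: np.random.Generator, lo: int = 3, hi: int = 7) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_FILLER_LETTERS, size=n))


def filler_vocabulary(config: SynthConfig) -> list[str]:
    """The deterministic filler vocabulary for a config (seed-derived)."""
    rng = np.random.default_rng(config.seed + 1)
    vocab: list[str] = []
    seen = set()
    while len(vocab) < config.vocab_size:
        w = _random_word(rng)
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    return vocab


def _event_token(rng: np.random.Generator, type_: str, signal: float) -> str:
    stem = _random_word(rng, 3, 5)
    if rng.random() < signal:
        return stem + TYPE_AFFIXES[type_]
    return stem


def generate_corpus(config: SynthConfig) -> list[LabeledSentence]:
    """Generate ``n_sentences`` schema-valid labeled sentences."""
    rng = np.random.default_rng(config.seed)
    vocab = filler_vocabulary(config)
    types = list(config.proportions)
    probs = np.array([config.proportions[t] for t in types])
    schema = TagSchema()
    sentences: list[LabeledSentence] = []
    for _ in range(config.n_sentences):
        length = int(rng.integers(config.min_len, config.max_len + 1))
        k = int(rng.poisson(config.events_per_sentence_mean))
        ev_lens: list[int] = []
        for _ in range(k):
            ev_len = int(rng.integers(1, config.max_event_len + 1))
            # keep total event + separating-gap budget within the sentence
            if sum(ev_lens) + len(ev_lens) + ev_len <= length:
                ev_lens.append(ev_len)
        k = len(ev_lens)
        n_fill = length - sum(ev_lens)
        # distribute filler tokens into k+1 buckets; internal buckets >= 1
        gaps = [0] + [1] * (k - 1) + [0] if k else [n_fill]
        if k:
            spare = n_fill - (k - 1)
            for _ in range(spare):
                gaps[int(rng.integers(0, k + 1))] += 1
        tokens: list[str] = []
        spans: list[EventSpan] = []
        for i in range(k + 1 if k else 1):
            tokens.extend(str(w) for w in rng.choice(vocab, size=gaps[i]))
            if k and i < k:
                t = types[int(rng.choice(len(types), p=probs))]
                start = len(tokens)
                tokens.extend(_event_token(rng, t, config.signal)
                              for _ in range(ev_lens[i]))
                spans.append(EventSpan(start, start + ev_lens[i], t))
        tags = encode_spans(len(tokens), spans, schema)
        sentences.append(LabeledSentence(tokens, tags))
    return sentences


def generate_lexicon(vocabulary: list[str], config: SynthConfig) -> Lexicon:
    """Synthetic relation lists over the filler vocabulary only.

    Event-affixed words are excluded from both keys and candidates by
    construction, mirroring the non-event-only replacement rule, so
    augmenting a generated corpus can never corrupt its labels.
    """
    rng = np.random.default_rng(config.seed + 2)
    fillers = [w for w in vocabulary
               if not any(w.endswith(a) for a in TYPE_AFFIXES.values())]
    entries: dict[str, dict[str, list[str]]] = {}
    for word in fillers:
        if rng.random() > 0.7:
            continue
        entry: dict[str, list[str]] = {}
        for rel in ("synonyms", "antonyms", "hypernyms", "hyponyms",
                    "related_words"):
            if rng.random() < 0.35:
                n = int(rng.integers(1, 4))
                cands = [str(c) for c in rng.choice(fillers, size=n)
                         if c != word]
                entry[rel] = list(dict.fromkeys(cands))
            else:
                entry[rel] = []
        if any(entry.values()):
            entries[word] = entry
    return Lexicon(entries)


def worked_example() -> tuple[LabeledSentence, Lexicon]:
    """The packaged worked augmentation example.

    One clinical sentence with "barium enema" tagged as a test event, and
    the fixture lexicon (has -> synonym "have"; worked -> hypernym "set",
    hyponym "cut", related word "put"; up -> antonym "down").  Only
    O-tagged tokens are replaceable, so augmentation touches {has, worked,
    up} and never the event tokens.
    """
    tokens = ["She", "has", "been", "worked", "up", "with", "barium",
              "enema", "09/97", "."]
    tags = ["O", "O", "O", "O", "O", "O", "B-test", "E-test", "O", "O"]
    return LabeledSentence(tokens, tags), worked_example_lexicon()
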