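"""Word representations: character-level attention encoder and word lookup.

Character shape is informative in clinical text (prefixes like "un-",
units, abbreviation patterns), so each word is encoded by running a small
relative-position attention stack over its characters and max-pooling the
result.  Word-level embeddings are pluggable behind the
:class:`WordEmbedder` protocol; the default is a trainable lookup table.
A contextual embedder (e.g. a pretrained biomedical BERT producing 768-wide
rows) can be slotted in through the same protocol, but no pretrained weights
are bundled or required.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np

from ._autodiff import Tensor
from .corpus import LabeledSentence
from .tener_core import TenerConfig, TenerStack

__all__ = [
    "CharVocab",
    "CharEncoderConfig",
    "CharEncoder",
    "embed_sentence_chars",
    "WordEmbedder",
    "LookupWordEmbedder",
    "build_word_vocab",
]

_NEG = -1e30


class CharVocab:
    """Character inventory seeded with printable ASCII; PAD=0, UNK=1."""

    PAD = 0
    UNK = 1

    def __init__(self, extra_chars: Iterable[str] = ()):
        chars = list(string.printable.strip()) + sorted(
            set(extra_chars) - set(string.printable)
        )
        self._index = {c: i + 2 for i, c in enumerate(chars)}

    def __len__(self) -> int:
        return len(self._index) + 2

    def encode(self, word: str, wl: int) -> np.ndarray:
        ids = [self._index.get(c, self.UNK) for c in word[:wl]]
        ids += [self.PAD] * (wl - len(ids))
        return np.array(ids, dtype=np.intp)


@dataclass
class CharEncoderConfig:
    cd: int = 30          # character embedding width
    layers: int = 1
    heads: int = 3
    cd_ff: int = 60       # FFN hidden width inside the char attention block
    wl_cap: int = 24      # hard cap on word length in characters
    out_dim: int | None = None  # resize-FC output width; defaults to cd
    layer_norm: bool = True

    def __post_init__(self):
        if self.cd % self.heads != 0:
            raise ValueError(f"cd={self.cd} not divisible by heads={self.heads}")
        if self.out_dim is None:
            self.out_dim = self.cd


class CharEncoder:
    """Characters -> lookup -> attention stack -> resize FC -> masked max-pool.

    The word length `wl` is dynamic (the longest word in the batch, capped by
    ``wl_cap``); padding characters are masked out of both the attention and
    the pooling, so outputs are independent of the amount of padding.
    """

    def __init__(self, config: CharEncoderConfig, rng: np.random.Generator,
                 vocab: CharVocab | None = None):
        self.config = config
        self.vocab = vocab or CharVocab()
        self.embedding = Tensor(
            rng.normal(0.0, 0.1, size=(len(self.vocab), config.cd)),
            requires_grad=True,
        )
        self.embedding.data[CharVocab.PAD] = 0.0
        self.stack = TenerStack(
            TenerConfig(d_model=config.cd, heads=config.heads,
                        d_ff=config.cd_ff, layers=config.layers,
                        layer_norm=config.layer_norm),
            rng,
        )
        scale = np.sqrt(2.0 / (config.cd + config.out_dim))
        self.W_r = Tensor(rng.normal(0.0, scale, size=(config.cd, config.out_dim)),
                          requires_grad=True)
        self.b_r = Tensor(np.zeros(config.out_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.embedding, *self.stack.parameters(), self.W_r, self.b_r]

    def embed_words(self, words: list[str],
                    rng: np.random.Generator | None = None) -> Tensor:
        """Encode a batch of words; returns an (n_words, out_dim) tensor."""
        if any(not w for w in words):
            raise ValueError("cannot encode an empty word")
        if not words:
            return Tensor(np.zeros((0, self.config.out_dim)))
        wl = min(max(len(w) for w in words), self.config.wl_cap)
        ids = np.stack([self.vocab.encode(w, wl) for w in words])
        mask = ids != CharVocab.PAD
        H = self.embedding[ids]                       # (n, wl, cd)
        H = self.stack(H, mask=mask, rng=rng)
        X = H @ self.W_r + self.b_r                   # (n, wl, out_dim)
        X = X + np.where(mask, 0.0, _NEG)[..., None]  # exclude padding from pool
        return X.max(axis=1)

    def encode_word_chars(self, word: str) -> np.ndarray:
        """Character-level vector of one word (inference convenience)."""
        return self.embed_words([word]).data[0]


def embed_sentence_chars(tokens: list[str], encoder: CharEncoder) -> np.ndarray:
    """Stack per-word character vectors into an (l, out_dim) matrix."""
    if not tokens:
        return np.zeros((0, encoder.config.out_dim))
    return encoder.embed_words(list(tokens)).data


class WordEmbedder(Protocol):
    """Contract: ``embed(tokens)`` returns an (l, wd) tensor; ``wd`` fixed."""

    wd: int

    def embed(self, tokens: list[str]) -> Tensor: ...

    def parameters(self) -> list[Tensor]: ...


UNK_TOKEN = "<unk>"


def build_word_vocab(corpus: Iterable[LabeledSentence],
                     min_count: int = 2) -> dict[str, int]:
    """Frequency-thresholded word vocabulary; rare words fall back to UNK."""
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {UNK_TOKEN: 0}
    for tok in sorted(counts):
        if counts[tok] >= min_count:
            vocab[tok] = len(vocab)
    return vocab


class LookupWordEmbedder:
    """Trainable lookup-table word embedder; OOV tokens map to the UNK row."""

    def __init__(self, vocab: dict[str, int], wd: int, seed: int = 0):
        if wd < 1:
            raise ValueError("wd must be >= 1")
        self.vocab = dict(vocab)
        self.wd = wd
        rng = np.random.default_rng(seed)
        self.table = Tensor(rng.normal(0.0, 0.1, size=(len(vocab), wd)),
                            requires_grad=True)

    def token_ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocab[UNK_TOKEN]
        return np.array([self.vocab.get(t, unk) for t in tokens], dtype=np.intp)

    def embed(self, tokens: list[str]) -> Tensor:
        if not tokens:
            return Tensor(np.zeros((0, self.wd)))
        return self.table[self.token_ids(tokens)]

    def parameters(self) -> list[Tensor]:
        return [self.table]


def lookup_word_embedder(vocab: dict[str, int] | Iterable[str], wd: int,
                         seed: int = 0) -> LookupWordEmbedder:
    """Build the default word embedder from a vocabulary."""
    if not isinstance(vocab, dict):
        words = [w for w in vocab if w != UNK_TOKEN]
        vocab = {UNK_TOKEN: 0, **{w: i + 1 for i, w in enumerate(words)}}
    if UNK_TOKEN not in vocab:
        vocab = {UNK_TOKEN: len(vocab), **vocab}
    return LookupWordEmbedder(vocab, wd, seed=seed)
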