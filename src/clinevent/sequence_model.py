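"""The full tagger: char + word features -> attention encoder -> linear CRF.

Per sentence, character-level vectors H^c (l x cd) and word-level vectors
H^w (l x wd) are concatenated, projected to the encoder width d_model, passed
through a stack of relative-position attention layers, and mapped by an
affine layer to one emission score per BIOES label.  A linear-chain CRF with
explicit START/STOP boundary scores turns the emission matrix into a
distribution over whole label sequences::

    score(y) = start[y_1] + sum_i emis[i, y_i] + sum_i trans[y_{i-1}, y_i]
             + stop[y_l]
    P(y | H) = exp(score(y)) / sum_{y'} exp(score(y'))

Decoding uses the Viterbi algorithm; training minimizes the negative
log-likelihood computed with the forward algorithm in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat
from .corpus import LabeledSentence, TagSchema
from .embedders import (CharEncoder, CharEncoderConfig, LookupWordEmbedder,
                        build_word_vocab)
from .tener_core import TenerConfig, TenerStack

__all__ = [
    "CrfParams",
    "ModelConfig",
    "EventTagger",
    "crf_sequence_score",
    "crf_log_partition",
    "viterbi_decode",
    "nll_loss",
]

_NEG = -1e30


class CrfParams:
    """Label-transition table plus START/STOP boundary scores.

    ``transitions[p, c]`` scores label c following label p.  Emission scores
    are supplied externally (the model's final affine layer plays the role of
    the per-label emission projection).
    """

    def __init__(self, d_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.transitions = Tensor(rng.normal(0.0, 0.01, size=(d_f, d_f)),
                                  requires_grad=True)
        self.start = Tensor(np.zeros(d_f), requires_grad=True)
        self.stop = Tensor(np.zeros(d_f), requires_grad=True)

    @property
    def d_f(self) -> int:
        return self.transitions.shape[0]

    def parameters(self) -> list[Tensor]:
        return [self.transitions, self.start, self.stop]


def _check(scores: np.ndarray, y, crf: CrfParams):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != crf.d_f:
        raise ValueError(f"scores must be (l, {crf.d_f}), got {scores.shape}")
    if y is not None:
        y = np.asarray(y, dtype=int)
        if len(y) != len(scores):
            raise ValueError("label sequence length != score rows")
        if y.min() < 0 or y.max() >= crf.d_f:
            raise ValueError("label index out of range")
    return scores, y


def crf_sequence_score(scores: np.ndarray, y, crf: CrfParams) -> float:
    """Unnormalized log-score of one label sequence (Viterbi-path numerator)."""
    scores, y = _check(scores, y, crf)
    trans = crf.transitions.data
    total = crf.start.data[y[0]] + crf.stop.data[y[-1]]
    total += scores[np.arange(len(y)), y].sum()
    total += trans[y[:-1], y[1:]].sum()
    return float(total)


def crf_log_partition(scores: np.ndarray, crf: CrfParams) -> float:
    """log sum over all d_f^l label sequences, by the forward algorithm."""
    scores, _ = _check(scores, None, crf)
    trans = crf.transitions.data
    alpha = crf.start.data + scores[0]
    for t in range(1, len(scores)):
        m = alpha.max()
        alpha = m + np.log(np.exp(alpha - m) @ np.exp(trans)) + scores[t]
    m = alpha.max()
    return float(m + np.log(np.exp(alpha + crf.stop.data - m).sum()))


def viterbi_decode(scores: np.ndarray, crf: CrfParams) -> list[int]:
    """Argmax label sequence; ties break toward the lowest label index."""
    scores, _ = _check(scores, None, crf)
    trans = crf.transitions.data
    delta = crf.start.data + scores[0]
    back: list[np.ndarray] = []
    for t in range(1, len(scores)):
        cand = delta[:, None] + trans           # (prev, cur)
        best_prev = cand.argmax(axis=0)         # first max -> lowest index
        back.append(best_prev)
        delta = cand[best_prev, np.arange(crf.d_f)] + scores[t]
    delta = delta + crf.stop.data
    path = [int(delta.argmax())]
    for best_prev in reversed(back):
        path.append(int(best_prev[path[-1]]))
    return path[::-1]


def nll_loss(batch: list[tuple[np.ndarray, list[int]]], crf: CrfParams) -> float:
    """Sum over the batch of (log-partition - gold sequence score); >= 0."""
    return float(sum(
        crf_log_partition(scores, crf) - crf_sequence_score(scores, y, crf)
        for scores, y in batch
    ))


def crf_nll_batched(emissions: Tensor, tags: np.ndarray, lengths: np.ndarray,
                    crf: CrfParams) -> Tensor:
    """Differentiable batched NLL; used by the training loop.

    ``emissions`` is (B, L, d_f); ``tags`` (B, L) int, padded arbitrarily
    beyond each sentence's length; ``lengths`` (B,).  Padded positions are
    excluded from emissions, transitions and the partition function.
    Equals the sum of per-sentence :func:`nll_loss` terms.
    """
    B, L, d_f = emissions.shape
    rows = np.repeat(np.arange(B), lengths)
    cols = np.concatenate([np.arange(n) for n in lengths])
    gold = emissions[rows, cols, tags[rows, cols]].sum()
    prev_rows, prev_cols = [], []
    for b, n in enumerate(lengths):
        prev_rows.extend([b] * (n - 1))
        prev_cols.extend(range(n - 1))
    prev_rows = np.array(prev_rows, dtype=np.intp)
    prev_cols = np.array(prev_cols, dtype=np.intp)
    gold = gold + crf.transitions[tags[prev_rows, prev_cols],
                                  tags[prev_rows, prev_cols + 1]].sum()
    last = lengths - 1
    gold = gold + crf.start[tags[np.arange(B), 0]].sum()
    gold = gold + crf.stop[tags[np.arange(B), last]].sum()

    alpha = emissions[:, 0, :] + crf.start
    trans = crf.transitions.reshape(1, d_f, d_f)
    for t in range(1, L):
        new = (alpha.reshape(B, d_f, 1) + trans).logsumexp(axis=1) \
            + emissions[:, t, :]
        live = (t < lengths).astype(float)[:, None]
        alpha = new * live + alpha * (1.0 - live)
    log_z = (alpha + crf.stop).logsumexp(axis=1).sum()
    return log_z - gold


def bioes_transition_penalty(schema: TagSchema) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive penalties forbidding strict-BIOES-invalid moves at decode time."""
    labels = schema.labels
    d_f = len(labels)

    def part(lab):  # ("O", None) or (prefix, type)
        return ("O", None) if lab == "O" else (lab[0], lab[2:])

    trans = np.zeros((d_f, d_f))
    start = np.zeros(d_f)
    stop = np.zeros(d_f)
    for i, a in enumerate(labels):
        pa, ta = part(a)
        if pa in ("B", "I"):
            stop[i] = _NEG  # span left open
        for j, b in enumerate(labels):
            pb, tb = part(b)
            if pb in ("I", "E"):
                ok = pa in ("B", "I") and ta == tb
            else:
                ok = pa not in ("B", "I")
            if not ok:
                trans[i, j] = _NEG
    for j, b in enumerate(labels):
        pb, _ = part(b)
        if pb in ("I", "E"):
            start[j] = _NEG
    return trans, start, stop


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the tagger.

    The published configuration uses cd=30 / 3 char heads / cd_ff=60, two
    encoder layers with 8 heads, batch 16.  The concatenated feature width
    cd+wd need not divide the head count: a learned input projection maps it
    to ``d_model`` first.
    """

    char: CharEncoderConfig = field(default_factory=CharEncoderConfig)
    wd: int = 100
    d_model: int = 256
    heads: int = 8
    d_ff: int | None = None       # defaults to 2 * d_model
    layers: int = 2
    dropout: float = 0.0
    zero_char: bool = False       # ablation switch: zero character features
    constrained_decode: bool = False
    word_min_count: int = 2

    def __post_init__(self):
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model


class EventTagger:
    """End-to-end clinical event tagger."""

    def __init__(self, config: ModelConfig, schema: TagSchema,
                 word_vocab: dict[str, int], seed: int = 0):
        self.config = config
        self.schema = schema
        rng = np.random.default_rng(seed)
        self.char_encoder = CharEncoder(config.char, rng)
        self.word_embedder = LookupWordEmbedder(word_vocab, config.wd,
                                                seed=int(rng.integers(2 ** 31)))
        d_in = config.char.out_dim + config.wd
        scale = np.sqrt(2.0 / (d_in + config.d_model))
        self.W_p = Tensor(rng.normal(0.0, scale, size=(d_in, config.d_model)),
                          requires_grad=True)
        self.b_p = Tensor(np.zeros(config.d_model), requires_grad=True)
        self.encoder = TenerStack(
            TenerConfig(d_model=config.d_model, heads=config.heads,
                        d_ff=config.d_ff, layers=config.layers,
                        dropout=config.dropout),
            rng,
        )
        d_f = schema.d_f
        scale = np.sqrt(2.0 / (config.d_model + d_f))
        self.W_out = Tensor(rng.normal(0.0, scale, size=(config.d_model, d_f)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(d_f), requires_grad=True)
        self.crf = CrfParams(d_f, rng)

    @classmethod
    def build(cls, config: ModelConfig, schema: TagSchema,
              train_corpus: list[LabeledSentence], seed: int = 0) -> "EventTagger":
        vocab = build_word_vocab(train_corpus, min_count=config.word_min_count)
        return cls(config, schema, vocab, seed=seed)

    def parameters(self) -> list[Tensor]:
        return [
            *self.char_encoder.parameters(),
            *self.word_embedder.parameters(),
            self.W_p, self.b_p,
            *self.encoder.parameters(),
            self.W_out, self.b_out,
            *self.crf.parameters(),
        ]

    # -------------------------------------------------------------- forward
    def _forward_batch(self, batch_tokens: list[list[str]],
                       rng: np.random.Generator | None = None
                       ) -> tuple[Tensor, np.ndarray, np.ndarray]:
        """Emission scores for a padded batch: (B, L, d_f), mask, lengths."""
        if not batch_tokens or any(len(t) == 0 for t in batch_tokens):
            raise ValueError("empty sentence in batch")
        B = len(batch_tokens)
        lengths = np.array([len(t) for t in batch_tokens])
        L = int(lengths.max())
        flat = [tok for sent in batch_tokens for tok in sent]
        # gather flat per-word features into padded (B, L, .) matrices via an
        # index map; padding positions point at an appended all-zero row
        n_words = len(flat)
        idx = np.full(B * L, n_words, dtype=np.intp)
        pos = 0
        for b, sent in enumerate(batch_tokens):
            idx[b * L: b * L + len(sent)] = np.arange(pos, pos + len(sent))
            pos += len(sent)

        def scatter(flat_tensor: Tensor) -> Tensor:
            width = flat_tensor.shape[-1]
            padded = concat([flat_tensor, Tensor(np.zeros((1, width)))], axis=0)
            return padded[idx].reshape(B, L, width)

        Hc = scatter(self.char_encoder.embed_words(flat, rng=rng))
        if self.config.zero_char:
            Hc = Hc * 0.0
        Hw = scatter(self.word_embedder.embed(flat))
        H = concat([Hc, Hw], axis=-1)
        H = H @ self.W_p + self.b_p
        mask = np.arange(L)[None, :] < lengths[:, None]
        H = self.encoder(H, mask=mask, rng=rng)
        emissions = H @ self.W_out + self.b_out
        return emissions, mask, lengths

    def forward_features(self, tokens: list[str]) -> np.ndarray:
        """Emission score matrix (l, d_f) for one sentence, inference mode."""
        emissions, _, _ = self._forward_batch([list(tokens)])
        return emissions.data[0]

    def loss(self, batch: list[LabeledSentence],
             rng: np.random.Generator | None = None) -> Tensor:
        """Batched CRF negative log-likelihood (differentiable)."""
        emissions, _, lengths = self._forward_batch(
            [s.tokens for s in batch], rng=rng)
        L = emissions.shape[1]
        tags = np.zeros((len(batch), L), dtype=np.intp)
        for b, sent in enumerate(batch):
            tags[b, :len(sent)] = [self.schema.label_index(t) for t in sent.tags]
        return crf_nll_batched(emissions, tags, lengths, self.crf)

    def predict(self, sentences: list[LabeledSentence] | list[list[str]],
                batch_size: int = 32) -> list[list[str]]:
        """Viterbi-decoded BIOES tags for each sentence."""
        token_lists = [s.tokens if isinstance(s, LabeledSentence) else list(s)
                       for s in sentences]
        crf = self.crf
        if self.config.constrained_decode:
            pen_t, pen_s, pen_e = bioes_transition_penalty(self.schema)
            crf = CrfParams(self.schema.d_f)
            crf.transitions = Tensor(self.crf.transitions.data + pen_t)
            crf.start = Tensor(self.crf.start.data + pen_s)
            crf.stop = Tensor(self.crf.stop.data + pen_e)
        out: list[list[str]] = []
        for i in range(0, len(token_lists), batch_size):
            chunk = token_lists[i:i + batch_size]
            emissions, _, lengths = self._forward_batch(chunk)
            for b, n in enumerate(lengths):
                path = viterbi_decode(emissions.data[b, :n], crf)
                out.append([self.schema.labels[j] for j in path])
        return out

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        """Single-archive checkpoint: config JSON + every parameter array."""
        meta = {
            "config": asdict(self.config),
            "types": list(self.schema.types),
            "word_vocab": self.word_embedder.vocab,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "EventTagger":
        archive = np.load(path if str(path).endswith(".npz") else f"{path}")
        meta = json.loads(archive["meta"].tobytes().decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["char"] = CharEncoderConfig(**cfg_dict["char"])
        config = ModelConfig(**cfg_dict)
        model = cls(config, TagSchema(tuple(meta["types"])),
                    meta["word_vocab"], seed=0)
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"p{i}"]
        return model

    def copy_params(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_params(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()

    def predict_corpus(self, corpus: list[LabeledSentence]) -> list[LabeledSentence]:
        tag_lists = self.predict(corpus)
        return [LabeledSentence(list(s.tokens), tags)
                for s, tags in zip(corpus, tag_lists)]
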