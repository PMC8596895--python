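"""Relative-position multi-head self-attention (TENER-style) layers.

A vanilla Transformer's absolute sinusoidal positions lose direction
information once projected into query/key space, which hurts sequence
labeling.  The variant implemented here scores each query/key pair with a
*signed-offset* sinusoidal embedding R_{t-j} and two learned global biases::

    A[t, j] = Q_t K_j^T  +  Q_t R_{t-j}^T  +  u K_j^T  +  v R_{t-j}^T

Two deliberate departures from the vanilla Transformer are kept as designed:
keys are *unprojected* (K is a per-head slice of the input H) and attention
is *un-scaled* (no 1/sqrt(d_k)).  The sine components of R are odd in the
offset and the cosine components even, so the v-term distinguishes left from
right context.

The same layer stack serves both the character encoder (attention over the
characters of one word) and the sentence encoder (attention over tokens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "TenerConfig",
    "TenerLayer",
    "TenerStack",
    "rel_pos_embedding",
    "rel_pos_matrix",
    "attention_scores",
]

_NEG = -1e30  # additive mask value; exp(_NEG - max) underflows to exactly 0


def rel_pos_embedding(offset: int, d_k: int) -> np.ndarray:
    """Sinusoidal embedding of a signed offset, interleaved [sin, cos, ...].

    Component pairs use angular frequencies w_i = 10000^(-2i/d_k),
    i in [0, d_k/2).  Offset 0 maps to [0, 1, 0, 1, ...].
    """
    if d_k % 2 != 0:
        raise ValueError(f"d_k must be even, got {d_k}")
    i = np.arange(d_k // 2)
    omega = 10000.0 ** (-2.0 * i / d_k)
    angles = omega * offset
    out = np.empty(d_k)
    out[0::2] = np.sin(angles)
    out[1::2] = np.cos(angles)
    return out


def rel_pos_matrix(length: int, d_k: int) -> np.ndarray:
    """R_mat[t, j] = rel_pos_embedding(t - j); shape (length, length, d_k)."""
    offsets = np.arange(-(length - 1), length)
    table = np.stack([rel_pos_embedding(int(o), d_k) for o in offsets])
    idx = np.arange(length)[:, None] - np.arange(length)[None, :] + (length - 1)
    return table[idx]


@dataclass
class TenerConfig:
    d_model: int
    heads: int
    d_ff: int
    layers: int = 1
    dropout: float = 0.0
    layer_norm: bool = True

    def __post_init__(self):
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by heads={self.heads}"
            )
        if (self.d_model // self.heads) % 2 != 0:
            raise ValueError(
                "per-head width d_k must be even for the sin/cos embedding"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads


def _xavier(rng: np.random.Generator, *shape) -> Tensor:
    scale = np.sqrt(2.0 / sum(shape[-2:])) if len(shape) >= 2 else 0.1
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class TenerLayer:
    """One attention + feed-forward block with the relative-position score.

    Residual connections and post-layer-norm wrap both sub-layers by default
    (``layer_norm=False`` turns both off for algebraic unit tests — without
    them a multi-layer stack is untrainable in practice).
    """

    def __init__(self, config: TenerConfig, rng: np.random.Generator):
        d, n, d_k, d_ff = config.d_model, config.heads, config.d_k, config.d_ff
        self.config = config
        self.W_q = _xavier(rng, n, d, d_k)
        self.W_v = _xavier(rng, n, d, d_k)
        self.u = Tensor(rng.normal(0.0, 0.1, size=(n, d_k)), requires_grad=True)
        self.v = Tensor(rng.normal(0.0, 0.1, size=(n, d_k)), requires_grad=True)
        self.W_1 = _xavier(rng, d, d_ff)
        self.b_1 = Tensor(np.zeros(d_ff), requires_grad=True)
        self.W_2 = _xavier(rng, d_ff, d)
        self.b_2 = Tensor(np.zeros(d), requires_grad=True)
        if config.layer_norm:
            self.ln1_g = Tensor(np.ones(d), requires_grad=True)
            self.ln1_b = Tensor(np.zeros(d), requires_grad=True)
            self.ln2_g = Tensor(np.ones(d), requires_grad=True)
            self.ln2_b = Tensor(np.zeros(d), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        params = [self.W_q, self.W_v, self.u, self.v,
                  self.W_1, self.b_1, self.W_2, self.b_2]
        if self.config.layer_norm:
            params += [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
        return params

    # ------------------------------------------------------------------ core
    def _scores(self, H: Tensor, head: int, rel: np.ndarray,
                mask: np.ndarray | None) -> Tensor:
        """Score matrix A for one head; H is (..., L, d), rel is (L, L, d_k)."""
        d_k = self.config.d_k
        L = H.shape[-2]
        Q = H @ self.W_q[head]                                   # (..., L, d_k)
        K = H[..., head * d_k:(head + 1) * d_k]                  # unprojected
        term_qk = Q @ K.swapaxes(-1, -2)                         # (..., L, L)
        Qx = Q.reshape(*Q.shape[:-1], 1, d_k)
        term_qr = (Qx * Tensor(rel)).sum(axis=-1)                # (..., L, L)
        uk = (K * self.u[head]).sum(axis=-1)                     # (..., L)
        term_uk = uk.reshape(*uk.shape[:-1], 1, L)
        term_vr = (self.v[head] * Tensor(rel)).sum(axis=-1)      # (L, L)
        A = term_qk + term_qr + term_uk + term_vr
        if mask is not None:
            pad = np.where(mask, 0.0, _NEG)                      # (..., L)
            A = A + pad[..., None, :]
        return A

    def _layer_norm(self, X: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
        mu = X.mean(axis=-1, keepdims=True)
        centered = X - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * (var + 1e-5) ** -0.5 * gain + bias

    def _dropout(self, X: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if p <= 0.0 or rng is None:
            return X
        keep = rng.random(X.shape) >= p
        return X * (keep / (1.0 - p))

    def __call__(self, H: Tensor, mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Apply the block; mask is a boolean (..., L) array, False = padding."""
        cfg = self.config
        L = H.shape[-2]
        rel = rel_pos_matrix(L, cfg.d_k)
        heads = []
        for h in range(cfg.heads):
            A = self._scores(H, h, rel, mask)
            attn = A.softmax(axis=-1)
            V = H @ self.W_v[h]
            heads.append(attn @ V)
        X = concat(heads, axis=-1)
        X = self._dropout(X, rng)
        if cfg.layer_norm:
            X = self._layer_norm(H + X, self.ln1_g, self.ln1_b)
        else:
            X = H + X
        F = (X @ self.W_1 + self.b_1).relu() @ self.W_2 + self.b_2
        F = self._dropout(F, rng)
        if cfg.layer_norm:
            out = self._layer_norm(X + F, self.ln2_g, self.ln2_b)
        else:
            out = X + F
        if mask is not None:
            out = out * mask[..., None].astype(float)  # zero padded rows
        return out


class TenerStack:
    """A stack of ``config.layers`` identical-shape TENER blocks."""

    def __init__(self, config: TenerConfig, rng: np.random.Generator):
        self.config = config
        self.layers = [TenerLayer(config, rng) for _ in range(config.layers)]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, H: Tensor, mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers:
            H = layer(H, mask=mask, rng=rng)
        return H


def attention_scores(H: np.ndarray, layer: TenerLayer, head: int,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Pre-softmax score matrix of one head on a plain array (for inspection)."""
    L = H.shape[-2]
    rel = rel_pos_matrix(L, layer.config.d_k)
    return layer._scores(Tensor(H), head, rel, mask).data
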