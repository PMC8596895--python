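"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package (relative-position attention encoder + linear-chain
CRF) needs gradients of a scalar loss with respect to a few dozen parameter
arrays.  No autograd library is available in the target environment, so this
module provides a small tape-based ``Tensor`` with exactly the primitives the
model uses: broadcasting arithmetic, matmul, relu, exp/log, axis reductions
(sum / max / logsumexp), reshape/transpose/concat and integer-array gather.

All arrays are float64; at desk scale the extra precision is free and makes
the finite-difference tests tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order topological sort
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                order.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._acc(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g):
            self._acc(g * e * self.data ** (e - 1.0))

        return Tensor(self.data ** e, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._acc(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._acc(_unbroadcast(gb, other.shape))

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=bwd)

    # ------------------------------------------------------------ nonlinear
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._acc(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._acc(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._acc(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient stays well-defined
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(g * mask)

        return Tensor(out_data if keepdims else out_data.squeeze(axis),
                      parents=(self,), backward=bwd)

    def logsumexp(self, axis: int, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        softmax = e / s

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(g * softmax)

        return Tensor(out_data if keepdims else out_data.squeeze(axis),
                      parents=(self,), backward=bwd)

    def softmax(self, axis: int = -1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._acc(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._acc(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g):
            self._acc(g.swapaxes(a, b))

        return Tensor(self.data.swapaxes(a, b), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._acc(acc)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # ------------------------------------------------------------------ misc
    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._acc(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, i, axis=axis))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


class SGD:
    """SGD with classical momentum and global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], momentum: float = 0.9, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        for p, v, g in zip(self.params, self._velocity, grads):
            v *= self.momentum
            v += g
            p.data -= lr * v
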