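"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine providing exactly the tensor operations the
sequence-labeling layers need: broadcasting arithmetic, (batched) matmul,
the usual pointwise nonlinearities, reductions including a numerically
stable ``logsumexp``, concatenation / slicing / padding, and an embedding
lookup with scatter-add gradients.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` on a scalar output.

The engine is deliberately minimal: float64 only, no in-place autograd, no
higher-order derivatives.  Graph construction can be suspended with
:func:`no_grad` for inference.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "tsum",
    "tmean",
    "logsumexp",
    "softmax",
    "maximum",
    "concat",
    "stack",
    "pad",
    "reshape",
    "swapaxes",
    "embedding",
    "AdamW",
    "clip_grad_norm",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager that disables graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A float64 NumPy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # Make ndarray binary ops defer to our reflected dunders.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable | None = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", requires_grad=True" if self.requires_grad else ""
        return f"Tensor({self.data!r}{flag})"

    # -- graph traversal -----------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output, accumulating ``.grad``."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, int]] = [(self, 0)]
        # Iterative DFS: recurrent graphs can be thousands of nodes deep.
        while stack:
            node, idx = stack.pop()
            if idx == 0:
                if id(node) in seen:
                    continue
                seen.add(id(node))
            if idx < len(node._parents):
                stack.append((node, idx + 1))
                stack.append((node._parents[idx], 0))
            else:
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if g.shape != parent.data.shape:
                    g = g.reshape(parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _from_op(data: np.ndarray, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    parents = tuple(parents)
    requires = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=requires)
    if requires:
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _from_op(out, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _from_op(out, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def bw(g):
        return (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
        )

    return _from_op(out, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def bw(g):
        ad, bd = a.data, b.data
        a2 = ad[None, :] if ad.ndim == 1 else ad
        b2 = bd[:, None] if bd.ndim == 1 else bd
        g2 = g
        if ad.ndim == 1 and bd.ndim == 1:
            g2 = g.reshape(1, 1)
        elif ad.ndim == 1:
            g2 = np.expand_dims(g, -2)
        elif bd.ndim == 1:
            g2 = np.expand_dims(g, -1)
        ga = np.matmul(g2, np.swapaxes(b2, -1, -2))
        gb = np.matmul(np.swapaxes(a2, -1, -2), g2)
        ga = _unbroadcast(ga, a2.shape).reshape(ad.shape)
        gb = _unbroadcast(gb, b2.shape).reshape(bd.shape)
        return ga, gb

    return _from_op(out, (a, b), bw)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        return (g * out * (1.0 - out),)

    return _from_op(out, (x,), bw)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)

    def bw(g):
        return (g * (1.0 - out * out),)

    return _from_op(out, (x,), bw)


def relu(x) -> Tensor:
    x = as_tensor(x)
    out = np.maximum(x.data, 0.0)

    def bw(g):
        return (g * (x.data > 0.0),)

    return _from_op(out, (x,), bw)


def exp(x) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)

    def bw(g):
        return (g * out,)

    return _from_op(out, (x,), bw)


def log(x) -> Tensor:
    x = as_tensor(x)
    out = np.log(x.data)

    def bw(g):
        return (g / x.data,)

    return _from_op(out, (x,), bw)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            return (np.broadcast_to(g, x.data.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, x.data.shape).copy(),)

    return _from_op(out, (x,), bw)


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def logsumexp(x, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` with softmax gradient."""
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out = np.log(s) + m
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bw(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return (gg * (e / s),)

    return _from_op(out, (x,), bw)


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    return exp(add(x, mul(logsumexp(x, axis=axis, keepdims=True), -1.0)))


def maximum(a, b) -> Tensor:
    """Elementwise max; subgradient routes ties to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)
    take_a = a.data >= b.data

    def bw(g):
        return (
            _unbroadcast(g * take_a, a.data.shape),
            _unbroadcast(g * (~take_a), b.data.shape),
        )

    return _from_op(out, (a, b), bw)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    datas = [t.data for t in ts]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _from_op(out, ts, bw)


def stack(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in ts], axis=axis)

    def bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(ts)))

    return _from_op(out, ts, bw)


def pad(x, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` follows :func:`numpy.pad` conventions."""
    x = as_tensor(x)
    out = np.pad(x.data, pad_width, mode="constant")
    slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, x.data.shape))

    def bw(g):
        return (g[slices],)

    return _from_op(out, (x,), bw)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    out = x.data.reshape(shape)

    def bw(g):
        return (g.reshape(x.data.shape),)

    return _from_op(out, (x,), bw)


def swapaxes(x, a: int, b: int) -> Tensor:
    x = as_tensor(x)
    out = np.swapaxes(x.data, a, b)

    def bw(g):
        return (np.swapaxes(g, a, b),)

    return _from_op(out, (x,), bw)


def getitem(x, idx) -> Tensor:
    x = as_tensor(x)
    out = x.data[idx]

    def bw(g):
        z = np.zeros_like(x.data)
        np.add.at(z, idx, g)
        return (z,)

    return _from_op(out, (x,), bw)


def embedding(table: Tensor, idx) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add gradient into the table."""
    table = as_tensor(table)
    idx = np.asarray(idx)
    out = table.data[idx]

    def bw(g):
        z = np.zeros_like(table.data)
        np.add.at(z, idx, g)
        return (z,)

    return _from_op(out, (table,), bw)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter).

    The decay term is applied directly to the parameter, not folded into the
    gradient, so it is active even when a parameter's gradient is zero.
    """

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


def clip_grad_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm
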