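"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the graph-attention layers need: dense
matmul, broadcasting elementwise arithmetic, row gather/scatter (for
edge-wise message passing), the usual activations, and a numerically
stable binary cross-entropy. Gradients are accumulated by a topological
backward pass over the recorded operation graph.

Everything is float64 and fully deterministic: no threading, no in-place
aliasing of parameter buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "add", "sub", "mul", "div", "neg", "matmul",
    "gather", "scatter_sum", "exp", "log", "leaky_relu", "elu", "sigmoid",
    "softplus", "concat", "tsum", "backward", "Adam", "segment_max",
]


class Tensor:
    """A node in the computation graph: value, gradient slot, backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    g = np.asarray(g, dtype=np.float64)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


def add(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = Tensor(a.data + b.data, (a, b))

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    out._backward = bwd
    return out


def neg(a) -> Tensor:
    a = constant(a)
    out = Tensor(-a.data, (a,))
    out._backward = lambda g: _accum(a, -g)
    return out


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = Tensor(a.data * b.data, (a, b))

    def bwd(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    out._backward = bwd
    return out


def div(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = Tensor(a.data / b.data, (a, b))

    def bwd(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data ** 2))

    out._backward = bwd
    return out


def matmul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bwd
    return out


def gather(a, idx) -> Tensor:
    """Select rows ``a[idx]`` (idx is a fixed integer array)."""
    a = constant(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.data[idx], (a,))

    def bwd(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            _accum(a, acc)

    out._backward = bwd
    return out


def scatter_sum(a, idx, n: int) -> Tensor:
    """Row-wise segment sum: out[k] = sum over rows i with idx[i] == k of a[i]."""
    a = constant(a)
    idx = np.asarray(idx, dtype=np.intp)
    shape = (n,) + a.data.shape[1:]
    data = np.zeros(shape, dtype=np.float64)
    np.add.at(data, idx, a.data)
    out = Tensor(data, (a,))
    out._backward = lambda g: _accum(a, g[idx])
    return out


def segment_max(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Plain-numpy segment max (used as a stop-gradient softmax shift)."""
    out = np.full((n,) + x.shape[1:], -np.inf)
    np.maximum.at(out, np.asarray(idx, dtype=np.intp), x)
    return out


def exp(a) -> Tensor:
    a = constant(a)
    data = np.exp(a.data)
    out = Tensor(data, (a,))
    # capture the value, not the Tensor: keeps the graph cycle-free so
    # refcounting frees each epoch's graph promptly
    out._backward = lambda g: _accum(a, g * data)
    return out


def log(a) -> Tensor:
    a = constant(a)
    out = Tensor(np.log(a.data), (a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = constant(a)
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), (a,))
    out._backward = lambda g: _accum(a, g * np.where(a.data > 0, 1.0, slope))
    return out


def elu(a, alpha: float = 1.0) -> Tensor:
    a = constant(a)
    neg_part = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out = Tensor(np.where(a.data > 0, a.data, neg_part), (a,))
    out._backward = lambda g: _accum(
        a, g * np.where(a.data > 0, 1.0, neg_part + alpha)
    )
    return out


def sigmoid(a) -> Tensor:
    a = constant(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def softplus(a) -> Tensor:
    """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
    a = constant(a)
    out = Tensor(np.logaddexp(0.0, a.data), (a,))
    out._backward = lambda g: _accum(a, g / (1.0 + np.exp(-a.data)))
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [constant(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = bwd
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = constant(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bwd(g):
        g = np.asarray(g, dtype=np.float64)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = bwd
    return out


def backward(root: Tensor):
    """Run the backward pass from ``root`` (a scalar) through the graph."""
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


class Adam:
    """Adam with decoupled weight decay, operating on a list of Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data = p.data * (1 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
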