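"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the message-passing encoders need:
dense affine maps, elementwise nonlinearities, gather / scatter-add by
integer index (for neighborhood aggregation and readout), concatenation,
and a numerically stable binary cross-entropy on logits. Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g


def param(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def const(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(g, shape):
    """Reduce gradient g back to `shape` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, scale(b, -1.0))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * c)

    out._backward = bw
    return out


def add_const(a: Tensor, c) -> Tensor:
    out = Tensor(a.data + c, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(s, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * (1.0 - t * t))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Rows of a selected by integer index (with repetition)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], (a,))

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

    out._backward = bw
    return out


def segment_sum(a: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-add rows of `a` into `n_segments` buckets given by `seg`."""
    seg = np.asarray(seg, dtype=np.int64)
    data = np.zeros((n_segments,) + a.data.shape[1:])
    np.add.at(data, seg, a.data)
    out = Tensor(data, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g[seg])

    out._backward = bw
    return out


def spmm(M, MT, a: Tensor) -> Tensor:
    """Sparse @ dense: out = M @ a, with MT = M.T prebuilt for backward.

    One sparse operator covers gather (row-selection matrix), scatter-add
    (segment-sum matrix) and neighbor aggregation (adjacency matrix).
    """
    out = Tensor(M @ a.data, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(MT @ g)

    out._backward = bw
    return out


def permute_rows(a: Tensor, perm: np.ndarray, inv_perm: np.ndarray) -> Tensor:
    """out[i] = a[perm[i]]; backward routes through the inverse permutation."""
    out = Tensor(a.data[perm], (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g[inv_perm])

    out._backward = bw
    return out


def rowscale(a: Tensor, w: np.ndarray) -> Tensor:
    """Multiply each row of `a` by a constant per-row weight."""
    w = np.asarray(w, dtype=np.float64).reshape(-1, 1)
    out = Tensor(a.data * w, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * w)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (stable log-sum-exp form)."""
    y = np.asarray(labels, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    # loss = max(z,0) - z*y + log(1+exp(-|z|))
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.array(loss.mean()), (logits,))
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def bw(g):
        if logits.requires_grad:
            logits._accum(g * (s - y) / y.size)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer with bias-corrected first/second moments."""

    def __init__(self, params: list[Tensor], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
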