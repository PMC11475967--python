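"""Minimal vectorized reverse-mode automatic differentiation.

Supports exactly the operations the message-passing network and the MLP
baseline need: affine maps, ReLU, concatenation, row gather, segment
(scatter) sum/mean, and mean-absolute-error style reductions. Everything
is float64 numpy, single-threaded, and therefore bitwise deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var", "matmul", "add", "sub", "scale", "relu", "concat",
    "gather", "segment_sum", "segment_mean", "mean_abs", "Adam",
]


class Var:
    """A node in the computation tape: an ndarray plus a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients of self w.r.t. every ancestor (self scalar)."""
        # iterative DFS post-order: parents end up before their consumers
        order: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for v in order:
            v.grad = None
        self.grad = np.ones_like(self.data)
        for v in reversed(order):
            if v._backward is not None and v.grad is not None:
                v._backward(v.grad)


def _acc(v: Var, g: np.ndarray) -> None:
    if v.grad is None:
        v.grad = np.zeros_like(v.data)
    v.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Var, b: Var) -> Var:
    out_data = a.data @ b.data

    def bwd(g):
        _acc(a, g @ b.data.T)
        _acc(b, a.data.T @ g)

    return Var(out_data, (a, b), bwd)


def add(a: Var, b: Var) -> Var:
    out_data = a.data + b.data

    def bwd(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return Var(out_data, (a, b), bwd)


def sub(a: Var, b: Var) -> Var:
    out_data = a.data - b.data

    def bwd(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, -_unbroadcast(g, b.data.shape))

    return Var(out_data, (a, b), bwd)


def scale(a: Var, c: float) -> Var:
    out_data = a.data * c

    def bwd(g):
        _acc(a, g * c)

    return Var(out_data, (a,), bwd)


def relu(a: Var) -> Var:
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        _acc(a, g * mask)

    return Var(out_data, (a,), bwd)


def concat(parts: list[Var], axis: int = 1) -> Var:
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _acc(p, g[tuple(sl)])

    return Var(out_data, tuple(parts), bwd)


def gather(a: Var, idx: np.ndarray) -> Var:
    """Row gather: out[i] = a[idx[i]]."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _acc(a, ga)

    return Var(out_data, (a,), bwd)


def segment_sum(a: Var, seg: np.ndarray, n_segments: int) -> Var:
    """out[s] = sum of rows of a whose segment id is s. Empty segments are 0."""
    seg = np.asarray(seg, dtype=np.intp)
    out_data = np.zeros((n_segments, a.data.shape[1]))
    np.add.at(out_data, seg, a.data)

    def bwd(g):
        _acc(a, g[seg])

    return Var(out_data, (a,), bwd)


def segment_mean(a: Var, seg: np.ndarray, n_segments: int) -> Var:
    """Like segment_sum but divided by segment size; empty segments stay 0."""
    seg = np.asarray(seg, dtype=np.intp)
    counts = np.bincount(seg, minlength=n_segments).astype(np.float64)
    safe = np.where(counts > 0, counts, 1.0)[:, None]
    out_data = np.zeros((n_segments, a.data.shape[1]))
    np.add.at(out_data, seg, a.data)
    out_data /= safe

    def bwd(g):
        _acc(a, (g / safe)[seg])

    return Var(out_data, (a,), bwd)


def mean_abs(a: Var) -> Var:
    """Mean absolute value of all entries (MAE when a holds residuals)."""
    n = a.data.size
    out_data = np.abs(a.data).mean()
    sgn = np.sign(a.data)

    def bwd(g):
        _acc(a, g * sgn / n)

    return Var(out_data, (a,), bwd)


class Adam:
    """Adaptive-moment gradient descent over a list of Var parameters."""

    def __init__(self, params: list[Var], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
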