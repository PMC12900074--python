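"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The equivariant scorer is small (a few thousand parameters, desk-scale graphs),
so it runs on a deliberately compact tape-based autodiff core rather than a deep
learning framework.  Only the operations the scorer needs are implemented:
elementwise arithmetic with broadcasting, matmul, relu / sigmoid / exp / log /
sqrt, reductions, concatenation, indexing and index-add scatter.

Gradient correctness is enforced by finite-difference checks in the test suite.
All arrays are float64 internally; the scorer's public tolerances are stated for
32-bit-equivalent precision.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # make ndarray.__mul__ defer to Tensor.__rmul__

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ b.data.swapaxes(-1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accum(g * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g, a=self, r=r):
            if a.requires_grad:
                a._accum(g * 0.5 / r)

        return Tensor._make(r, (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def index_add(self, n_rows: int, index: np.ndarray) -> "Tensor":
        """Scatter-add rows of self into an (n_rows, …) output by `index`."""
        index = np.asarray(index)
        out_data = np.zeros((n_rows,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, index, self.data)

        def backward(g, a=self, index=index):
            if a.requires_grad:
                a._accum(g[index])

        return Tensor._make(out_data, (self,), backward)

    def softmax_rows(self) -> "Tensor":
        """Row-wise softmax over the last axis, built from primitive ops."""
        shifted = self - Tensor(self.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=-1, keepdims=True)

    # -- backward pass --------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offsets=offsets):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def grad_check(fn, params: list[Tensor], eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    `fn` maps the current parameter values to a scalar Tensor.
    """
    out = fn()
    for p in params:
        p.grad = None
    out.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            f_plus = float(fn().data)
            flat[i] = orig - eps
            f_minus = float(fn().data)
            flat[i] = orig
            numeric = (f_plus - f_minus) / (2 * eps)
            denom = max(abs(numeric), abs(analytic.ravel()[i]), 1e-8)
            worst = max(worst, abs(numeric - analytic.ravel()[i]) / denom)
    return worst
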