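"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's models (gated recurrent nets, additive attention, a small
text-CNN) are defined directly from their update equations, so all that is
needed from an autodiff engine is a handful of dense ops with broadcasting,
an embedding gather, a 1-d convolution and a max-pool.  Graphs are built
eagerly; :meth:`Tensor.backward` runs a topological sweep.  Gradient
computation can be switched off globally with :func:`no_grad` for cheap
inference passes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "stack",
    "embedding",
    "conv1d_same",
    "scatter_rows",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=[p for p in parents if p.requires_grad],
                      backward=backward if req else None)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order (graphs from long sequences can be deep)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-self.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(self.data / other.data, (a, b), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(self.data @ other.data, (a, b), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def sigmoid(self):
        out = np.exp(-np.logaddexp(0.0, -self.data))  # overflow-safe
        a = self

        def bwd(g):
            a._accumulate(g * out * (1.0 - out))

        return Tensor._make(out, (a,), bwd)

    def tanh(self):
        out = np.tanh(self.data)
        a = self

        def bwd(g):
            a._accumulate(g * (1.0 - out ** 2))

        return Tensor._make(out, (a,), bwd)

    def relu(self):
        out = np.maximum(self.data, 0.0)
        a = self

        def bwd(g):
            a._accumulate(g * (self.data > 0.0))

        return Tensor._make(out, (a,), bwd)

    def exp(self):
        out = np.exp(self.data)
        a = self

        def bwd(g):
            a._accumulate(g * out)

        return Tensor._make(out, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (a,), bwd)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes through only inside the range."""
        a = self
        inside = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            a._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (a,), bwd)

    # -- reductions / shape --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                ge = np.expand_dims(g, axis) if not keepdims else g
                a._accumulate(np.broadcast_to(ge, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(self.data, axis=axis)
        out = np.max(self.data, axis=axis, keepdims=keepdims)

        def bwd(g):
            ge = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), ge, axis=axis)
            a._accumulate(grad)

        return Tensor._make(out, (a,), bwd)

    def reshape(self, *shape):
        a = self
        orig = self.data.shape

        def bwd(g):
            a._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx, g)
            a._accumulate(grad)

        return Tensor._make(self.data[idx], (a,), bwd)

    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        ex = np.exp(x - m)
        lse = np.log(ex.sum(axis=axis, keepdims=True)) + m
        out = x - lse
        soft = ex / ex.sum(axis=axis, keepdims=True)
        a = self

        def bwd(g):
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out, (a,), bwd)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (always requires grad when autograd is enabled)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # survives no_grad construction


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tensors, bwd)


def stack(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(data, tensors, bwd)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def bwd(g):
        grad = np.zeros_like(table.data)
        np.add.at(grad, ids, g)
        table._accumulate(grad)

    return Tensor._make(table.data[ids], (table,), bwd)


def scatter_rows(values: Tensor, rows: np.ndarray, size: int) -> Tensor:
    """Scatter a vector of per-row values into a length-``size`` vector.

    ``out[rows[i]] += values[i]``; used to accumulate per-position log
    probabilities into per-sequence totals.
    """
    rows = np.asarray(rows)
    data = np.zeros(size)
    np.add.at(data, rows, values.data)

    def bwd(g):
        values._accumulate(g[rows])

    return Tensor._make(data, (values,), bwd)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1-d convolution over the length axis with same-padding.

    x: (B, L, C_in); weight: (K, C_in, C_out); bias: (C_out,).
    Implemented by im2col so forward and backward are single matmuls.
    """
    B, L, Cin = x.data.shape
    K, _, Cout = weight.data.shape
    left = K // 2
    right = K - 1 - left
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    # (B, L, K, Cin) windows
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, L, K * Cin)
    w2 = weight.data.reshape(K * Cin, Cout)
    out = cols @ w2 + bias.data

    def bwd(g):
        if weight.requires_grad:
            gw = cols.reshape(-1, K * Cin).T @ g.reshape(-1, Cout)
            weight._accumulate(gw.reshape(K, Cin, Cout))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = (g @ w2.T).reshape(B, L, K, Cin)
            gx = np.zeros_like(xp)
            for k in range(K):
                gx[:, k:k + L, :] += gcols[:, :, k, :]
            x._accumulate(gx[:, left:left + L, :])

    return Tensor._make(out, (x, weight, bias), bwd)
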