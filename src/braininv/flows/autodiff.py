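"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train conditional normalizing flows: a ``Tensor``
wrapping an ndarray, elementwise and matrix primitives with broadcasting,
and a topological-order backward pass. Gradients are accumulated in
``Tensor.grad``. Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "softplus", "take_along"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, prev, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- primitives -----------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (
                self._accum(g * other.data),
                other._accum(g * self.data),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (
                self._accum(g / other.data),
                other._accum(-g * self.data / other.data**2),
            )
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (
                self._accum(np.asarray(g) @ np.swapaxes(other.data, -1, -2)),
                other._accum(np.swapaxes(self.data, -1, -2) @ np.asarray(g)),
            )
        return out

    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def square(self):
        out = self._make(self.data**2, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(2.0 * g * self.data)
        return out

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = self._make(out_data, (self,), None)
        if out.requires_grad:
            def backward(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = backward
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def softplus(x: Tensor, beta: float = 1.0) -> Tensor:
    """log(1 + exp(beta x)) / beta as a single stable primitive."""
    z = beta * x.data
    val = (np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))) / beta
    out = Tensor(val)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-z))
        out._prev = (x,)
        out._backward = lambda g: x._accum(np.asarray(g) * sig)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def take_along(x: Tensor, idx: np.ndarray, axis: int = -1) -> Tensor:
    """Differentiable take_along_axis with integer index array."""
    out = Tensor(np.take_along_axis(x.data, idx, axis=axis))
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        def backward(g):
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx, 0.0, axis=axis)  # shape check
            # scatter-add: put_along_axis overwrites, so accumulate manually
            grid = np.indices(idx.shape)
            index = list(grid)
            index[axis] = idx
            np.add.at(full, tuple(index), np.asarray(g))
            x._accum(full)
        out._prev = (x,)
        out._backward = backward
    return out
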