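"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the point-cloud classifiers are built on: a
``Tensor`` wrapping an ``ndarray`` plus the handful of differentiable
operations the architectures need (broadcast arithmetic, batched matmul,
reductions, gather/scatter indexing, concatenation, softmax). Gradients are
accumulated by a topological backward sweep from a scalar loss.

The op set is deliberately small; anything not listed here is composed from
these primitives in :mod:`cloudshape.nn` and the model modules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "index_points",
    "softmax",
    "logsumexp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _lift_like(self, x) -> "Tensor":
        """Lift ``x`` to a Tensor; bare Python scalars adopt our dtype so
        float32 graphs are not silently promoted to float64."""
        if isinstance(x, Tensor):
            return x
        if isinstance(x, (int, float)):
            return Tensor(np.asarray(x, dtype=self.data.dtype))
        return Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift_like(other)
        data = self.data + other.data
        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        return Tensor._node(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift_like(other))

    def __rsub__(self, other):
        return self._lift_like(other) + (-self)

    def __mul__(self, other):
        other = self._lift_like(other)
        data = self.data * other.data
        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        return Tensor._node(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift_like(other)
        data = self.data / other.data
        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return Tensor._node(data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift_like(other) / self

    def __pow__(self, exponent: float):
        data = self.data ** exponent
        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)
        return Tensor._node(data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        data = self.data @ other.data
        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)
        return Tensor._node(data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        data = np.exp(self.data)
        return Tensor._node(data, (self,), lambda g: (g * data,))

    def log(self):
        def backward(g):
            return (g / self.data,)
        return Tensor._node(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)
        return Tensor._node(self.data * factor, (self,), lambda g: (g * factor,))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)
        return Tensor._node(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = data if keepdims else np.expand_dims(data, axis)
        mask = (self.data == expanded)
        # split gradient among exact ties so the op stays well-defined
        count = mask.sum(axis=axis, keepdims=True)
        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * (g / count),)
        return Tensor._node(data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        data = self.data.reshape(shape)
        return Tensor._node(data, (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)
        return Tensor._node(data, (self,), lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        data = self.data.swapaxes(a, b)
        return Tensor._node(data, (self,), lambda g: (g.swapaxes(a, b),))

    def broadcast_to(self, shape):
        shape = tuple(shape)
        data = np.broadcast_to(self.data, shape)
        src = self.shape
        return Tensor._node(data, (self,), lambda g: (_unbroadcast(g, src),))

    def __getitem__(self, key):
        data = self.data[key]
        shape = self.shape
        dtype = self.data.dtype
        def backward(g):
            full = np.zeros(shape, dtype=dtype)
            np.add.at(full, key, g)
            return (full,)
        return Tensor._node(data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would overflow recursion
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
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                parent.grad = g if parent.grad is None else parent.grad + g


# -- free functions -----------------------------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._node(data, tensors, backward)


def index_points(points: Tensor, idx: np.ndarray) -> Tensor:
    """Batched gather: ``out[b, ...] = points[b, idx[b, ...]]``.

    ``points`` has shape (B, N, *F) and ``idx`` integer shape (B, *I);
    the result has shape (B, *I, *F). Gradients scatter-add back.
    """
    points = Tensor._lift(points)
    idx = np.asarray(idx)
    B = points.shape[0]
    b_idx = np.arange(B).reshape((B,) + (1,) * (idx.ndim - 1))
    b_idx = np.broadcast_to(b_idx, idx.shape)
    data = points.data[b_idx, idx]
    shape = points.shape
    dtype = points.data.dtype
    def backward(g):
        full = np.zeros(shape, dtype=dtype)
        np.add.at(full, (b_idx, idx), g)
        return (full,)
    return Tensor._node(data, (points,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # subtracting the (constant) max leaves both value and gradient unchanged
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(t.data.max(axis=axis, keepdims=True))
    return (t - m).exp().sum(axis=axis, keepdims=True).log() + m
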