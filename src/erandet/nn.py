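"""Reverse-mode automatic differentiation over numpy, plus the small set of
layers and the Adam optimizer the models in this package need.

The engine is deliberately minimal: a :class:`Tensor` wraps a float64
ndarray, records its parents and a backward closure, and ``backward()``
runs the chain rule over a topological ordering.  float64 keeps the
finite-difference gradient checks in the test suite meaningful.

All randomness is injected through ``numpy.random.Generator`` instances;
nothing here touches global RNG state, so runs are reproducible from a
single seed on one thread.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "Linear",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data
        a, b = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            if a.ndim == 1:  # (k,) @ (k, m)
                return (np.matmul(b, g), np.outer(a, g))
            if b.ndim == 1:  # (..., k) @ (k,)
                ga = np.expand_dims(g, -1) * b
                gb = np.matmul(np.swapaxes(a, -1, -2), np.expand_dims(g, -1))[..., 0]
                if gb.ndim > 1:
                    gb = gb.sum(axis=tuple(range(gb.ndim - 1)))
                return (ga, gb)
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            if ga.ndim > a.ndim:
                ga = ga.sum(axis=tuple(range(ga.ndim - a.ndim)))
            if gb.ndim > b.ndim:
                gb = gb.sum(axis=tuple(range(gb.ndim - b.ndim)))
            return (ga, gb)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data * out_data),)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        # numerically stable split form of 1/(1+exp(-x))
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        mask = (self.data > 0).astype(np.float64)

        def backward(g):
            return (g * mask,)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)
        a = self.data

        def backward(g):
            return (g / a,)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis] if isinstance(axis, int) else math.prod(
                self.data.shape[a] for a in axis
            )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax (ties broken
        deterministically)."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g_exp = np.expand_dims(g, axis)
            else:
                g_exp = g
            grad = np.zeros(shape)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g_exp, axis=axis)
            return (grad,)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        axes = axes or None
        out_data = self.data.transpose(axes)
        if axes is None:
            inv = None
        else:
            inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        shape = self.data.shape

        def backward(g):
            grad = np.zeros(shape)
            np.add.at(grad, key, g)
            return (grad,)

        return Tensor._make(out_data, (self,), backward)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=np.float64).copy()
                else:
                    parent.grad += g


# -- free functions ---------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(out_data, tuple(tensors), backward)


def sigmoid(x: Tensor) -> Tensor:
    return Tensor.as_tensor(x).sigmoid()


def tanh(x: Tensor) -> Tensor:
    return Tensor.as_tensor(x).tanh()


def relu(x: Tensor) -> Tensor:
    return Tensor.as_tensor(x).relu()


# -- layers & optimizer ------------------------------------------------------

class Linear:
    """Affine map with Glorot-uniform weights and zero bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
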