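"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration networks in this package are small multi-layer perceptrons
with max-aggregation; this module provides exactly the operations they need
(broadcasted arithmetic, batched matmul, ReLU/tanh, reductions with
subgradient routing for max/min) plus an Adam optimizer.  Gradients are
accumulated by topological sweep over the recorded graph.

Only ``Tensor`` leaves created with ``requires_grad=True`` receive ``.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def backward(self, grad=None):
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: keeps dtype
            return Tensor(self.data + other, parents=(self,),
                          backward=lambda g: (g,))
        other = self._lift(other)
        out_data = self.data + other.data
        return Tensor(out_data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.shape),
                                          _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.data * other, parents=(self,),
                          backward=lambda g: (g * other,))
        other = self._lift(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.data / other, parents=(self,),
                          backward=lambda g: (g / other,))
        other = self._lift(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (
                          _unbroadcast(g / other.data, self.shape),
                          _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bw(g):
            ga = _unbroadcast(np.matmul(g, b.swapaxes(-1, -2)), a.shape)
            gb = _unbroadcast(np.matmul(a.swapaxes(-1, -2), g), b.shape)
            return ga, gb

        return Tensor(np.matmul(a, b), parents=(self, other), backward=bw)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,),
                      backward=lambda g: (g * mask,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * (1 - out ** 2),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g / (2 * out),))

    def square(self):
        return self * self

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along `axis`; the subgradient is routed to the FIRST argmax."""
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = np.take_along_axis(self.data, idx, axis=axis)

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros(self.shape, dtype=self.data.dtype)
            np.put_along_axis(full, idx, g, axis=axis)
            return (full,)

        return Tensor(out if keepdims else np.squeeze(out, axis), parents=(self,),
                      backward=bw)

    def min(self, axis: int, keepdims: bool = False):
        return -((-self).max(axis=axis, keepdims=keepdims))

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: (g.reshape(old),))

    def swapaxes(self, a, b):
        return Tensor(self.data.swapaxes(a, b), parents=(self,),
                      backward=lambda g: (g.swapaxes(a, b),))

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros(self.shape, dtype=self.data.dtype)
            np.add.at(full, key, g)
            return (full,)

        return Tensor(self.data[key], parents=(self,), backward=bw)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    out = (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
    if not keepdims:
        out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
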