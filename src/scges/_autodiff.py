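"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the conditional negative-binomial
autoencoder needs: affine maps, ReLU/softplus, row-wise (log-)softmax,
log-gamma, elementwise arithmetic with broadcasting, gathers and
reductions. Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(
            (p, vjp) for p, vjp in parents if p.requires_grad
        )
        self.requires_grad = requires_grad or bool(self._parents)

    # -- graph -----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in node._parents:
                g = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad = parent.grad + g

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data @ other.data,
            parents=(
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ),
        )

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor(
            self.data**e,
            parents=((self, lambda g: g * e * self.data ** (e - 1)),),
        )

    # -- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(
            np.where(mask, self.data, 0.0),
            parents=((self, lambda g: g * mask),),
        )

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(out, parents=((self, lambda g: g * sig),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(
            np.log(self.data), parents=((self, lambda g: g / self.data),)
        )

    def gammaln(self):
        return Tensor(
            _gammaln(self.data),
            parents=((self, lambda g: g * _digamma(self.data)),),
        )

    # -- structural ------------------------------------------------------
    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)

        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=((self, vjp),))

    def sum(self, axis=None):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            return np.broadcast_to(
                np.expand_dims(g, axis), self.data.shape
            ).copy()

        return Tensor(self.data.sum(axis=axis), parents=((self, vjp),))

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- row-wise softmax -------------------------------------------------
    def log_softmax(self):
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        out = shifted - logz
        probs = np.exp(out)

        def vjp(g):
            return g - probs * g.sum(axis=1, keepdims=True)

        return Tensor(out, parents=((self, vjp),))

    def softmax(self):
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=1, keepdims=True)

        def vjp(g):
            return p * (g - (g * p).sum(axis=1, keepdims=True))

        return Tensor(p, parents=((self, vjp),))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * tensors[i].data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple((t, make_vjp(i)) for i, t in enumerate(tensors)),
    )


class Parameter(Tensor):
    """A leaf tensor whose gradient is tracked unless frozen."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def freeze(self):
        self.requires_grad = False
        self.grad = None

    def unfreeze(self):
        self.requires_grad = True


class Adam:
    """Adaptive-moment gradient descent over an explicit parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
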