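"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective composes recurrent updates, attention softmaxes,
spline contractions and pairwise penalties; all of it is expressed with the
small :class:`Tensor` type below, which records a tape of vectorised numpy
operations and back-propagates gradients through it.  Broadcasting follows
numpy semantics, with gradients summed back to the operand shapes.

Only the operations the model needs are implemented; every one of them is
exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "parameter", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None, requires_grad=None):
        self.value = np.asarray(value, dtype=float)
        self._parents = tuple(parents)
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self._parents)
        self.requires_grad = requires_grad
        self.grad = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Back-propagate from a scalar output."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(self.value + other.value, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g * other.value)
            other._accumulate(g * self.value)

        return Tensor(self.value * other.value, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g / other.value)
            other._accumulate(-g * self.value / other.value**2)

        return Tensor(self.value / other.value, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g @ other.value.T)
            other._accumulate(self.value.T @ g)

        return Tensor(self.value @ other.value, (self, other), bwd)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_val = np.exp(self.value)
        return Tensor(out_val, (self,), lambda g: self._accumulate(g * out_val))

    def log(self):
        return Tensor(np.log(self.value), (self,), lambda g: self._accumulate(g / self.value))

    def tanh(self):
        out_val = np.tanh(self.value)
        return Tensor(out_val, (self,), lambda g: self._accumulate(g * (1 - out_val**2)))

    def sigmoid(self):
        out_val = 1.0 / (1.0 + np.exp(-self.value))
        return Tensor(out_val, (self,), lambda g: self._accumulate(g * out_val * (1 - out_val)))

    def relu(self):
        mask = self.value > 0

        return Tensor(np.where(mask, self.value, 0.0), (self,),
                      lambda g: self._accumulate(g * mask))

    def square(self):
        return self * self

    # -- reductions and reshaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.value.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.value.shape))

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis=-1):
        def bwd(g):
            self._accumulate(np.flip(np.cumsum(np.flip(g, axis), axis), axis))

        return Tensor(np.cumsum(self.value, axis=axis), (self,), bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.value.shape
        return Tensor(self.value.reshape(shape), (self,),
                      lambda g: self._accumulate(g.reshape(old)))

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.value[idx], (self,), bwd)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), bwd)


def parameter(value) -> Tensor:
    """A leaf tensor that collects gradients."""
    return Tensor(np.array(value, dtype=float), requires_grad=True)


def constant(value) -> Tensor:
    """A leaf tensor excluded from differentiation."""
    return Tensor(value, requires_grad=False)
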