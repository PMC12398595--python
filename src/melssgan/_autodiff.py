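"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based scalar-output engine sized for the small attention-MLP
networks trained in this package: dense matmuls, broadcasting
elementwise arithmetic, the activations of the hyperparameter search
space, row-softmax and the loss reductions.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via topological sort.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, (self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))

        def backward(g):
            return (g @ other.value.T, self.value.T @ g)

        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: (g.T,)
        return out

    # -- elementwise functions ------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.value), (self,))
        out._backward = lambda g: (g * out.value,)
        return out

    def log(self):
        out = Tensor(np.log(self.value), (self,))
        out._backward = lambda g: (g / self.value,)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.value), (self,))

        def backward(g):
            # zero subgradient at 0 keeps row-norm losses finite there
            safe = np.where(out.value > 0.0, out.value, np.inf)
            return (g * 0.5 / safe,)

        out._backward = backward
        return out

    def square(self):
        out = Tensor(self.value**2, (self,))
        out._backward = lambda g: (2.0 * g * self.value,)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.value), (self,))
        out._backward = lambda g: (g * (1.0 - out.value**2),)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.value)), (self,))
        out._backward = lambda g: (g * out.value * (1.0 - out.value),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.value, 0.0), (self,))
        out._backward = lambda g: (g * (self.value > 0.0),)
        return out

    def leaky_relu(self, alpha: float = 0.01):
        out = Tensor(np.where(self.value > 0.0, self.value, alpha * self.value), (self,))
        out._backward = lambda g: (g * np.where(self.value > 0.0, 1.0, alpha),)
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes through only where not clipped."""
        out = Tensor(np.clip(self.value, lo, hi), (self,))
        inside = (self.value > lo) & (self.value < hi)
        out._backward = lambda g: (g * inside,)
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- composites ------------------------------------------------------

    def softmax_rows(self):
        """Row-wise softmax (max-shifted for overflow safety)."""
        shift = self - np.max(self.value, axis=-1, keepdims=True)
        e = shift.exp()
        return e / e.sum(axis=-1, keepdims=True)

    def row_l2(self):
        """Euclidean norm of each row; returns an (n,) tensor."""
        return self.square().sum(axis=-1).sqrt()

    # -- backward pass ---------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + g

    def item(self) -> float:
        return float(self.value)


def constant(value) -> Tensor:
    """A graph leaf that never receives parameter updates."""
    return Tensor(value)
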