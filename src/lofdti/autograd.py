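"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The execution environment provides no deep-learning framework, so the
network layers in this package are built on this small tape-based engine.
It supports exactly the operations the model needs: broadcasted
arithmetic, (batched) matrix products, element-wise nonlinearities,
reductions, reshaping, concatenation, gather (embedding lookup) and 1-D
convolution.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _make(self, data: np.ndarray, prev: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        out._prev = tuple(p for p in prev if p.requires_grad)
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution is kept by reference (topological order makes
        # upstream grads read-only by now); later ones allocate a fresh sum
        # so aliased arrays are never mutated in place.
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = self._make(self.data ** exponent, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = self._make(np.matmul(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)  # numerically stable
        out = self._make(s, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = self._make(e, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), computed stably."""
        out = self._make(np.logaddexp(0.0, self.data), (self,))

        def backward(g):
            if self.requires_grad:
                s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)
                self._accumulate(g * s)

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=True)
        out_data = data if keepdims else np.squeeze(data, axis=axis)
        out = self._make(out_data, (self,))

        def backward(g):
            if self.requires_grad:
                mask = self.data == data  # ties share gradient
                counts = mask.sum(axis=axis, keepdims=True)
                g = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * g / counts)

        out._backward = backward
        return out

    # -- shape manipulation ---------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(self.data.transpose(axes), (self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        out._backward = backward
        return out

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (embedding lookup): result shape indices.shape + (D,)."""
        idx = np.asarray(indices, dtype=np.intp)
        out = self._make(self.data[idx], (self,))

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx.ravel(), g.reshape(-1, self.shape[-1]))
                self._accumulate(acc)

        out._backward = backward
        return out

    # -- composite helpers ----------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shift = self.data.max(axis=axis, keepdims=True)  # constant, no grad
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release intermediate grads and graph edges so the whole graph is
        # freed by reference counting as soon as the outputs are dropped
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._prev = ()
                node.grad = None if not isinstance(node, Parameter) else node.grad


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._prev = tuple(t for t in tensors if t.requires_grad)

    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * data.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out._backward = backward
    return out
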