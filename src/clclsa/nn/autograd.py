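"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs reverse accumulation over the recorded
graph. Only the primitives the model needs are implemented (elementwise
arithmetic with broadcasting, matmul, sigmoid/relu/exp/log, reductions,
concatenation, fancy indexing). Everything is float64 and deterministic,
which keeps finite-difference gradient checks tight.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._grad_fn = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"], grad_fn) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._grad_fn = grad_fn
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        out = Tensor._result(self.data.T, (self,), None)
        if out.requires_grad:
            def grad_fn(g=None):
                self._accumulate(out.grad.T)
            out._grad_fn = grad_fn
        return out

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def grad_fn():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            out._grad_fn = grad_fn
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def grad_fn():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            out._grad_fn = grad_fn
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def grad_fn():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                    )
            out._grad_fn = grad_fn
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor._result(self.data**exponent, (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))
            out._grad_fn = grad_fn
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor._result(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def grad_fn():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)
            out._grad_fn = grad_fn
        return out

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self) -> "Tensor":
        value = np.exp(self.data)
        out = Tensor._result(value, (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad * value)
            out._grad_fn = grad_fn
        return out

    def log(self) -> "Tensor":
        out = Tensor._result(np.log(self.data), (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad / self.data)
            out._grad_fn = grad_fn
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def sigmoid(self) -> "Tensor":
        # numerically stable two-branch logistic
        value = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, 0, None))),
            np.exp(np.clip(self.data, None, 0))
            / (1.0 + np.exp(np.clip(self.data, None, 0))),
        )
        out = Tensor._result(value, (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad * value * (1.0 - value))
            out._grad_fn = grad_fn
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor._result(self.data * mask, (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad * mask)
            out._grad_fn = grad_fn
        return out

    def clamp_min(self, floor: float) -> "Tensor":
        """Elementwise max with ``floor``; gradient passes where unclamped."""
        mask = self.data > floor
        out = Tensor._result(np.maximum(self.data, floor), (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad * mask)
            out._grad_fn = grad_fn
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def grad_fn():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._grad_fn = grad_fn
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        value = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor._result(value, (self,), None)
        if out.requires_grad:
            def grad_fn():
                g = out.grad
                v = value
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                    v = np.expand_dims(v, axis)
                mask = self.data == v
                # split ties evenly so the check against finite differences holds
                mask = mask / mask.sum(axis=axis, keepdims=True)
                self._accumulate(np.broadcast_to(g, self.shape) * mask)
            out._grad_fn = grad_fn
        return out

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor._result(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            def grad_fn():
                self._accumulate(out.grad.reshape(self.shape))
            out._grad_fn = grad_fn
        return out

    def __getitem__(self, index) -> "Tensor":
        out = Tensor._result(self.data[index], (self,), None)
        if out.requires_grad:
            def grad_fn():
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accumulate(g)
            out._grad_fn = grad_fn
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        """Row softmax with a detached max-shift for numerical stability."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backprop -------------------------------------------------------------

    def backward(self) -> None:
        """Reverse accumulation from this (scalar or any-shape) tensor.

        Gradients of every node reachable from ``self`` are reset first, so one
        optimization step corresponds to one ``backward`` call.
        """
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is not None and node.grad is not None:
                node._grad_fn()


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, None
    )
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def grad_fn():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    slicer = [slice(None)] * out.grad.ndim
                    slicer[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(slicer)])

        out._grad_fn = grad_fn
    return out
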