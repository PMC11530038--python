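"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements only the operations the segmentation network needs: broadcasted
arithmetic, matmul, pointwise nonlinearities, reductions and concatenation
(convolution, pooling, normalization and resampling live in
``lesionseg.nn.functional``). Gradients accumulate into ``Tensor.grad``
after :meth:`Tensor.backward`; the :class:`no_grad` context disables graph
construction for inference.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple[Tensor, ...] = ()
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph bookkeeping -------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a gradient array owned exclusively by the caller.

        Skips the defensive copy; only valid for freshly allocated arrays
        that no other node will read or write.
        """
        if self.grad is None:
            self.grad = g if g.dtype == DTYPE else g.astype(DTYPE)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        if _wire(out, (self, other)):

            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g, other.data.shape))

            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        if _wire(out, (self, other)):

            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate_owned(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate_owned(_unbroadcast(g * self.data, other.data.shape))

            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data)
        if _wire(out, (self, other)):

            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate_owned(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate_owned(
                        _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                    )

            out._backward = bw
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        if _wire(out, (self, other)):

            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate_owned(g @ other.data.T)
                if other.requires_grad or other._parents:
                    other._accumulate_owned(self.data.T @ g)

            out._backward = bw
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if _wire(out, (self,)):

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate_owned(
                    np.broadcast_to(g, self.data.shape).astype(DTYPE, copy=True)
                )

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r)
        if _wire(out, (self,)):
            out._backward = lambda g: self._accumulate_owned(g * 0.5 / r)
        return out


def _wire(out: Tensor, parents: Sequence[Tensor]) -> bool:
    """Register graph edges; returns False when gradients are disabled."""
    if not _GRAD_ENABLED:
        return False
    tracked = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = tracked
    return True


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if _wire(out, tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._parents:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = bw
    return out
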