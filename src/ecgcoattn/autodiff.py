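"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine: every operation builds a :class:`Tensor` whose
``_backward`` closure scatters the upstream gradient to its parents.
``Tensor.backward()`` runs the closures in reverse topological order.

All arithmetic is float32.  The engine keeps gradients on *every* tensor in
the graph (not only leaves), which is what gradient-weighted class-activation
mapping needs: the gradient of a logit with respect to any intermediate
feature map can be read off after a single backward pass.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf, expit

DTYPE = np.float32

__all__ = [
    "Tensor",
    "concat",
    "as_tensor",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "retain_grad",
                 "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self.retain_grad = False
        self._parents = tuple(parents)
        self._backward = backward_fn

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate gradients promptly to bound peak memory;
            # leaves (parameters, inputs) and retain_grad tensors keep theirs
            if node._parents and not node.retain_grad:
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """2-D matrix product."""
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        in_shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(in_shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        in_shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, in_shape).astype(DTYPE))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(in_shape) for a in axes)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, in_shape).astype(DTYPE))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along one axis; ties share the gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            gk = g if keepdims else np.expand_dims(g, axis)
            mask = (self.data == m)
            counts = mask.sum(axis=axis, keepdims=True)
            self._accumulate((mask / counts) * gk)

        out._backward = bw
        return out

    # ----------------------------------------------------------- activations
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def log_sigmoid(self) -> "Tensor":
        """Numerically stable log(sigmoid(x)) = -softplus(-x)."""
        out = Tensor(-np.logaddexp(0.0, -self.data), self.requires_grad,
                     (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * expit(-self.data))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = bw
        return out

    def pow_const(self, p: float, eps: float = 1e-12) -> "Tensor":
        """x**p for x >= 0 with a guarded derivative at 0."""
        base = np.maximum(self.data, 0.0)
        out = Tensor(base ** p, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * np.maximum(base, eps) ** (p - 1.0))

        out._backward = bw
        return out

    def gelu(self) -> "Tensor":
        x = self.data.astype(np.float64)
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor((x * cdf).astype(DTYPE), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accumulate(g * (cdf + x * pdf).astype(DTYPE))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = 1) -> "Tensor":
        z = self.data
        m = z.max(axis=axis, keepdims=True)
        e = np.exp(z - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = z - m - np.log(s)
        out = Tensor(out_data, self.requires_grad, (self,))
        softmax = e / s

        def bw(g):
            if self.requires_grad:
                self._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    out._backward = bw
    return out
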