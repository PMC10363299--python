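"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package (capsule encoders, patch-graph convolutions,
Kronecker fusion heads) are small enough that a compact tape-based engine over
float64 numpy arrays is sufficient; everything differentiable in the package is
built from the operations defined here.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sp

__all__ = ["Tensor", "concat", "spmm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a backward closure on the autodiff tape."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep per training step
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def bw(g):
                g = np.asarray(g)
                a, b = self.data, other.data
                if self.requires_grad:
                    if b.ndim == 1 and a.ndim >= 2:
                        self._accum(np.outer(g, b) if a.ndim == 2 else g[..., None] * b)
                    elif a.ndim == 1:
                        self._accum(b @ g if b.ndim == 2 else g * b)
                    else:
                        self._accum(g @ b.swapaxes(-1, -2))
                if other.requires_grad:
                    if a.ndim == 1 and b.ndim == 2:
                        other._accum(np.outer(a, g))
                    elif b.ndim == 1:
                        other._accum(a.T @ g if a.ndim == 2 else g * a)
                    else:
                        other._accum(a.swapaxes(-1, -2) @ g)
            out._backward = bw
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def bw(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out

    def take(self, idx):
        """Row selection (differentiable gather along axis 0)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, np.asarray(g))
                self._accum(full)
            out._backward = bw
        return out

    def logsumexp(self):
        """Numerically stable log-sum-exp over all entries (scalar output)."""
        m = float(self.data.max())
        return ((self - m).exp().sum()).log() + m


def concat(tensors, axis: int = 0) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def spmm(mat, x: Tensor) -> Tensor:
    """Sparse (constant) matrix times dense Tensor; backward uses the transpose.

    Used for neighbour-mean aggregation in graph convolutions, where ``mat`` is
    a row-normalised adjacency stored as scipy CSR.
    """
    mat = _sp.csr_matrix(mat)
    out = Tensor(mat @ x.data, _parents=(x,))
    if out.requires_grad:
        mt = mat.T.tocsr()
        out._backward = lambda g: x._accum(mt @ np.asarray(g))
    return out
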