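"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the peak-set transformer needs
(broadcasted arithmetic, batched matmul, gather/scatter embedding lookup,
softmax, layer normalization, GELU, stable binary cross-entropy) with
analytic backward passes.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which walks the tape in reverse topological
order.  All arithmetic is float64; the tape is dynamic (rebuilt per
forward pass) and single-threaded.

The engine is deliberately small rather than general: no in-place ops,
no higher-order gradients, scalar outputs only for ``backward``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # copy: g may be reused
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, True, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other: "Tensor"):
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), True, (self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def narrow(self, start: int, end: int):
        """Slice [start, end) along the last axis."""
        out = Tensor(self.data[..., start:end], True, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[..., start:end] = g
            self._accum(full)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, True, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        out = Tensor(x * cdf, True, (self,))
        out._backward = lambda g: self._accum(g * (cdf + x * pdf))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, True, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, True, (self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, True, (self,))

        def bw(g):
            self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out

    # -- normalization --------------------------------------------------
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis then scale/shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, True, (self, gamma, beta))
        d = self.data.shape[-1]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            self._accum(term * inv)

        out._backward = bw
        return out

    # -- losses ---------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray, weights: np.ndarray | None = None):
        """Mean binary cross-entropy from logits; numerically stable.

        ``weights`` (same shape) masks/weights elements; the mean is taken
        over the total weight.
        """
        x = self.data
        t = np.asarray(targets, dtype=np.float64)
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=np.float64)
        total = w.sum()
        # log(1 + e^{-|x|}) + max(x,0) - x*t
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        out = Tensor((loss * w).sum() / total, True, (self,))
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bw(g):
            self._accum(g * w * (s - t) / total)

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), True, tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accum(piece)

    out._backward = bw
    return out


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``table`` at integer ``idx`` (any shape).

    Backward scatter-adds, so only the looked-up rows receive gradient.
    """
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], True, (table,))

    def bw(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))

    out._backward = bw
    return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
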