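"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the vision-transformer stack needs:
broadcasting add/mul, batched matmul, reshape/transpose/concat, row
gathering, softmax, layer normalization, GELU, and fused losses.
Gradients are accumulated into ``Tensor.grad`` by :func:`backward`,
which walks the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "cat", "softmax_cross_entropy", "mse_masked"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape wrapping a float64/float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bw(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), bw)

    def gather_rows(self, index: np.ndarray, axis: int = -2) -> "Tensor":
        """Select rows along ``axis`` (token selection); gradient scatters back."""
        index = np.asarray(index, dtype=np.intp)
        taken = np.take(self.data, index, axis=axis)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(np.moveaxis(full, axis, 0), index, np.moveaxis(g, axis, 0))
                self._accum(full)

        return self._make(taken, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities ---------------------------------------------------
    def gelu(self) -> "Tensor":
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (cdf + x * pdf))

        return self._make(x * cdf, (self,), bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        return self._make(p, (self,), bw)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gamma.data + beta.data

        def bw(g):
            if gamma.requires_grad:
                axes = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                axes = tuple(range(g.ndim - 1))
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gy = g * gamma.data
                m1 = gy.mean(axis=-1, keepdims=True)
                m2 = (gy * xhat).mean(axis=-1, keepdims=True)
                self._accum(inv * (gy - m1 - xhat * m2))

        return self._make(out, (self, gamma, beta), bw)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    ``logits`` has class scores on the last axis; ``labels`` matches the
    leading axes. Fused forward/backward for numerical stability.
    """
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = int(np.prod(labels.shape)) if labels.shape else 1
    flat_p = p.reshape(n, p.shape[-1])
    flat_l = labels.reshape(n)
    nll = -np.log(np.maximum(flat_p[np.arange(n), flat_l], 1e-300))
    loss = Tensor(nll.mean())
    loss.requires_grad = logits.requires_grad
    if loss.requires_grad:
        loss._parents = (logits,)

        def bw(g):
            grad = flat_p.copy()
            grad[np.arange(n), flat_l] -= 1.0
            logits._accum(float(g) * grad.reshape(p.shape) / n)

        loss._backward = bw
    return loss


def mse_masked(pred: Tensor, target: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Mean squared error, optionally weighted (e.g. masked patches only)."""
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    if weight is None:
        loss_val = float((diff * diff).mean())
        scale = 2.0 / diff.size
        w = None
    else:
        w = np.asarray(weight, dtype=np.float64)
        denom = max(float(w.sum()), 1e-12)
        loss_val = float((w * diff * diff).sum() / denom)
        scale = 2.0 / denom
    loss = Tensor(loss_val)
    loss.requires_grad = pred.requires_grad
    if loss.requires_grad:
        loss._parents = (pred,)

        def bw(g):
            gr = float(g) * scale * diff
            if w is not None:
                gr = gr * w
            pred._accum(gr)

        loss._backward = bw
    return loss
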