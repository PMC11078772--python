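"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the conditional transformer decoder needs:
broadcasting arithmetic, batched matmul, reshape/transpose, reductions,
relu/exp/log, fused softmax and masked cross-entropy, and an embedding
gather.  Float64 throughout; determinism is inherited from numpy.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation / sampling paths)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- construction helper ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_on() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        def bw(g):
            self._accumulate(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gpart)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), bw)


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of `table` (V, d) at integer `indices` (...,) -> (..., d)."""
    idx = np.asarray(indices)

    def bw(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(acc)

    return Tensor._make(table.data[idx], (table,), bw)


def pergene_linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Per-row linear map: x (B, G, r) x weight (G, r, d) + bias (G, d)."""
    out = np.einsum("bgr,grd->bgd", x.data, weight.data) + bias.data

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.einsum("bgd,grd->bgr", g, weight.data))
        if weight.requires_grad:
            weight._accumulate(np.einsum("bgr,bgd->grd", x.data, g))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))

    return Tensor._make(out, (x, weight, bias), bw)


def masked_cross_entropy(logits: Tensor, targets: np.ndarray,
                         mask: np.ndarray) -> Tensor:
    """Mean of -log p(target) over positions where mask is truthy.

    `logits` (B, L, V); `targets` integer (B, L); `mask` (B, L).
    Equals the token-level KL divergence against one-hot targets.
    """
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=bool)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("masked_cross_entropy: no unmasked positions")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    b_idx, l_idx = np.nonzero(mask)
    true_logit = z[b_idx, l_idx, targets[b_idx, l_idx]]
    loss = (lse[b_idx, l_idx] - true_logit).sum() / n_valid

    def bw(g):
        p = np.exp(z - np.log(np.exp(z).sum(axis=-1, keepdims=True)))
        p[b_idx, l_idx, targets[b_idx, l_idx]] -= 1.0
        p *= mask[..., None] / n_valid
        logits._accumulate(g * p)

    return Tensor._make(loss, (logits,), bw)
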