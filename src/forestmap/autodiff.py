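"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the transformer needs: broadcasting
arithmetic, batched matmul, reshape/transpose/concat/slicing, reductions,
tanh/exp/log/sqrt, a numerically stable log-softmax, and a fused
masked-cross-entropy node with its closed-form gradient. Float32
throughout; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gelu",
    "layernorm",
    "log_softmax",
    "masked_cross_entropy_node",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seed = ones."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- constructors for derived nodes -----------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, rg, parents if rg else (), backward if rg else None)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), bw)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and g.ndim > 2:
                    # batched input x 2-D weight: fold the batch axes into
                    # one GEMM instead of a batched matmul plus reduction
                    k = self.data.shape[-1]
                    n = g.shape[-1]
                    gb = self.data.reshape(-1, k).T @ g.reshape(-1, n)
                    other._accumulate(gb)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax; the max shift is treated as constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax node; backward is y * (g - sum(g * y))."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        inner = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - inner))

    return Tensor._make(y, (x,), bw)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def bw(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gy - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), bw)


def gelu(x: Tensor) -> Tensor:
    """Fused tanh-approximation GELU."""
    c = 0.7978845608028654
    a = 0.044715
    u = c * (x.data + a * x.data**3)
    t = np.tanh(u)
    out = 0.5 * x.data * (1.0 + t)

    def bw(g):
        du = c * (1.0 + 3.0 * a * x.data**2)
        grad = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t * t) * du
        x._accumulate(g * grad)

    return Tensor._make(out, (x,), bw)


def masked_cross_entropy_node(logits: Tensor, target_idx: np.ndarray) -> Tensor:
    """Mean negative log-softmax over rows where ``target_idx >= 0``.

    ``logits`` has shape (n, C); rows with ``target_idx == -1`` are ignored.
    Fused node: the gradient (softmax - onehot) / n_valid is applied in
    closed form, avoiding a long primitive chain on the hot path.
    """
    idx = np.asarray(target_idx)
    valid = idx >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return Tensor(0.0)
    rows = np.nonzero(valid)[0]
    sel = logits.data[rows]
    shift = sel.max(axis=1, keepdims=True)
    z = sel - shift
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n_valid), idx[rows]].mean()

    def bw(g):
        grad = np.zeros_like(logits.data)
        p = np.exp(logp)
        p[np.arange(n_valid), idx[rows]] -= 1.0
        grad[rows] = p * (float(g) / n_valid)
        logits._accumulate(grad)

    return Tensor._make(np.float32(loss), (logits,), bw)
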