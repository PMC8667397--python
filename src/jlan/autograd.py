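"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure, and :meth:`Tensor.backward`
runs a topological sweep accumulating gradients.  Only the operations the
network needs are provided (broadcast arithmetic, matmul, pointwise
nonlinearities, masked softmax, embedding lookup, slicing, concatenation,
reductions).  Gradients through broadcasting are reduced with
:func:`_unbroadcast`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            # copy: grad may be a view into another node's buffer
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate ``grad`` (default: ones for scalar outputs)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b  # (..., m) x (n,) -> (..., m, n)
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if b.ndim == 1:
                    gb = np.einsum("...mn,...m->...n", a, g)
                elif a.ndim == 1:
                    gb = a[:, None] * g[..., None, :]
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        # basic indexing (ints/slices) never selects a cell twice, so plain
        # in-place add suffices; fancy indexing needs the unbuffered add.at
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice)) for p in parts)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- reductions and reshaping ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# ---------------------------------------------------------------------------
# pointwise nonlinearities


def _pointwise(x: Tensor, value: Array, dvalue: Array) -> Tensor:
    out = Tensor(value, parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * dvalue)

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.data)
    return _pointwise(x, v, 1.0 - v * v)


def sigmoid(x: Tensor) -> Tensor:
    v = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic
    return _pointwise(x, v, v * (1.0 - v))


def relu(x: Tensor) -> Tensor:
    v = np.maximum(x.data, 0.0)
    return _pointwise(x, v, (x.data > 0).astype(np.float64))


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.data)
    return _pointwise(x, v, v)


def log(x: Tensor) -> Tensor:
    return _pointwise(x, np.log(x.data), 1.0 / x.data)


def softplus(x: Tensor) -> Tensor:
    v = np.logaddexp(0.0, x.data)
    s = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return _pointwise(x, v, s)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    v = np.clip(x.data, lo, hi)
    inside = ((x.data > lo) & (x.data < hi)).astype(np.float64)
    return _pointwise(x, v, inside)


def maximum_const(x: Tensor, c: float) -> Tensor:
    """max(x, c) elementwise; gradient flows only where x > c."""
    v = np.maximum(x.data, c)
    return _pointwise(x, v, (x.data > c).astype(np.float64))


# ---------------------------------------------------------------------------
# structured operations


def masked_softmax(logits: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` restricted to positions where ``mask`` is true.

    Masked positions receive exactly zero weight (and zero gradient).  A row
    with no unmasked position is an error: the distribution is undefined.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), logits.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_softmax: some row has all positions masked")
    z = np.where(mask, logits.data, -np.inf)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    e = np.where(mask, e, 0.0)
    v = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(v, parents=(logits,))

    def bwd(g: Array) -> None:
        if logits.requires_grad:
            inner = (g * v).sum(axis=axis, keepdims=True)
            logits._accumulate(v * (g - inner))

    out._backward = bwd
    return out


def embedding(table: Tensor, ids: Array) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))

    def bwd(g: Array) -> None:
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, ids, g)
            table._accumulate(full)

    out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g: Array) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, gt in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gt)

    out._backward = bwd
    return out


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad ``x`` along one axis (used for same-padded convolutions)."""
    widths = [(0, 0)] * x.ndim
    widths[axis] = (before, after)
    out = Tensor(np.pad(x.data, widths), parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            sl = [slice(None)] * x.ndim
            sl[axis] = slice(before, before + x.shape[axis])
            x._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
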