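"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives the detection model needs are
provided (broadcast arithmetic, batched matmul, 1D convolution and pooling,
softmax/log-softmax, elementwise nonlinearities, indexing, concatenation).
Every primitive is exercised by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "cat", "conv1d", "maxpool1d",
           "set_default_dtype", "default_dtype"]

_grad_enabled = True

#: working precision of the engine.  float32 is the practical choice on a
#: CPU (memory-bandwidth bound); float64 is available for numerical checks.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used by newly created tensors (set before building models)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the tensor dtype (for finite-difference tests)."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference fast path)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))
        return Tensor._from_op(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)
        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g / (2.0 * y))
        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        z = self.data
        out_data = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                            np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))
        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))
        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return Tensor._from_op(self.data * mask, (self,), backward)

    def clip_min(self, low: float):
        """Elementwise ``max(x, low)`` with subgradient 1 on the kept side."""
        mask = self.data > low
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return Tensor._from_op(np.maximum(self.data, low), (self,), backward)

    def maximum(self, other):
        other = self._wrap(other)
        take_a = self.data >= other.data
        def backward(g, a=self, b=other, m=take_a):
            if a.requires_grad:
                a._accum(_unbroadcast(g * m, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~m, b.data.shape))
        return Tensor._from_op(np.maximum(self.data, other.data), (self, other), backward)

    def minimum(self, other):
        other = self._wrap(other)
        take_a = self.data <= other.data
        def backward(g, a=self, b=other, m=take_a):
            if a.requires_grad:
                a._accum(_unbroadcast(g * m, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~m, b.data.shape))
        return Tensor._from_op(np.minimum(self.data, other.data), (self, other), backward)

    def abs(self):
        sign = np.sign(self.data)
        def backward(g, a=self, s=sign):
            if a.requires_grad:
                a._accum(g * s)
        return Tensor._from_op(np.abs(self.data), (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.data.shape))
        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- softmax family ------------------------------------------------------

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g, a=self, yy=y, ax=axis):
            if a.requires_grad:
                dot = (g * yy).sum(axis=ax, keepdims=True)
                a._accum(yy * (g - dot))
        return Tensor._from_op(y, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)
        def backward(g, a=self, s=sm, ax=axis):
            if a.requires_grad:
                a._accum(g - s * g.sum(axis=ax, keepdims=True))
        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g, a=self, s=old):
            if a.requires_grad:
                a._accum(g.reshape(s))
        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g, a=self, iv=inv):
            if a.requires_grad:
                a._accum(g.transpose(iv))
        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, ix=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, ix, g)
                a._accum(full)
        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- autodiff driver -----------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        # never mutate in place: incoming buffers may be shared between
        # consumers (e.g. the two sides of a residual add)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g, ts=tensors, off=offsets, ax=axis):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1D cross-correlation: ``x (B,C,L)`` with kernels ``w (O,C,K)``."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    B, C, Lp = xd.shape
    O, _, K = w.data.shape
    lout = (Lp - K) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, K, axis=2)[:, :, ::stride, :]
    out = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, xx=x, ww=w, bb=b, window=win, pad=padding, st=stride,
                 k=K, lp=Lp):
        if ww.requires_grad:
            ww._accum(np.einsum("bclk,bol->ock", window, g, optimize=True))
        if bb is not None and bb.requires_grad:
            bb._accum(g.sum(axis=(0, 2)))
        if xx.requires_grad:
            gxp = np.zeros((g.shape[0], ww.data.shape[1], lp), dtype=g.dtype)
            n = g.shape[2]
            for kk in range(k):
                gxp[:, :, kk:kk + st * n:st] += np.einsum(
                    "bol,oc->bcl", g, ww.data[:, :, kk], optimize=True
                )
            if pad:
                gxp = gxp[:, :, pad:-pad]
            xx._accum(gxp)

    return Tensor._from_op(out, parents, backward)


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling (stride == kernel); trailing rest dropped."""
    B, C, L = x.data.shape
    lout = L // kernel
    xr = x.data[:, :, : lout * kernel].reshape(B, C, lout, kernel)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g, a=x, ix=idx, k=kernel, lo=lout, shape=(B, C, L)):
        if a.requires_grad:
            full = np.zeros(shape, dtype=g.dtype)
            fr = full[:, :, : lo * k].reshape(shape[0], shape[1], lo, k)
            np.put_along_axis(fr, ix[..., None], g[..., None], axis=-1)
            a._accum(full)

    return Tensor._from_op(out, (x,), backward)
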