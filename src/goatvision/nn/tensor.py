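"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The detector in this package is a few dozen convolution / normalization /
attention blocks; this module provides exactly the tensor operations those
blocks need (convolution with groups, batch statistics, pooling, nearest
upsampling, pointwise math, reductions, gather) with a define-by-run tape.
Arrays are used as-is (float32 for model weights; float64 works too, which
the gradient-check tests exploit).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Optional, Sequence, Union

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------
    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    """Create a result tensor, attaching the tape node if grads are needed."""
    track = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=track)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pointwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)
    return _make(out_data, (a, b), bwd)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)
    return _make(out_data, (a, b), bwd)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(-g)
    return _make(out_data, (a, b), bwd)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g / b.data)
        if b.requires_grad:
            b._accum(-g * a.data / (b.data ** 2))
    return _make(out_data, (a, b), bwd)


def neg(a):
    a = _as_tensor(a)

    def bwd(g):
        a._accum(-g)
    return _make(-a.data, (a,), bwd)


def power(a, exponent: float):
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def bwd(g):
        a._accum(g * exponent * a.data ** (exponent - 1))
    return _make(out_data, (a,), bwd)


def exp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        a._accum(g * out_data)
    return _make(out_data, (a,), bwd)


def log(a):
    a = _as_tensor(a)

    def bwd(g):
        a._accum(g / a.data)
    return _make(np.log(a.data), (a,), bwd)


def sqrt(a):
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def bwd(g):
        a._accum(g * 0.5 / np.maximum(out_data, 1e-12))
    return _make(out_data, (a,), bwd)


def atan(a):
    a = _as_tensor(a)

    def bwd(g):
        a._accum(g / (1.0 + a.data ** 2))
    return _make(np.arctan(a.data), (a,), bwd)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accum(g * out_data * (1.0 - out_data))
    return _make(out_data, (a,), bwd)


def silu(a):
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def bwd(g):
        a._accum(g * (s + a.data * s * (1.0 - s)))
    return _make(out_data, (a,), bwd)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        a._accum(g * mask)
    return _make(a.data * mask, (a,), bwd)


def clamp(a, lo: Optional[float] = None, hi: Optional[float] = None):
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    pass_through = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        pass_through &= a.data >= lo
    if hi is not None:
        pass_through &= a.data <= hi

    def bwd(g):
        a._accum(g * pass_through)
    return _make(out_data, (a,), bwd)


def maximum(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    amax = a.data >= b.data
    out_data = np.where(amax, a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * amax)
        if b.requires_grad:
            b._accum(g * ~amax)
    return _make(out_data, (a, b), bwd)


def minimum(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    amin = a.data <= b.data
    out_data = np.where(amin, a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * amin)
        if b.requires_grad:
            b._accum(g * ~amin)
    return _make(out_data, (a, b), bwd)


def abs_(a):
    a = _as_tensor(a)
    sign = np.sign(a.data)

    def bwd(g):
        a._accum(g * sign)
    return _make(np.abs(a.data), (a,), bwd)


# ---------------------------------------------------------------------------
# reductions, shaping, indexing
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))
    return _make(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / out_data.size

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape) / n)
    return _make(out_data, (a,), bwd)


def tmax(a, axis: int, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    arg = a.data.argmax(axis=axis)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(arg, axis), g, axis=axis)
        a._accum(ga)
    return _make(out_data, (a,), bwd)


def reshape(a, *shape):
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def bwd(g):
        a._accum(g.reshape(a.data.shape))
    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a, axes: Sequence[int]):
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))
    return _make(a.data.transpose(axes), (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0):
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, s0, s1 in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(s0, s1)
                t._accum(g[tuple(idx)])
    return _make(out_data, ts, bwd)


def narrow(a, axis: int, start: int, length: int):
    """Contiguous slice along one axis."""
    a = _as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def bwd(g):
        ga = np.zeros_like(a.data)
        ga[idx] = g
        a._accum(ga)
    return _make(a.data[idx], (a,), bwd)


def gather_rows(a, index: np.ndarray):
    """Select rows of a 2-D tensor: ``out[i] = a[index[i]]`` (rows may repeat)."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        a._accum(ga)
    return _make(a.data[index], (a,), bwd)


def take_along(a, index: np.ndarray, axis: int):
    """Differentiable ``np.take_along_axis``."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, index, g, axis=axis)  # indices unique along axis
        a._accum(ga)
    return _make(np.take_along_axis(a.data, index, axis=axis), (a,), bwd)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(np.matmul(g, np.swapaxes(b.data, -1, -2)))
        if b.requires_grad:
            b._accum(np.matmul(np.swapaxes(a.data, -1, -2), g))
    return _make(out_data, (a, b), bwd)


def softmax(a, axis: int = -1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))
    return _make(out_data, (a,), bwd)


def log_softmax(a, axis: int = -1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def bwd(g):
        a._accum(g - soft * g.sum(axis=axis, keepdims=True))
    return _make(out_data, (a,), bwd)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, Ho, Wo) patch tensor (copies)."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + Ho * stride:stride,
                                  j:j + Wo * stride:stride]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation with optional groups (NCHW x OIkk)."""
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.shape
    Co, Cg, k, k2 = w.shape
    assert k == k2 and C == Cg * groups and Co % groups == 0
    s, p = stride, padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = _im2col(xp, k, s, Ho, Wo)  # N,C,k,k,Ho,Wo
    L = Ho * Wo
    cols_g = cols.reshape(N, groups, Cg * k * k, L)
    wg = w.data.reshape(groups, Co // groups, Cg * k * k)
    out = np.matmul(wg[None], cols_g)  # (N, g, Co/g, L)
    out = out.reshape(N, Co, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gl = np.ascontiguousarray(g).reshape(N, groups, Co // groups, L)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.matmul(gl, cols_g.swapaxes(-1, -2)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(wg.swapaxes(-1, -2)[None], gl)
            dcols = dcols.reshape(N, C, k, k, Ho, Wo)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += dcols[:, :, i, j]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)
    return _make(out, parents, bwd)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = _as_tensor(x)
    N, C, H, W = x.shape
    k, s, p = kernel, stride, padding
    fill = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else None
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=fill) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    out = np.full((N, C, Ho, Wo), -np.inf, dtype=x.data.dtype)
    winner = np.zeros((N, C, Ho, Wo), dtype=np.int8)
    for idx in range(k * k):
        i, j = divmod(idx, k)
        win = xp[:, :, i:i + Ho * s:s, j:j + Wo * s:s]
        better = win > out
        out = np.where(better, win, out)
        winner = np.where(better, idx, winner)

    def bwd(g):
        dxp = np.zeros_like(xp)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += g * (winner == idx)
        x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)
    return _make(out, (x,), bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.shape

    def bwd(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))
    return _make(out, (x,), bwd)


# operator sugar -------------------------------------------------------------

Tensor.__add__ = lambda self, o: add(self, o)
Tensor.__radd__ = lambda self, o: add(o, self)
Tensor.__sub__ = lambda self, o: sub(self, o)
Tensor.__rsub__ = lambda self, o: sub(o, self)
Tensor.__mul__ = lambda self, o: mul(self, o)
Tensor.__rmul__ = lambda self, o: mul(o, self)
Tensor.__truediv__ = lambda self, o: div(self, o)
Tensor.__rtruediv__ = lambda self, o: div(o, self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__pow__ = lambda self, e: power(self, e)
Tensor.sum = tsum
Tensor.mean = tmean
Tensor.max = tmax
Tensor.reshape = reshape
Tensor.transpose = transpose
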