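"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the segmentation network needs:
elementwise arithmetic, matmul, 2-D convolution (im2col, BLAS-backed),
global pooling, softmax, nearest-neighbour 2x upsampling, concatenation
and shape manipulation.  Tensors carry float32 data; gradients are
accumulated into ``.grad`` by :meth:`Tensor.backward` in reverse
topological order.
"""
from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)

    def backward(g):
        x._accum(g * (x.data > 0))

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def log(x: Tensor) -> Tensor:
    data = np.log(x.data)

    def backward(g):
        x._accum(g / x.data)

    return _make(data, (x,), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(data, (a, b), backward)


def sqrt(x: Tensor) -> Tensor:
    data = np.sqrt(x.data)

    def backward(g):
        x._accum(g / (2.0 * data))

    return _make(data, (x,), backward)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(x.data, lo, hi)

    def backward(g):
        x._accum(g * ((x.data >= lo) & (x.data <= hi)))

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------

def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(gg, x.data.shape).copy())

    return _make(data, (x,), backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    data = x.data.reshape(shape)

    def backward(g):
        x._accum(g.reshape(orig))

    return _make(data, (x,), backward)


def transpose(x: Tensor, axes: tuple) -> Tensor:
    data = x.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        x._accum(g.transpose(inv))

    return _make(data, (x,), backward)


def concat(xs: Iterable[Tensor], axis: int = 1) -> Tensor:
    xs = list(xs)
    data = np.concatenate([x.data for x in xs], axis=axis)
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                x._accum(g[tuple(idx)])

    return _make(data, tuple(xs), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) mean."""
    return tmean(x, axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) max; gradient routed to the (first) argmax."""
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, -1)
    idx = flat.argmax(axis=2)
    data = np.take_along_axis(flat, idx[:, :, None], axis=2).reshape(N, C, 1, 1)

    def backward(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[:, :, None], g.reshape(N, C, 1), axis=2)
        x._accum(gf.reshape(x.data.shape))

    return _make(data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return _make(s, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product on the last two axes; leading batch axes must match."""
    a, b = as_tensor(a), as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)),
                                  a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g),
                                  b.data.shape))

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------
# convolution and resampling
# ---------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    N, C, H, W = xp.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, kh, kw, Ho, Wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return cols, Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """x (N,Cin,H,W), w (Cout,Cin,kh,kw), b (Cout,) -> (N,Cout,Ho,Wo)."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, Ho, Wo = _im2col(xp, kh, kw, stride)
    out = np.tensordot(w.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out = out.transpose(1, 0, 2, 3)  # (N, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
            w._accum(dw)
        if x.requires_grad:
            # dcols[n,c,u,v,i,j] = sum_o g[n,o,i,j] w[o,c,u,v]
            dcols = np.tensordot(g, w.data, axes=([1], [0]))
            dcols = dcols.transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u:u + stride * Ho:stride,
                        v:v + stride * Wo:stride] += dcols[:, :, u, v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return _make(out, parents, backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling; adjoint sums 2x2 blocks."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        N, C, H2, W2 = g.shape
        x._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return _make(data, (x,), backward)
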