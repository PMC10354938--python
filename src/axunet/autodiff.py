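"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the recorded
graph.  The operation set is exactly what the segmentation network needs:
broadcasting arithmetic, matmul, reductions, shape ops, elementwise
nonlinearities, 2-D convolution / pooling / bilinear resampling, indexing and
concatenation.  Everything is float32 by default; float64 inputs stay float64
(gradient-checking tests rely on that).

A global multiply–accumulate counter can be armed with :func:`mac_counting`
to measure the arithmetic cost of matmul/conv stages — used to compare the
axial attention's Q·K cost against dense attention.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "no_grad",
    "mac_counting",
    "mac_count",
    "concatenate",
    "stack",
    "matmul",
    "conv2d",
    "max_pool2d",
    "upsample_bilinear",
    "sigmoid",
    "softmax",
    "relu",
    "tanh",
    "gelu",
    "clip",
]

_GRAD_ENABLED = True

# multiply–accumulate bookkeeping: [enabled, count]
_MAC = [False, 0]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def mac_counting():
    """Count multiply–accumulates of matmul/conv ops executed inside."""
    prev = (_MAC[0], _MAC[1])
    _MAC[0], _MAC[1] = True, 0
    try:
        yield
    finally:
        _MAC[0], _MAC[1] = prev


def mac_count() -> int:
    """Current value of the multiply–accumulate counter."""
    return _MAC[1]


def _as_array(data):
    a = np.asarray(data)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


class Tensor:
    """An ndarray with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    # basic introspection
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    # autodiff machinery
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy() \
                if not isinstance(g, np.ndarray) or g.dtype != self.data.dtype else g.copy()
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads to bound memory; leaves keep theirs
                if node is not self and node._parents:
                    node.grad = None

    # ------------------------------------------------------------------
    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # reductions / shape ops as methods
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def sqrt(self):
        return power(self, 0.5)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward):
    """Build an op result; record the graph only when needed."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out = Tensor(data, requires_grad=True)
        out._parents = tuple(parents)
        out._backward = backward
        return out
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ----------------------------------------------------------------------
# arithmetic
def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def power(a, p) -> Tensor:
    a = astensor(a)
    p = float(p)
    out = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out)

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(out, (a,), backward)


def tanh(a) -> Tensor:
    a = astensor(a)
    out = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out * out))

    return _make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out * (1.0 - out))

    return _make(out, (a,), backward)


def relu(a) -> Tensor:
    a = astensor(a)
    out = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _make(out, (a,), backward)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(a) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    a = astensor(a)
    inner = tanh(mul(add(a, mul(power(a, 3.0), 0.044715)), _GELU_C))
    return mul(mul(a, 0.5), add(inner, 1.0))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; the gradient passes only inside the band."""
    a = astensor(a)
    out = np.clip(a.data, lo, hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))

    return _make(out, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    a = astensor(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


# ----------------------------------------------------------------------
# reductions
def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    axes = _norm_axis(axis, a.data.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axes)
            a._accumulate(np.broadcast_to(gg, a.data.shape))

    return _make(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    axes = _norm_axis(axis, a.data.ndim)
    n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axes, keepdims=keepdims), 1.0 / n)


# ----------------------------------------------------------------------
# shape ops
def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(out, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    out = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out = a.data[idx]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accumulate(ga)

    return _make(out, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accumulate(g[tuple(sl)])

    return _make(out, ts, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [reshape(astensor(t), t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors]
    return concatenate(ts, axis=axis)


# ----------------------------------------------------------------------
# linear algebra
def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = np.matmul(a.data, b.data)
    if _MAC[0]:
        # batched (..., m, k) @ (..., k, n): m*n*k MACs per batch element
        batch = int(np.prod(out.shape[:-2])) if out.ndim > 2 else 1
        _MAC[1] += batch * out.shape[-2] * out.shape[-1] * a.data.shape[-1]

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out, (a, b), backward)


# ----------------------------------------------------------------------
# 2-D image ops (NCHW layout)
def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` [B,C,H,W] with ``w`` [O,C,kh,kw]."""
    x, w = astensor(x), astensor(w)
    B, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {C2}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    out = np.zeros((B, O, Ho, Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
            out += np.einsum("bchw,oc->bohw", xs, w.data[:, :, i, j], optimize=True)
    if _MAC[0]:
        _MAC[1] += B * O * C * Ho * Wo * kh * kw
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        out = out + b.data.reshape(1, O, 1, 1)
        parents.append(b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += np.einsum(
                        "bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accumulate(gxp[:, :, p : p + H, p : p + W] if p else gxp)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                    gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = astensor(x)
    B, C, H, W = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    fill = -np.inf
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill)
        if p
        else x.data
    )
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    windows = np.stack(
        [
            xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
            for i in range(k)
            for j in range(k)
        ]
    )  # [k*k, B, C, Ho, Wo]
    arg = windows.argmax(axis=0)
    out = np.take_along_axis(windows, arg[None], axis=0)[0]

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for idx in range(k * k):
                i, j = divmod(idx, k)
                mask = arg == idx
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += g * mask
            x._accumulate(gxp[:, :, p : p + H, p : p + W] if p else gxp)

    return _make(out, (x,), backward)


def _linear_interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic matrix realizing align_corners=False bilinear resampling."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        A[o, i0c] += 1.0 - frac
        A[o, i1c] += frac
    return A


def upsample_bilinear(x, scale: int = 2) -> Tensor:
    """Bilinear upsampling of [B,C,H,W] by an integer factor."""
    x = astensor(x)
    B, C, H, W = x.data.shape
    Ah = _linear_interp_matrix(H * scale, H, x.data.dtype)
    Aw = _linear_interp_matrix(W * scale, W, x.data.dtype)
    out = np.einsum("oh,bchw,pw->bcop", Ah, x.data, Aw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.einsum("oh,bcop,pw->bchw", Ah, g, Aw, optimize=True))

    return _make(out, (x,), backward)
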