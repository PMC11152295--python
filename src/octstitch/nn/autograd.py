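"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor library sufficient for training the hybrid
convolution/attention backbones in this package: broadcasting arithmetic,
matmul, 2-d (grouped, strided) convolution, average pooling, softmax and
the reductions needed for losses.  Gradients are accumulated by a
topological-order backward sweep, micrograd-style, but over numpy arrays.

Only what the backbones need is implemented; this is not a general deep
learning framework.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation mode forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward(out)
    return out


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.shape))
        return run

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.shape))
        return run

    return _make(data, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** exponent

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * exponent * a.data ** (exponent - 1.0))
        return run

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * out.data)
        return run

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad / a.data)
        return run

    return _make(data, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * mask)
        return run

    return _make(data, (a,), bw)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


# -- shape ----------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad.reshape(a.shape))
        return run

    return _make(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad.transpose(inv))
        return run

    return _make(data, (a,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(out):
        def run():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(g)
        return run

    return _make(data, tuple(tensors), bw)


# -- reductions -----------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out):
        def run():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).astype(DTYPE))
        return run

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        count = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[i] for i in ax]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / count)


# -- linear algebra -------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(out):
        def run():
            if a.requires_grad:
                ga = out.grad @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ out.grad
                b._accum(_unbroadcast(gb, b.shape))
        return run

    return _make(data, (a, b), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        def run():
            if a.requires_grad:
                y, g = out.data, out.grad
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))
        return run

    return _make(data, (a,), bw)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse

    def bw(out):
        def run():
            if a.requires_grad:
                y = np.exp(out.data)
                g = out.grad
                a._accum(g - y * g.sum(axis=axis, keepdims=True))
        return run

    return _make(data, (a,), bw)


def gather_rows(a, index: np.ndarray) -> Tensor:
    """out[i] = a[i, index[i]] for a 2-d tensor (per-sample class pick)."""
    a = _as_tensor(a)
    index = np.asarray(index)
    rows = np.arange(a.shape[0])
    data = a.data[rows, index]

    def bw(out):
        def run():
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, (rows, index), out.grad)
                a._accum(g)
        return run

    return _make(data, (a,), bw)


# -- spatial ops ----------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-d cross-correlation. x: (B,Cin,H,W); w: (Cout,Cin/groups,KH,KW)."""
    x, w = _as_tensor(x), _as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cin_g, KH, KW = w.shape
    if Cin % groups or Cout % groups or Cin // groups != Cin_g:
        raise ValueError(
            f"conv2d channel/group mismatch: in={Cin}, out={Cout}, "
            f"groups={groups}, weight expects {Cin_g} per group")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - KH) // s + 1
    Wo = (Wp - KW) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW), axis=(2, 3))
    win = win[:, :, ::s, ::s]                      # (B,Cin,Ho,Wo,KH,KW)
    win_g = win.reshape(B, groups, Cin_g, Ho, Wo, KH, KW)
    w_g = w.data.reshape(groups, Cout // groups, Cin_g, KH, KW)
    out_data = np.einsum("bgihwkl,goikl->bgohw", win_g, w_g,
                         optimize=True).reshape(B, Cout, Ho, Wo)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    def bw(out):
        def run():
            go = out.grad.reshape(B, groups, Cout // groups, Ho, Wo)
            if w.requires_grad:
                gw = np.einsum("bgihwkl,bgohw->goikl", win_g, go,
                               optimize=True)
                w._accum(gw.reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                t = np.einsum("bgohw,goikl->bgihwkl", go, w_g, optimize=True)
                gxp = np.zeros((B, Cin, Hp, Wp), dtype=DTYPE)
                gxp_g = gxp.reshape(B, groups, Cin_g, Hp, Wp)
                for k in range(KH):
                    for l in range(KW):
                        gxp_g[:, :, :, k:k + s * Ho:s, l:l + s * Wo:s] += \
                            t[..., k, l]
                gx = gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp
                x._accum(gx)
        return run

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out_data, parents, bw)


def avg_pool2d(x, stride: int) -> Tensor:
    """Average pooling with kernel == stride (non-overlapping)."""
    x = _as_tensor(x)
    if stride == 1:
        return x
    B, C, H, W = x.shape
    if H % stride or W % stride:
        raise ValueError(
            f"avg_pool2d: spatial dims ({H},{W}) not divisible by "
            f"stride {stride}")
    s = stride
    data = x.data.reshape(B, C, H // s, s, W // s, s).mean(axis=(3, 5))

    def bw(out):
        def run():
            if x.requires_grad:
                g = out.grad[:, :, :, None, :, None] / (s * s)
                g = np.broadcast_to(g, (B, C, H // s, s, W // s, s))
                x._accum(g.reshape(B, C, H, W).astype(DTYPE))
        return run

    return _make(data, (x,), bw)
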