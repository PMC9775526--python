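"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the primitives the package's two trainable
models need (1D convolutions, pointwise nonlinearities, reductions,
batched matrix products, gather), with a tape-based backward pass.  It is
deliberately small: no broadcasting tricks beyond NumPy's own, no dtype
promotion policy, no higher-order gradients.  The gradient-penalty term of
the Wasserstein-divergence loss — which normally needs double backprop —
is handled in ``gan.py`` by building the discriminator's input gradient
*as a graph over the weight tensors*, which is exact for a piecewise-linear
discriminator.

All operations are functions returning new :class:`Tensor` objects; a
``Tensor`` also supports the usual arithmetic operators.  Gradients are
plain ``numpy`` arrays accumulated on ``Tensor.grad``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "backward",
    "concat",
    "conv1d",
    "exp",
    "leaky_relu",
    "log",
    "matmul",
    "mean",
    "relu",
    "sigmoid",
    "sqrt",
    "sum_",
    "tanh",
    "upsample_linear",
    "upsample_matrix",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An n-d array with an optional backward closure.

    Parameters
    ----------
    data : array_like
        Wrapped values; stored as ``numpy.ndarray`` without copy when possible.
    requires_grad : bool
        Mark as a leaf that accumulates gradients (model parameters).
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)

    def flip(self, axis):
        return flip(self, axis)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, backward_fn) -> Tensor:
    """Create a graph node if grad is enabled and any parent needs it."""
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None for p in parents):
        t = Tensor(data)
        t.requires_grad = False
        t._parents = tuple(parents)
        t._backward = backward_fn
        return t
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------- arithmetic
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(out, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data

    def bwd(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _node(out, (a, b), bwd)


def power(a, p) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out = a.data**p

    def bwd(g):
        return (g * p * a.data ** (p - 1.0),)

    return _node(out, (a,), bwd)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = _wrap(a)
    out = np.exp(a.data)

    def bwd(g):
        return (g * out,)

    return _node(out, (a,), bwd)


def log(a) -> Tensor:
    a = _wrap(a)
    out = np.log(a.data)

    def bwd(g):
        return (g / a.data,)

    return _node(out, (a,), bwd)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out = np.tanh(a.data)

    def bwd(g):
        return (g * (1.0 - out * out),)

    return _node(out, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), bwd)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = np.where(mask, a.data, 0.0)

    def bwd(g):
        return (g * mask,)

    return _node(out, (a,), bwd)


def leaky_relu(a, alpha: float = 0.05) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = np.where(mask, a.data, alpha * a.data)

    def bwd(g):
        return (g * np.where(mask, 1.0, alpha),)

    return _node(out, (a,), bwd)


# ---------------------------------------------------------------- reductions
def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out, (a,), bwd)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / max(out.size, 1)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape) / n,)

    return _node(out, (a,), bwd)


# ------------------------------------------------------------- shape / index
def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = a.data.reshape(shape)

    def bwd(g):
        return (g.reshape(a.data.shape),)

    return _node(out, (a,), bwd)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _wrap(a)
    out = a.data.swapaxes(ax1, ax2)

    def bwd(g):
        return (g.swapaxes(ax1, ax2),)

    return _node(out, (a,), bwd)


def flip(a, axis: int) -> Tensor:
    a = _wrap(a)
    out = np.flip(a.data, axis=axis)

    def bwd(g):
        return (np.flip(g, axis=axis),)

    return _node(out, (a,), bwd)


def take(a, idx) -> Tensor:
    """Basic or integer-array indexing; backward scatter-adds."""
    a = _wrap(a)
    out = a.data[idx]

    def bwd(g):
        ga = np.zeros_like(a.data, dtype=g.dtype if g.dtype.kind == "f" else np.float64)
        np.add.at(ga, idx, g)
        return (ga,)

    return _node(out, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    cuts = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, cuts, axis=axis))

    return _node(out, tuple(tensors), bwd)


# ------------------------------------------------------------- linear algebra
def matmul(a, b) -> Tensor:
    """``numpy.matmul`` semantics (supports stacked/batched operands)."""
    a, b = _wrap(a), _wrap(b)
    out = np.matmul(a.data, b.data)

    def bwd(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1:
            ga = np.matmul(g[..., None, :], np.swapaxes(bd, -1, -2))[..., 0, :]
        else:
            ga = np.matmul(g, np.swapaxes(bd, -1, -2)) if bd.ndim > 1 else np.multiply.outer(g, bd)
        if bd.ndim == 1:
            gb = np.matmul(np.swapaxes(ad, -1, -2), g[..., None])[..., 0]
        elif bd.ndim == 2 and ad.ndim >= 2:
            # stacked-input @ shared-weight: contract all leading axes at
            # once instead of materializing per-sample outer products
            gb = ad.reshape(-1, ad.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        else:
            gb = np.matmul(np.swapaxes(ad, -1, -2), g) if ad.ndim > 1 else np.multiply.outer(ad, g)
        return _unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape)

    return _node(out, (a, b), bwd)


# -------------------------------------------------------------- convolutions
def conv1d(x, w, b=None) -> Tensor:
    """1D cross-correlation with 'same' zero padding, stride 1.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K) with K odd; ``b``: (C_out,).
    """
    x, w = _wrap(x), _wrap(w)
    B, Cin, L = x.data.shape
    Cout, Cin2, K = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin2}")
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size")
    P = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (P, P)))
    out = np.zeros((B, Cout, L), dtype=np.result_type(x.data, w.data))
    for k in range(K):
        out += np.matmul(w.data[:, :, k], xp[:, :, k : k + L])
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out = out + b.data[None, :, None]
        parents.append(b)

    def bwd(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k in range(K):
            gxp[:, :, k : k + L] += np.matmul(w.data[:, :, k].T, g)
            gw[:, :, k] = np.tensordot(g, xp[:, :, k : k + L], axes=([0, 2], [0, 2]))
        gx = gxp[:, :, P : P + L]
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2))

    return _node(out, tuple(parents), bwd)


def conv1d_weight_transposed(w: Tensor) -> Tensor:
    """The kernel whose 'same' conv computes the input gradient of ``conv1d``.

    For odd K and symmetric padding, d(conv1d(x, w))/dx applied to an output
    cotangent g equals ``conv1d(g, w.swapaxes(0, 1).flip(2))``.
    """
    return flip(swapaxes(w, 0, 1), 2)


# ---------------------------------------------------------------- upsampling
def upsample_matrix(L_in: int, L_out: int, dtype=np.float64) -> np.ndarray:
    """Dense (L_in, L_out) linear-interpolation matrix mapping endpoints to
    endpoints (positions ``linspace(0, L_in-1, L_out)``)."""
    pos = np.linspace(0.0, L_in - 1.0, L_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, L_in - 1)
    frac = pos - lo
    A = np.zeros((L_in, L_out), dtype=dtype)
    A[lo, np.arange(L_out)] += 1.0 - frac
    A[hi, np.arange(L_out)] += frac
    return A


def upsample_linear(x, L_out: int) -> Tensor:
    """Linearly resample (B, C, L) along the last axis to length ``L_out``."""
    x = _wrap(x)
    A = Tensor(upsample_matrix(x.data.shape[-1], L_out, dtype=x.data.dtype))
    return matmul(x, A)


# ------------------------------------------------------------------ backward
def backward(t: Tensor, grad=None) -> None:
    """Run reverse-mode accumulation from ``t``.

    Gradients land on every reachable leaf with ``requires_grad=True``.
    """
    topo: list[Tensor] = []
    seen: set[int] = set()
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
            if id(p) not in seen and (p._backward is not None or p.requires_grad):
                stack.append((p, False))

    t.grad = np.ones_like(t.data) if grad is None else np.asarray(grad)
    for node in reversed(topo):
        if node._backward is None or node.grad is None:
            continue
        grads = node._backward(node.grad)
        for parent, g in zip(node._parents, grads):
            if g is None or not (parent.requires_grad or parent._backward is not None):
                continue
            if parent.grad is None:
                parent.grad = np.asarray(g, dtype=parent.data.dtype).copy()
            else:
                parent.grad += g
        if not node.requires_grad:
            node.grad = None  # free intermediate cotangents early
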