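"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the translation networks need: elementwise
arithmetic with broadcasting, SiLU/tanh, global mean, spatial slicing,
channel concatenation, 3D convolution (stride 1 or 2), nearest-neighbour
x2 upsampling, group normalization, and a box ("uniform") filter used by the
differentiable SSIM.  Gradients are accumulated by topological-order
backpropagation from a scalar loss.  Training runs in float32; every op's backward
is finite-difference checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["Tensor", "concat", "conv3d", "group_norm", "upsample2", "uniform_filter", "crop"]


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- graph machinery -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- elementwise ops -------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            _accum(self, -g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = self.data / other.data

        def bwd(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * out / other.data, other.data.shape))

        return Tensor(out, _parents=(self, other), _backward=bwd)

    def square(self):
        def bwd(g):
            _accum(self, 2.0 * g * self.data)

        return Tensor(self.data**2, _parents=(self,), _backward=bwd)

    def abs(self):
        def bwd(g):
            _accum(self, g * np.sign(self.data))

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bwd)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * sig

        def bwd(g):
            _accum(self, g * (sig * (1.0 + self.data * (1.0 - sig))))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            _accum(self, g * (1.0 - out**2))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            _accum(self, np.full_like(self.data, float(g) / n))

        return Tensor(self.data.mean(), _parents=(self,), _backward=bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        if t.grad is None:
            t.grad = np.array(np.broadcast_to(g, t.data.shape), dtype=t.data.dtype)
        else:
            t.grad += g.astype(t.data.dtype, copy=False)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def crop(t: Tensor, slices) -> Tensor:
    """Slice a tensor; backward scatters the gradient into zeros."""
    slices = tuple(slices)

    def bwd(g):
        full = np.zeros_like(t.data)
        full[slices] = g
        _accum(t, full)

    return Tensor(t.data[slices], _parents=(t,), _backward=bwd)


def _conv_ranges(n_in: int, n_out: int, k_off: int, stride: int, pad: int):
    """Valid output/input index ranges for one kernel offset of a zero-padded conv.

    Output index ``o`` reads input index ``o*stride + k_off - pad``; returns
    ``(o_lo, o_hi, i_lo)`` with ``o_hi`` exclusive, or None if empty.
    """
    o_lo = max(0, -(-(pad - k_off) // stride))
    o_hi = min(n_out - 1, (n_in - 1 - k_off + pad) // stride)
    if o_hi < o_lo:
        return None
    return o_lo, o_hi + 1, o_lo * stride + k_off - pad


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 1) -> Tensor:
    """3D cross-correlation, NCDHW layout, kernel OCkkk, zero padding.

    Computed as a sum over kernel offsets of channel contractions on the
    valid (in-bounds) region, which gives exact zero-padding semantics
    without materializing a padded copy.
    """
    s = int(stride)
    p = int(padding)
    xd = x.data
    N, C, D, H, W = xd.shape
    O, Cw, kd, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, kernel {Cw}")
    Do, Ho, Wo = (D + 2 * p - kd) // s + 1, (H + 2 * p - kh) // s + 1, (W + 2 * p - kw) // s + 1
    y = np.zeros((N, O, Do, Ho, Wo), dtype=np.result_type(xd, w.data))

    def offset_slices():
        for i in range(kd):
            rd = _conv_ranges(D, Do, i, s, p)
            if rd is None:
                continue
            for j in range(kh):
                rh = _conv_ranges(H, Ho, j, s, p)
                if rh is None:
                    continue
                for k in range(kw):
                    rw = _conv_ranges(W, Wo, k, s, p)
                    if rw is None:
                        continue
                    out_sl = (
                        slice(None), slice(None),
                        slice(rd[0], rd[1]), slice(rh[0], rh[1]), slice(rw[0], rw[1]),
                    )
                    in_sl = (
                        slice(None), slice(None),
                        slice(rd[2], rd[2] + (rd[1] - rd[0]) * s, s),
                        slice(rh[2], rh[2] + (rh[1] - rh[0]) * s, s),
                        slice(rw[2], rw[2] + (rw[1] - rw[0]) * s, s),
                    )
                    yield (i, j, k), out_sl, in_sl

    for (i, j, k), out_sl, in_sl in offset_slices():
        y[out_sl] += np.einsum("ncdhw,oc->nodhw", xd[in_sl], w.data[:, :, i, j, k], optimize=True)
    if b is not None:
        y += b.data.reshape(1, O, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gx = np.zeros_like(xd)
        gw = np.zeros_like(w.data)
        for (i, j, k), out_sl, in_sl in offset_slices():
            gw[:, :, i, j, k] = np.einsum("ncdhw,nodhw->oc", xd[in_sl], g[out_sl], optimize=True)
            gx[in_sl] += np.einsum("nodhw,oc->ncdhw", g[out_sl], w.data[:, :, i, j, k], optimize=True)
        _accum(x, gx)
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))

    return Tensor(y, _parents=parents, _backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of the three spatial axes."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def bwd(g):
        N, C, D, H, W = x.data.shape
        _accum(x, g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7)))

    return Tensor(y, _parents=(x,), _backward=bwd)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over (channels/groups, spatial) per sample."""
    N, C = x.data.shape[:2]
    if C % groups:
        raise ValueError(f"{groups} groups do not divide {C} channels")
    spatial = x.data.shape[2:]
    xg = x.data.reshape(N, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv
    xhat_full = xhat.reshape(x.data.shape)
    gshape = (1, C) + (1,) * len(spatial)
    y = xhat_full * gamma.data.reshape(gshape) + beta.data.reshape(gshape)

    def bwd(g):
        _accum(gamma, (g * xhat_full).sum(axis=(0,) + tuple(range(2, g.ndim))))
        _accum(beta, g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        dxhat = (g * gamma.data.reshape(gshape)).reshape(N, groups, -1)
        m = dxhat.shape[2]
        dx = inv * (
            dxhat
            - dxhat.mean(axis=2, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=2, keepdims=True)
        )
        _accum(x, dx.reshape(x.data.shape))

    return Tensor(y, _parents=(x, gamma, beta), _backward=bwd)


def uniform_filter(x: Tensor, size: int) -> Tensor:
    """Box-mean filter over the spatial axes with zero padding.

    The operator is symmetric (box kernel, constant-zero boundary), so its
    adjoint — the backward pass — is the same filter applied to the gradient.
    """
    full = (1, 1) + (size,) * (x.data.ndim - 2)

    def run(a):
        return ndimage.uniform_filter(a, size=full, mode="constant", cval=0.0)

    def bwd(g):
        _accum(x, run(g.astype(x.data.dtype, copy=False)))

    return Tensor(run(x.data), _parents=(x,), _backward=bwd)
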