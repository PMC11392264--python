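"""Reverse-mode automatic differentiation on numpy arrays.

The package trains convolutional networks on the CPU, so the engine is built
around operations that reduce to large GEMMs: convolution is lowered to an
im2col matrix product, and bilinear resampling is expressed as a pair of
(dense) interpolation-matrix products.  Each operation records a closure that
propagates the upstream gradient to its parents; ``Tensor.backward`` runs the
closures in reverse topological order.

All operations preserve the dtype of their inputs, which lets the test suite
run finite-difference gradient checks in float64 while the network itself
runs in float32.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (and im2col caching) inside the block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- properties -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the graph node-by-node so im2col caches are reclaimed;
                # only leaves (parameters, inputs) keep their gradient
                node._backward = None
                node._parents = ()
                node.grad = None

    # -- operator sugar -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise and reduction ops -------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def relu(x):
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


def leaky_relu(x, slope=0.01):
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(mask, 1.0, slope))

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x):
    x = as_tensor(x)
    xd = x.data
    out_data = np.empty_like(xd)
    pos = xd >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
    ex = np.exp(xd[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), backward)


def log(x):
    x = as_tensor(x)
    out_data = np.log(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor._result(out_data, (x,), backward)


def clip(x, lo, hi):
    """Clamp values to [lo, hi]; gradient passes only through the interior."""
    x = as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    interior = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * interior)

    return Tensor._result(out_data, (x,), backward)


def tsum(x, axis=None, keepdims=False):
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if x.requires_grad:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.data.shape))

    return Tensor._result(out_data, (x,), backward)


def tmean(x, axis=None, keepdims=False):
    x = as_tensor(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size // out_data.size

    def backward(g):
        if x.requires_grad:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.data.shape) / n)

    return Tensor._result(out_data, (x,), backward)


def tmax(x, axis, keepdims=True):
    """Maximum along one axis; gradient routed to the (first) argmax."""
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if x.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            x._accumulate(gx)

    return Tensor._result(out_data, (x,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


# -- convolution --------------------------------------------------------------


def _im2col(xd, kh, kw, s, p):
    """Lower (B, C, H, W) to an (B*Ho*Wo, C*kh*kw) patch matrix."""
    if p:
        xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    B, C, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw)
    return cols, Ho, Wo


def _corr(xd, wd, s, p):
    """Raw cross-correlation of arrays (forward conv without autograd)."""
    Co, Ci, kh, kw = wd.shape
    if kh == 1 and kw == 1 and s == 1 and p == 0:
        B, _, H, W = xd.shape
        out = wd.reshape(Co, Ci) @ xd.reshape(B, Ci, H * W)
        return out.reshape(B, Co, H, W)
    B = xd.shape[0]
    cols, Ho, Wo = _im2col(xd, kh, kw, s, p)
    out = cols @ wd.reshape(Co, -1).T
    return np.ascontiguousarray(out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)), cols


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation, NCHW layout, lowered to im2col GEMMs.

    x: (B, Ci, H, W); w: (Co, Ci, kh, kw); b: (Co,) or None.  The input
    gradient is computed as a transposed convolution (zero-dilated upstream
    gradient correlated with the flipped kernel), so the backward pass is
    GEMM-bound as well.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Ci, H, W = x.data.shape
    Co, Ci2, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv2d channel mismatch: input {Ci} vs weight {Ci2}")
    s, p = int(stride), int(padding)
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d output would be empty for input {H}x{W}, kernel {kh}")
    if p > kh - 1 or p > kw - 1:
        raise ValueError("padding larger than kernel-1 is not supported")

    needs_grad = _grad_enabled and (x.requires_grad or w.requires_grad
                                    or (b is not None and b.requires_grad))
    pointwise = kh == 1 and kw == 1 and s == 1 and p == 0
    wmat = w.data.reshape(Co, -1)
    if pointwise:
        out_data = (wmat @ x.data.reshape(B, Ci, H * W)).reshape(B, Co, H, W)
        cols = None
    else:
        cols, _, _ = _im2col(x.data, kh, kw, s, p)
        out_data = np.ascontiguousarray(
            (cols @ wmat.T).reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data[None, :, None, None]
    if not needs_grad:
        return Tensor(out_data)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if pointwise:
            gflat = g.reshape(B, Co, H * W)
            if w.requires_grad:
                gw = np.einsum("boi,bci->oc", gflat, x.data.reshape(B, Ci, H * W),
                               optimize=True)
                w._accumulate(gw.reshape(w.data.shape))
            if x.requires_grad:
                gx = wmat.T @ gflat
                x._accumulate(gx.reshape(B, Ci, H, W))
            return
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Co)
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            # transposed convolution: dilate g by the stride, correlate with
            # the channel-swapped, spatially flipped kernel
            # rows/cols of x past the last window need extra dilation padding
            rh = (H + 2 * p - kh) % s
            rw = (W + 2 * p - kw) % s
            if s > 1 or rh or rw:
                gd = np.zeros((B, Co, (Ho - 1) * s + 1 + rh, (Wo - 1) * s + 1 + rw),
                              dtype=g.dtype)
                gd[:, :, :(Ho - 1) * s + 1:s, :(Wo - 1) * s + 1:s] = g
            else:
                gd = g
            wT = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            res = _corr(gd, wT.astype(g.dtype, copy=False), 1, kh - 1 - p)
            gx = res[0] if isinstance(res, tuple) else res
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


# -- pooling ------------------------------------------------------------------


def maxpool2d(x, kernel=3, stride=2, padding=1):
    """Max pooling with the given square window (NCHW)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    fill = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        Hp, Wp = H + 2 * p, W + 2 * p
        gxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
        ii, jj = np.unravel_index(idx, (k, k))
        oy = np.arange(Ho)[:, None] * s
        ox = np.arange(Wo)[None, :] * s
        rows = (oy[None, None] + ii).ravel()
        cols_ = (ox[None, None] + jj).ravel()
        bb = np.repeat(np.arange(B), C * Ho * Wo)
        cc = np.tile(np.repeat(np.arange(C), Ho * Wo), B)
        np.add.at(gxp, (bb, cc, rows, cols_), g.ravel())
        x._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return Tensor._result(out_data, (x,), backward)


def global_avg_pool(x):
    """Mean over the spatial axes, keeping (B, C, 1, 1)."""
    return tmean(x, axis=(2, 3), keepdims=True)


# -- bilinear resampling ------------------------------------------------------


@lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int, dtype_str: str) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out, n_in), half-pixel centres."""
    M = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = src - i0
    M[np.arange(n_out), i0] += 1.0 - w
    M[np.arange(n_out), i1] += w
    return M


def interpolate_bilinear(x, size):
    """Resize (B, C, H, W) to (B, C, *size) by separable bilinear interpolation.

    Uses the half-pixel (corner-aligned-off) convention everywhere so that the
    deep-supervision mask and the skip-fusion gates sample identically.
    """
    x = as_tensor(x)
    Ho, Wo = size
    B, C, H, W = x.data.shape
    if (H, W) == (Ho, Wo):
        return x
    dt = x.data.dtype.str
    R = _interp_matrix(H, Ho, dt)
    Cm = _interp_matrix(W, Wo, dt)
    out_data = np.matmul(np.matmul(R, x.data), Cm.T)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(R.T, g), Cm))

    return Tensor._result(out_data, (x,), backward)


# -- batch normalization ------------------------------------------------------


def batchnorm2d(x, gamma, beta, running_mean, running_var, momentum=0.1,
                eps=1e-5, training=True):
    """Channel-wise batch normalization for NCHW tensors.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    (they are state, not graph nodes).  In training mode the batch statistics
    normalize; in eval mode the running statistics do.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    B, C, H, W = x.data.shape
    n = B * H * W
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        if running_mean is not None:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            unbiased = var * (n / max(n - 1, 1))
            running_var *= 1.0 - momentum
            running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / n - xhat * s2 / n) * invstd[None, :, None, None]
            else:
                gx = gxhat * invstd[None, :, None, None]
            x._accumulate(gx)

    return Tensor._result(out_data, (x, gamma, beta), backward)
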