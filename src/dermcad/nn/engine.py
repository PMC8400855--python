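"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small encoder/decoder CNNs; rather than
depend on a heavyweight deep-learning framework, training runs on this
compact tape-based engine.  A :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it; calling :meth:`Tensor.backward`
on a scalar loss walks the tape in reverse topological order and
accumulates gradients into every tensor created with
``requires_grad=True``.

All gradients are checked against central finite differences in the test
suite; convolution is implemented as im2col + BLAS matmul so CPU training
stays practical.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "log",
    "exp",
    "clamp_min",
    "relu",
    "tsum",
    "tmean",
    "reshape",
    "concat",
    "center_crop",
    "take_channel",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "dense",
    "global_avg_pool",
    "softmax",
    "batchnorm2d",
    "softmax_cross_entropy",
    "weighted_softmax_cross_entropy",
]

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


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def needs_grad(self) -> bool:
        return self.requires_grad or self._backward is not None

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
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
        self.grad = np.ones_like(self.data, dtype=np.result_type(self.data, np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.needs_grad for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# --------------------------------------------------------------------------
# elementwise arithmetic
# --------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.needs_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.needs_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.needs_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.needs_grad:
            b.accumulate(_unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.needs_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.needs_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.needs_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.needs_grad:
            b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.needs_grad:
            a.accumulate(-g)

    return _make(-a.data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.needs_grad:
            a.accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.needs_grad:
            a.accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def clamp_min(a, lo: float) -> Tensor:
    """max(a, lo); the gradient is gated off where the clamp is active."""
    a = _as_tensor(a)
    mask = a.data >= lo

    def backward(g):
        if a.needs_grad:
            a.accumulate(g * mask)

    return _make(np.maximum(a.data, lo), (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.needs_grad:
            a.accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.needs_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g2, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.needs_grad:
            a.accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


# --------------------------------------------------------------------------
# structural ops
# --------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.needs_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return _make(out_data, tuple(ts), backward)


def center_crop(a, out_hw: tuple[int, int]) -> Tensor:
    """Center-crop the trailing two spatial axes of an NCHW tensor."""
    a = _as_tensor(a)
    H, W = a.data.shape[-2:]
    oh, ow = out_hw
    if oh > H or ow > W:
        raise ValueError(f"cannot crop {(H, W)} to larger {(oh, ow)}")
    top, left = (H - oh) // 2, (W - ow) // 2
    sl = (Ellipsis, slice(top, top + oh), slice(left, left + ow))
    out_data = a.data[sl]

    def backward(g):
        if a.needs_grad:
            gx = np.zeros_like(a.data)
            gx[sl] = g
            a.accumulate(gx)

    return _make(out_data, (a,), backward)


def take_channel(a, idx: int) -> Tensor:
    """Select channel ``idx`` of an NCHW tensor -> NHW."""
    a = _as_tensor(a)
    out_data = a.data[:, idx]

    def backward(g):
        if a.needs_grad:
            gx = np.zeros_like(a.data)
            gx[:, idx] = g
            a.accumulate(gx)

    return _make(out_data, (a,), backward)


# --------------------------------------------------------------------------
# neural-network ops (NCHW layout)
# --------------------------------------------------------------------------

def conv2d(x, w, b, pad: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with OCkk kernels, stride 1.

    Internally works in NHWC: the im2col matrix is assembled from the
    k*k shifted channel-contiguous slices, which keeps the copies on
    fast memory paths before the BLAS matmul.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = xd.shape
    O, _, kh, kw = w.data.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"input {H}x{W} too small for {kh}x{kw} valid convolution")
    xt = np.ascontiguousarray(xd.transpose(0, 2, 3, 1))  # NHWC
    cols = np.concatenate(
        [xt[:, i : i + Ho, j : j + Wo, :] for i in range(kh) for j in range(kw)],
        axis=3,
    ).reshape(N * Ho * Wo, kh * kw * C)
    # weight layout matching the (i, j, c) column ordering above
    Wm = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(kh * kw * C, O)
    y = cols @ Wm
    y += b.data[None, :]
    out_data = np.ascontiguousarray(y.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2))

    def backward(g):
        gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if b.needs_grad:
            b.accumulate(gflat.sum(axis=0))
        if w.needs_grad:
            gW = (cols.T @ gflat).reshape(kh, kw, C, O)
            w.accumulate(np.ascontiguousarray(gW.transpose(3, 2, 0, 1)))
        if x.needs_grad:
            gcols = (gflat @ Wm.T).reshape(N, Ho, Wo, kh * kw, C)
            gxt = np.zeros((N, H, W, C), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxt[:, i : i + Ho, j : j + Wo, :] += gcols[:, :, :, i * kw + j, :]
            gx = np.ascontiguousarray(gxt.transpose(0, 3, 1, 2))
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x.accumulate(gx)

    return _make(out_data, (x, w, b), backward)


def conv_transpose2x2(x, w, b) -> Tensor:
    """2x2 stride-2 transposed convolution (the up-sampling step).

    ``w`` has shape (C_in, C_out, 2, 2); output is exactly double the
    spatial size, so windows never overlap and the op reduces to an
    einsum plus a reshape.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    N, C, H, W = x.data.shape
    _, O, _, _ = w.data.shape
    y6 = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out_data = y6.reshape(N, O, 2 * H, 2 * W) + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(N, O, H, 2, W, 2)
        if b.needs_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.needs_grad:
            w.accumulate(np.einsum("nchw,nohiwj->coij", x.data, g6, optimize=True))
        if x.needs_grad:
            x.accumulate(np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True))

    return _make(out_data, (x, w, b), backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling, stride 2; spatial sides must be even."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even sides, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xr = np.ascontiguousarray(
        x.data.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(N, C, Ho, Wo, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.needs_grad:
            return
        g4 = np.zeros((N, C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = (
            g4.reshape(N, C, Ho, Wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        x.accumulate(gx)

    return _make(out_data, (x,), backward)


def dense(x, w, b) -> Tensor:
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    out_data = x.data @ w.data + b.data

    def backward(g):
        if b.needs_grad:
            b.accumulate(g.sum(axis=0))
        if w.needs_grad:
            w.accumulate(x.data.T @ g)
        if x.needs_grad:
            x.accumulate(g @ w.data.T)

    return _make(out_data, (x, w, b), backward)


def global_avg_pool(x) -> Tensor:
    """NCHW -> NC by averaging each feature map."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.needs_grad:
            x.accumulate(
                np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).copy()
            )

    return _make(out_data, (x,), backward)


def softmax(x, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.needs_grad:
            x.accumulate(p * (g - (g * p).sum(axis=axis, keepdims=True)))

    return _make(p, (x,), backward)


def batchnorm2d(x, gamma, beta, state: dict, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``state`` carries the running mean/variance used at inference; it is
    mutated in place during training passes.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        state["mean"] = (1 - momentum) * state["mean"] + momentum * mu
        state["var"] = (1 - momentum) * state["var"] + momentum * var
    else:
        mu, var = state["mean"], state["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = xd.shape[0] * xd.shape[2] * xd.shape[3]

    def backward(g):
        if beta.needs_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.needs_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.needs_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv_std[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)
            else:
                gx = gxhat * inv_std[None, :, None, None]
            x.accumulate(gx)

    return _make(out_data, (x, gamma, beta), backward)


# --------------------------------------------------------------------------
# fused classification losses
# --------------------------------------------------------------------------

def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a (N, K) logit matrix with int labels."""
    logits = _as_tensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = p.shape[0]
    pt = p[np.arange(n), labels]
    out_data = np.array(-np.log(np.maximum(pt, 1e-12)).mean())

    def backward(g):
        if logits.needs_grad:
            gz = p.copy()
            gz[np.arange(n), labels] -= 1.0
            logits.accumulate(gz * (float(g) / n))

    return _make(out_data, (logits,), backward)


def weighted_softmax_cross_entropy(logits, labels: np.ndarray,
                                   weights: np.ndarray) -> Tensor:
    """Per-pixel weighted cross-entropy on (N, K, H, W) logits.

    Implements the boundary-weighted segmentation loss: each pixel's
    negative log-likelihood of its true class is multiplied by the
    weight-map value, and the result is averaged over all pixels so the
    magnitude is insensitive to image size.
    """
    logits = _as_tensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    pt = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    npix = pt.size
    out_data = np.array((weights * -np.log(np.maximum(pt, 1e-12))).mean())

    def backward(g):
        if logits.needs_grad:
            onehot = (labels[:, None] == np.arange(p.shape[1])[None, :, None, None])
            gz = (p - onehot) * weights[:, None]
            logits.accumulate(gz * (float(g) / npix))

    return _make(out_data, (logits,), backward)
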