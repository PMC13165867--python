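"""Differentiable array operations (NHWC layout).

Convolutions are evaluated with ``sliding_window_view`` + ``tensordot``
(im2col); their input gradients are accumulated with a short loop over
kernel offsets (col2im).  ``same`` padding follows the usual convention
of putting the extra pixel on the bottom/right, which is also what the
stride-1 even-kernel max pooling of the MCP block requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .tensor import Tensor, accumulate_grad

__all__ = [
    "conv2d",
    "conv2d_transpose",
    "maxpool2d",
    "avgpool2d",
    "batchnorm",
    "relu",
    "sigmoid",
    "concat",
    "global_avg_pool",
    "broadcast_hw",
    "resize_bilinear",
    "add",
    "dice_loss",
]


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


def _same_padding(h, w, kh, kw, sh, sw, dh=1, dw=1):
    """(top, bottom, left, right) padding reproducing TF/Keras 'same'."""
    eff_kh = (kh - 1) * dh + 1
    eff_kw = (kw - 1) * dw + 1
    out_h = -(-h // sh)
    out_w = -(-w // sw)
    pad_h = max((out_h - 1) * sh + eff_kh - h, 0)
    pad_w = max((out_w - 1) * sw + eff_kw - w, 0)
    return pad_h // 2, pad_h - pad_h // 2, pad_w // 2, pad_w - pad_w // 2


def _pad_nhwc(x, pads, value=0.0):
    pt, pb, pl, pr = pads
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(
        x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=value
    )


def _windows(xp, kh, kw, sh, sw, dh, dw):
    """View of all kernel windows: (N, OH, OW, C, kh, kw)."""
    eff_kh = (kh - 1) * dh + 1
    eff_kw = (kw - 1) * dw + 1
    win = sliding_window_view(xp, (eff_kh, eff_kw), axis=(1, 2))
    return win[:, ::sh, ::sw, :, ::dh, ::dw]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride=1,
    dilation=1,
    padding: str = "same",
) -> Tensor:
    """2-D cross-correlation; ``w`` has shape (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.shape
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    n, h, wd, c = x.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cin}")
    if padding == "same":
        pads = _same_padding(h, wd, kh, kw, sh, sw, dh, dw)
    elif padding == "valid":
        pads = (0, 0, 0, 0)
    else:  # pragma: no cover - guarded by layer constructors
        raise ValueError(f"unknown padding {padding!r}")
    xp = _pad_nhwc(x.data, pads)
    win = _windows(xp, kh, kw, sh, sw, dh, dw)
    out = np.tensordot(win, w.data, axes=([3, 4, 5], [2, 0, 1]))
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)
    oh, ow = out.shape[1], out.shape[2]
    pt, _, pl, _ = pads

    def backward(g: np.ndarray) -> None:
        if b is not None:
            accumulate_grad(b, g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            dw_ = np.tensordot(win, g, axes=([0, 1, 2], [0, 1, 2]))
            accumulate_grad(w, np.transpose(dw_, (1, 2, 0, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :,
                        i * dh : i * dh + oh * sh : sh,
                        j * dw : j * dw + ow * sw : sw,
                        :,
                    ] += g @ w.data[i, j].T
            accumulate_grad(x, dxp[:, pt : pt + h, pl : pl + wd, :])

    return Tensor(out, parents, backward)


def conv2d_transpose(x: Tensor, w: Tensor, b: Tensor | None = None, stride=2) -> Tensor:
    """Transposed convolution with 'same'-style output size H*stride.

    ``w`` has shape (kh, kw, cin, cout).
    """
    kh, kw, cin, cout = w.shape
    sh, sw = _pair(stride)
    n, h, wd, c = x.shape
    if c != cin:
        raise ValueError(f"conv2d_transpose: input has {c} channels, expects {cin}")
    full_h = (h - 1) * sh + kh
    full_w = (wd - 1) * sw + kw
    out_h, out_w = h * sh, wd * sw
    ct = max(kh - sh, 0) // 2
    cl = max(kw - sw, 0) // 2
    yf = np.zeros((n, full_h, full_w, cout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            yf[:, i : i + h * sh : sh, j : j + wd * sw : sw, :] += x.data @ w.data[i, j]
    out = yf[:, ct : ct + out_h, cl : cl + out_w, :]
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g: np.ndarray) -> None:
        if b is not None:
            accumulate_grad(b, g.sum(axis=(0, 1, 2)))
        gf = np.zeros((n, full_h, full_w, cout), dtype=g.dtype)
        gf[:, ct : ct + out_h, cl : cl + out_w, :] = g
        if w.requires_grad:
            dw_ = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gs = gf[:, i : i + h * sh : sh, j : j + wd * sw : sw, :]
                    dw_[i, j] = np.tensordot(
                        x.data, gs, axes=([0, 1, 2], [0, 1, 2])
                    )
            accumulate_grad(w, dw_)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    gs = gf[:, i : i + h * sh : sh, j : j + wd * sw : sw, :]
                    dx += gs @ w.data[i, j].T
            accumulate_grad(x, dx)

    return Tensor(out, parents, backward)


def maxpool2d(x: Tensor, kernel=2, stride=1, padding: str = "same") -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    n, h, wd, c = x.shape
    if padding == "same":
        pads = _same_padding(h, wd, kh, kw, sh, sw)
    else:
        pads = (0, 0, 0, 0)
    if kh > h + pads[0] + pads[1] or kw > wd + pads[2] + pads[3]:
        raise ValueError(
            f"maxpool2d: kernel {kh}x{kw} larger than padded input {h}x{wd}"
        )
    xp = _pad_nhwc(x.data, pads, value=-np.inf)
    win = _windows(xp, kh, kw, sh, sw, 1, 1)
    out = win.max(axis=(4, 5))
    oh, ow = out.shape[1], out.shape[2]
    pt, _, pl, _ = pads

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, i : i + oh * sh : sh, j : j + ow * sw : sw, :]
                dxp[:, i : i + oh * sh : sh, j : j + ow * sw : sw, :] += (
                    sl == out
                ) * g
        accumulate_grad(x, dxp[:, pt : pt + h, pl : pl + wd, :])

    return Tensor(out, (x,), backward)


def avgpool2d(x: Tensor, kernel=3, stride=1, padding: str = "same") -> Tensor:
    """Average pooling; padded positions are excluded from the mean."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    n, h, wd, c = x.shape
    pads = _same_padding(h, wd, kh, kw, sh, sw) if padding == "same" else (0, 0, 0, 0)
    xp = _pad_nhwc(x.data, pads)
    ones = _pad_nhwc(np.ones((1, h, wd, 1), dtype=x.dtype), pads)
    win = _windows(xp, kh, kw, sh, sw, 1, 1)
    count = _windows(ones, kh, kw, sh, sw, 1, 1).sum(axis=(4, 5))
    out = win.sum(axis=(4, 5)) / count
    oh, ow = out.shape[1], out.shape[2]
    pt, _, pl, _ = pads

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gc = g / count
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + oh * sh : sh, j : j + ow * sw : sw, :] += gc
        accumulate_grad(x, dxp[:, pt : pt + h, pl : pl + wd, :])

    return Tensor(out, (x,), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.99,
    eps: float = 1e-3,
) -> Tensor:
    """Per-channel batch normalization over the (N, H, W) axes.

    ``running_mean``/``running_var`` are plain arrays owned by the layer and
    are updated in place while ``training`` is true.
    """
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out = gamma.data * xhat + beta.data
    m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def backward(g: np.ndarray) -> None:
        accumulate_grad(beta, g.sum(axis=(0, 1, 2)))
        accumulate_grad(gamma, (g * xhat).sum(axis=(0, 1, 2)))
        if not x.requires_grad:
            return
        if training:
            dxhat = g * gamma.data
            s1 = dxhat.sum(axis=(0, 1, 2))
            s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
            dx = ivar * (dxhat - s1 / m - xhat * s2 / m)
        else:
            dx = g * gamma.data * ivar
        accumulate_grad(x, dx)

    return Tensor(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def backward(g: np.ndarray) -> None:
        accumulate_grad(x, g * (x.data > 0))

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = expit(x.data)

    def backward(g: np.ndarray) -> None:
        accumulate_grad(x, g * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        accumulate_grad(a, g)
        accumulate_grad(b, g)

    return Tensor(out, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            accumulate_grad(t, piece)

    return Tensor(out, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, H, W, C) -> (N, 1, 1, C) spatial mean."""
    out = x.data.mean(axis=(1, 2), keepdims=True)
    n, h, wd, c = x.shape

    def backward(g: np.ndarray) -> None:
        accumulate_grad(x, np.broadcast_to(g / (h * wd), x.shape).copy())

    return Tensor(out, (x,), backward)


def broadcast_hw(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-style upsampling of a (N, 1, 1, C) map to (N, H, W, C)."""
    h, w = size
    out = np.broadcast_to(x.data, (x.shape[0], h, w, x.shape[3])).copy()

    def backward(g: np.ndarray) -> None:
        accumulate_grad(x, g.sum(axis=(1, 2), keepdims=True))

    return Tensor(out, (x,), backward)


def _resize_coeffs(n_in: int, n_out: int):
    """Half-pixel-centre bilinear sampling coefficients along one axis."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = (src - i0).astype(np.float32)
    return i0, i1, t


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    oh, ow = int(size[0]), int(size[1])
    n, h, w, c = x.shape
    if (oh, ow) == (h, w):
        out = x.data

        def backward_id(g: np.ndarray) -> None:
            accumulate_grad(x, g)

        return Tensor(out, (x,), backward_id)

    r0, r1, tr = _resize_coeffs(h, oh)
    c0, c1, tc = _resize_coeffs(w, ow)
    tr_ = tr[None, :, None, None]
    rows = x.data[:, r0] * (1 - tr_) + x.data[:, r1] * tr_
    tc_ = tc[None, None, :, None]
    out = rows[:, :, c0] * (1 - tc_) + rows[:, :, c1] * tc_

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        # transpose of the column interpolation
        drows = np.zeros((w, n, oh, c), dtype=g.dtype)
        gt = g.transpose(2, 0, 1, 3)
        np.add.at(drows, c0, gt * (1 - tc)[:, None, None, None])
        np.add.at(drows, c1, gt * tc[:, None, None, None])
        drows = drows.transpose(1, 2, 0, 3)  # (N, OH, W, C)
        # transpose of the row interpolation
        dx = np.zeros((h, n, w, c), dtype=g.dtype)
        dt = drows.transpose(1, 0, 2, 3)
        np.add.at(dx, r0, dt * (1 - tr)[:, None, None, None])
        np.add.at(dx, r1, dt * tr[:, None, None, None])
        accumulate_grad(x, dx.transpose(1, 0, 2, 3))

    return Tensor(out, (x,), backward)


def dice_loss(pred: Tensor, truth: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Mean per-sample soft Dice loss 1 - (2*sum(p*y)+s)/(sum(p)+sum(y)+s)."""
    y = np.asarray(truth, dtype=pred.dtype)
    if y.shape != pred.shape:
        raise ValueError(
            f"dice_loss: prediction shape {pred.shape} != truth shape {y.shape}"
        )
    axes = tuple(range(1, pred.ndim))
    inter = (pred.data * y).sum(axis=axes)
    psum = pred.data.sum(axis=axes)
    ysum = y.sum(axis=axes)
    denom = psum + ysum + smooth
    dice = (2.0 * inter + smooth) / denom
    n = pred.shape[0]
    out = np.asarray((1.0 - dice).mean(), dtype=pred.dtype)

    def backward(g: np.ndarray) -> None:
        shape = (n,) + (1,) * (pred.ndim - 1)
        num = (2.0 * inter + smooth).reshape(shape)
        dp = -(2.0 * y * denom.reshape(shape) - num) / denom.reshape(shape) ** 2
        accumulate_grad(pred, (float(g) / n) * dp)

    return Tensor(out, (pred,), backward)
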