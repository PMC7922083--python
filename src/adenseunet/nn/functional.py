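"""Differentiable operations for the NumPy autodiff engine.

All image tensors use the NCHW layout.  Convolutions are implemented as
cross-correlations (the deep-learning convention) via im2col and a batched
matmul; dilation is realised by striding the im2col view, so a dilated 3x3
kernel touches taps spaced ``dilation`` pixels apart without materialising
a zero-inflated kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, as_tensor, make_output, unbroadcast

# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(unbroadcast(g, b.shape))

    return make_output(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate_grad(unbroadcast(g * a.data, b.shape))

    return make_output(data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(-g)

    return make_output(-a.data, (a,), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def scale(a: Tensor, c: float) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * c)

    return make_output(a.data * c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * mask)

    return make_output(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    s = np.empty_like(a.data, dtype=np.result_type(a.data.dtype, np.float32))
    pos = a.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    s[~pos] = e / (1.0 + e)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * s * (1.0 - s))

    return make_output(s, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g / a.data)

    return make_output(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * mask)

    return make_output(np.clip(a.data, lo, hi), (a,), backward)


def tsum(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g, a.shape).copy())

    return make_output(np.asarray(a.data.sum()), (a,), backward)


def tmean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g / n, a.shape).copy())

    return make_output(np.asarray(a.data.mean()), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(sl)])

    return make_output(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------


def same_padding(size: int, kernel: int, stride: int, dilation: int) -> tuple[int, int]:
    """TensorFlow-style SAME padding: output side = ceil(size / stride)."""
    eff = (kernel - 1) * dilation + 1
    out = -(-size // stride)
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: tuple[int, int, int, int] = (0, 0, 0, 0),
) -> Tensor:
    """2-D cross-correlation.  ``w`` has shape (out, in, kh, kw);
    ``padding`` is (top, bottom, left, right) zero-padding."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Cw, kh, kw = wd.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C} vs kernel {Cw}")
    pt, pb, pl, pr = padding
    pointwise = kh == kw == 1 and stride == 1 and not any(padding)
    if pointwise:
        xp = xd
    else:
        xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    Hp, Wp = xp.shape[2:]
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    if eh > Hp or ew > Wp:
        raise ValueError("dilated kernel larger than padded input")
    Ho = (Hp - eh) // stride + 1
    Wo = (Wp - ew) // stride + 1
    P = N * Ho * Wo
    # im2col in (C*kh*kw, N*Ho*Wo) layout so the contraction is one GEMM
    if pointwise:
        cols = xp.transpose(1, 0, 2, 3).reshape(C, P)
    else:
        sN, sC, sH, sW = xp.strides
        view = as_strided(
            xp,
            (C, kh, kw, N, Ho, Wo),
            (sC, sH * dilation, sW * dilation, sN, sH * stride, sW * stride),
        )
        cols = np.ascontiguousarray(view).reshape(C * kh * kw, P)
    out = (wd.reshape(O, -1) @ cols).reshape(O, N, Ho, Wo).transpose(1, 0, 2, 3)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    def backward(g):
        go = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(O, P)
        if w.requires_grad:
            w.accumulate_grad((go @ cols.T).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)).reshape(b.shape))
        if x.requires_grad:
            gcols = wd.reshape(O, -1).T @ go
            if pointwise:
                gx = gcols.reshape(C, N, H, W).transpose(1, 0, 2, 3)
                x.accumulate_grad(gx)
            else:
                gcols = gcols.reshape(C, kh, kw, N, Ho, Wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[
                            :,
                            :,
                            i * dilation : i * dilation + (Ho - 1) * stride + 1 : stride,
                            j * dilation : j * dilation + (Wo - 1) * stride + 1 : stride,
                        ] += gcols[:, i, j].transpose(1, 0, 2, 3)
                x.accumulate_grad(gxp[:, :, pt : Hp - pb or None, pl : Wp - pr or None])

    parents = (x, w) if b is None else (x, w, b)
    return make_output(np.ascontiguousarray(out), parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, factor: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride == ``factor`` (exact
    non-overlapping upsampling).  ``w`` has shape (in, out, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Cw, O, k, k2 = wd.shape
    if C != Cw or k != factor or k2 != factor:
        raise ValueError("conv_transpose2d: weight shape inconsistent with input/factor")
    out = np.einsum("nchw,coij->nohiwj", xd, wd, optimize=True).reshape(
        N, O, H * k, W * k
    )
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def backward(g):
        g6 = g.reshape(N, O, H, k, W, k)
        if x.requires_grad:
            x.accumulate_grad(np.einsum("nohiwj,coij->nchw", g6, wd, optimize=True))
        if w.requires_grad:
            w.accumulate_grad(np.einsum("nchw,nohiwj->coij", xd, g6, optimize=True))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)).reshape(b.shape))

    parents = (x, w) if b is None else (x, w, b)
    return make_output(out, parents, backward)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (even input sides required)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2d expects even spatial sides")
    data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x.accumulate_grad(gx)

    return make_output(data, (x,), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2) -> Tensor:
    """Max pooling with SAME padding (pad value -inf, so padding never wins)."""
    x = as_tensor(x)
    xd = x.data
    N, C, H, W = xd.shape
    pt, pb = same_padding(H, kernel, stride, 1)
    pl, pr = same_padding(W, kernel, stride, 1)
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    sN, sC, sH, sW = xp.strides
    view = as_strided(
        xp, (N, C, Ho, Wo, kernel, kernel), (sN, sC, sH * stride, sW * stride, sH, sW)
    )
    windows = np.ascontiguousarray(view).reshape(N, C, Ho, Wo, kernel * kernel)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            iy, ix = idx // kernel, idx % kernel
            oy = np.arange(Ho)[None, None, :, None] * stride
            ox = np.arange(Wo)[None, None, None, :] * stride
            rows = (oy + iy).reshape(N, C, -1)
            cols_ = (ox + ix).reshape(N, C, -1)
            gxp = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
            ni = np.arange(N)[:, None, None]
            ci = np.arange(C)[None, :, None]
            np.add.at(gxp, (ni, ci, rows, cols_), g.reshape(N, C, -1))
            x.accumulate_grad(gxp[:, :, pt : Hp - pb or None, pl : Wp - pr or None])

    return make_output(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return make_output(data, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    Updates ``running_mean``/``running_var`` in place during training.
    """
    x = as_tensor(x)
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, C, 1, 1)) * inv_std.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)).reshape(gamma.shape))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)).reshape(beta.shape))
        if x.requires_grad:
            gm = gamma.data.reshape(1, C, 1, 1)
            ist = inv_std.reshape(1, C, 1, 1)
            dxhat = g * gm
            if training:
                m = N * H * W
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = ist / m * (m * dxhat - t1 - xhat * t2)
            else:
                gx = dxhat * ist
            x.accumulate_grad(gx)

    return make_output(out, (x, gamma, beta), backward)
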