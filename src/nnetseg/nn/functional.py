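"""Differentiable operations used by the segmentation networks.

Every function takes and returns :class:`~nnetseg.nn.tensor.Tensor` and
registers a backward closure on the result.  Convolutions are stride-1
with symmetric zero padding, which is all an encoder-decoder built from
3x3 / 1x1 convolutions, 2x2 pooling and x2 upsampling requires.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "concat",
    "max_pool2x2",
    "avg_pool2x2",
    "upsample_bilinear2x",
    "batch_norm2d",
    "binary_cross_entropy",
]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with dilation.

    ``x``: (N, C_in, H, W); ``weight``: (C_out, C_in, k, k);
    ``bias``: (C_out,) or None.  Output spatial size is
    ``H + 2*padding - dilation*(k-1)``.
    """
    xd, wd = x.data, weight.data
    n, cin, h, w = xd.shape
    cout, cin2, k, k2 = wd.shape
    if cin2 != cin:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin2}")
    if k != k2:
        raise ValueError("only square kernels are supported")
    d, p = int(dilation), int(padding)
    ho = h + 2 * p - d * (k - 1)
    wo = w + 2 * p - d * (k - 1)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel footprint {d*(k-1)+1} exceeds padded input {h+2*p}x{w+2*p}")

    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    out = np.zeros((n, cout, ho, wo), dtype=xd.dtype)
    flat = out.reshape(n, cout, ho * wo)
    # one BLAS matmul per kernel tap; avoids materialising im2col columns
    for ky in range(k):
        for kx in range(k):
            xs = xp[:, :, ky * d:ky * d + ho, kx * d:kx * d + wo]
            flat += np.matmul(wd[:, :, ky, kx], xs.reshape(n, cin, ho * wo))
    if bias is not None:
        out += bias.data[:, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        gf = g.reshape(n, cout, ho * wo)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        if weight.requires_grad:
            gw = np.zeros_like(wd)
        for ky in range(k):
            for kx in range(k):
                xs = xp[:, :, ky * d:ky * d + ho, kx * d:kx * d + wo]
                if weight.requires_grad:
                    gw[:, :, ky, kx] = np.tensordot(gf, xs.reshape(n, cin, ho * wo),
                                                    axes=([0, 2], [0, 2]))
                if x.requires_grad:
                    gxp[:, :, ky * d:ky * d + ho, kx * d:kx * d + wo] += np.matmul(
                        wd[:, :, ky, kx].T, gf).reshape(n, cin, ho, wo)
        if weight.requires_grad:
            weight.accumulate_grad(gw)
        if x.requires_grad:
            x.accumulate_grad(gxp[:, :, p:p + h, p:p + w] if p else gxp)
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))

    return Tensor.from_op(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(g * (x.data > 0))

    return Tensor.from_op(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    xd = x.data
    out = np.empty_like(xd)
    pos = xd >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
    e = np.exp(xd[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(g * out * (1.0 - out))

    return Tensor.from_op(out, (x,), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverses NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor.from_op(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return Tensor.from_op(out, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.accumulate_grad(piece)

    return Tensor.from_op(out, tuple(tensors), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate_grad(gx.reshape(n, c, h, w))

    return Tensor.from_op(out, (x,), backward)


def avg_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x.accumulate_grad(gx.astype(x.data.dtype, copy=False))

    return Tensor.from_op(out, (x,), backward)


@lru_cache(maxsize=32)
def _bilinear_matrix(n_in: int, dtype_str: str) -> np.ndarray:
    """(2n x n) interpolation matrix for x2 upsampling (half-pixel centers)."""
    m = np.zeros((2 * n_in, n_in), dtype=np.dtype(dtype_str))
    for i in range(2 * n_in):
        src = (i + 0.5) / 2.0 - 0.5
        f = int(np.floor(src))
        t = src - f
        i0 = min(max(f, 0), n_in - 1)
        i1 = min(max(f + 1, 0), n_in - 1)
        m[i, i0] += 1.0 - t
        m[i, i1] += t
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    mh = _bilinear_matrix(h, str(x.data.dtype))
    mw = _bilinear_matrix(w, str(x.data.dtype))
    out = np.matmul(np.matmul(mh, x.data), mw.T)

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(np.matmul(np.matmul(mh.T, g), mw))

    return Tensor.from_op(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray | None = None,
                 running_var: np.ndarray | None = None,
                 training: bool = True, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    In training mode batch statistics are used and ``running_*`` buffers
    are updated in place; in eval mode the buffers normalise the input.
    """
    xd = x.data
    n, c, h, w = xd.shape
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        if running_mean is not None:
            m = xd.shape[0] * h * w
            unbiased = var * m / max(m - 1, 1)
            running_mean *= 1 - momentum
            running_mean += momentum * mean
            running_var *= 1 - momentum
            running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx_hat = g * gamma.data[None, :, None, None]
            if training:
                m = n * h * w
                s1 = gx_hat.sum(axis=(0, 2, 3))
                s2 = (gx_hat * xhat).sum(axis=(0, 2, 3))
                gx = (inv_std[None, :, None, None] / m) * (
                    m * gx_hat - s1[None, :, None, None] - xhat * s2[None, :, None, None])
            else:
                gx = gx_hat * inv_std[None, :, None, None]
            x.accumulate_grad(gx.astype(xd.dtype, copy=False))

    return Tensor.from_op(out, (x, gamma, beta), backward)


def binary_cross_entropy(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean pixel-wise BCE between probabilities and a {0,1} target grid."""
    p = np.clip(pred.data, eps, 1.0 - eps)
    t = np.asarray(target, dtype=p.dtype)
    if t.shape != p.shape:
        raise ValueError(f"target shape {t.shape} != prediction shape {p.shape}")
    out = np.asarray(-(t * np.log(p) + (1 - t) * np.log1p(-p)).mean(), dtype=p.dtype)

    def backward(g: np.ndarray) -> None:
        pred.accumulate_grad(g * (p - t) / (p * (1 - p)) / p.size)

    return Tensor.from_op(out, (pred,), backward)
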