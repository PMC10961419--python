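"""Convolution, pooling and loss kernels with hand-written backward passes.

All spatial kernels use an im2col formulation: a strided sliding-window view
feeds a single einsum for the forward pass, and the backward pass scatters
gradients back with a small loop over the kernel taps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "conv1d_channels",
    "take_channels",
    "concat_channels",
    "slice_channels",
    "cross_entropy",
    "log_softmax",
]


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> view (N,C,OH,OW,kh,kw) at the given stride."""
    w = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def _scatter_windows(dcols: np.ndarray, xp_shape, kh, kw, stride, padding):
    """Inverse of _windows: accumulate (N,C,OH,OW,kh,kw) grads into (N,C,H,W)."""
    dxp = np.zeros(xp_shape)
    oh, ow = dcols.shape[2], dcols.shape[3]
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                :, :, :, :, i, j
            ]
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation.  weight: (out_c, in_c//groups, kh, kw).

    groups == in_channels gives a depthwise convolution.
    """
    n, c, h, w = x.data.shape
    out_c, cg, kh, kw = weight.data.shape
    if c % groups or out_c % groups or cg != c // groups:
        raise ValueError(
            f"channel/group mismatch: in={c}, out={out_c}, groups={groups}, w_in={cg}"
        )
    xp = _pad_hw(x.data, padding)
    cols = _windows(xp, kh, kw, stride)  # (N,C,OH,OW,kh,kw)
    oh, ow = cols.shape[2], cols.shape[3]
    og = out_c // groups
    xg = cols.reshape(n, groups, cg, oh, ow, kh, kw)
    wg = weight.data.reshape(groups, og, cg, kh, kw)
    out = np.einsum("ngcxykl,gockl->ngoxy", xg, wg, optimize=True)
    out = out.reshape(n, out_c, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, out_c, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    result = Tensor(out, parents=parents)

    def backward(g):
        gg = g.reshape(n, groups, og, oh, ow)
        if weight.requires_grad:
            dw = np.einsum("ngoxy,ngcxykl->gockl", gg, xg, optimize=True)
            weight._accumulate(dw.reshape(out_c, cg, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("ngoxy,gockl->ngcxykl", gg, wg, optimize=True)
            dcols = dcols.reshape(n, c, oh, ow, kh, kw)
            x._accumulate(_scatter_windows(dcols, xp.shape, kh, kw, stride, padding))

    result._backward = backward
    return result


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    if padding:
        # padded cells must never win the max for negative inputs
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    cols = _windows(xp, kernel, kernel, stride)
    oh, ow = cols.shape[2], cols.shape[3]
    flat = cols.reshape(n, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    result = Tensor(out, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.zeros((n, c, oh, ow, kernel * kernel))
        np.put_along_axis(dcols, idx[..., None], g[..., None], axis=-1)
        dcols = dcols.reshape(n, c, oh, ow, kernel, kernel)
        x._accumulate(
            _scatter_windows(dcols, (n, c, h + 2 * padding, w + 2 * padding),
                             kernel, kernel, stride, padding)
        )

    result._backward = backward
    return result


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    xp = _pad_hw(x.data, padding)
    cols = _windows(xp, kernel, kernel, stride)
    oh, ow = cols.shape[2], cols.shape[3]
    out = cols.mean(axis=(-2, -1))
    result = Tensor(out, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.broadcast_to(
            g[..., None, None] / (kernel * kernel), (n, c, oh, ow, kernel, kernel)
        ).copy()
        x._accumulate(
            _scatter_windows(dcols, xp.shape, kernel, kernel, stride, padding)
        )

    result._backward = backward
    return result


def conv1d_channels(y: Tensor, kernel: Tensor) -> Tensor:
    """Bias-free 1-D cross-correlation of a per-channel descriptor.

    y: (N, C) channel descriptor; kernel: (K,) with K odd.  Zero padding of
    K//2 keeps the output length at C.
    """
    if kernel.data.ndim != 1 or kernel.data.shape[0] % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    k = kernel.data.shape[0]
    p = k // 2
    n, c = y.data.shape
    yp = np.pad(y.data, ((0, 0), (p, p)))
    win = sliding_window_view(yp, k, axis=1)  # (N, C, K)
    out = win @ kernel.data
    result = Tensor(out, parents=(y, kernel))

    def backward(g):
        if kernel.requires_grad:
            kernel._accumulate(np.einsum("nc,nck->k", g, win))
        if y.requires_grad:
            gp = np.pad(g, ((0, 0), (p, p)))
            gwin = sliding_window_view(gp, k, axis=1)
            y._accumulate(gwin @ kernel.data[::-1].copy())

    result._backward = backward
    return result


def take_channels(x: Tensor, index: np.ndarray) -> Tensor:
    """Permute/select channels; backward scatter-adds along the index."""
    index = np.asarray(index)
    out = Tensor(x.data[:, index], parents=(x,))

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.add.at(dx, (slice(None), index), g)
            x._accumulate(dx)

    out._backward = backward
    return out


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[:, start:stop], parents=(x,))

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, start:stop] = g
            x._accumulate(dx)

    out._backward = backward
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=1)
    out = Tensor(data, parents=tuple(tensors))
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=1)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = backward
    return out


def log_softmax(logits: Tensor) -> Tensor:
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    out = Tensor(z - lse, parents=(logits,))
    p = np.exp(z - lse)

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(g - p * g.sum(axis=1, keepdims=True))

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    labels = np.asarray(labels)
    n, k = logits.data.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label out of range")
    ls = log_softmax(logits)
    picked = ls.data[np.arange(n), labels]
    out = Tensor(-picked.mean(), parents=(ls,))

    def backward(g):
        if ls.requires_grad:
            d = np.zeros_like(ls.data)
            d[np.arange(n), labels] = -float(g) / n
            ls._accumulate(d)

    out._backward = backward
    return out
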