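"""Fused sequence operations with custom gradients.

All sequence tensors are laid out (B, T, C): batch, time, channels.
Convolutions are stride-1 cross-correlations; padding is either
symmetric ("same") or left-only ("causal").
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .scan import recurrence_backward, recurrence_forward


def _pad_amounts(kernel: int, mode: str, dilation: int = 1) -> tuple[int, int]:
    k_eff = (kernel - 1) * dilation + 1
    if mode == "causal":
        return k_eff - 1, 0
    if mode == "same":
        left = (k_eff - 1) // 2
        return left, k_eff - 1 - left
    raise ValueError(f"unknown padding mode {mode!r}")


def _windows(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, Tp, C) -> (B, T_out, k, C) view."""
    w = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    return np.moveaxis(w, -1, 2)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: str = "same", dilation: int = 1) -> Tensor:
    """Dense 1-D convolution. weight: (C_out, C_in, k)."""
    c_out, c_in, k = weight.shape
    k_eff = (k - 1) * dilation + 1
    pl, pr = _pad_amounts(k, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    win = _windows(xp, k_eff)[:, :, ::dilation, :]  # (B, T, k, C_in)
    out = np.einsum("btkc,ock->bto", win, weight.data, optimize=True)
    if bias is not None:
        out += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gw = np.einsum("btkc,bto->ock", win, g, optimize=True)
        T = x.data.shape[1]
        gxp = np.zeros_like(xp)
        for j in range(k):
            o = j * dilation
            gxp[:, o:o + g.shape[1], :] += g @ weight.data[:, :, j]
        gx = gxp[:, pl:pl + T, :]
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 1))))
        return tuple(grads)

    return Tensor._make(out, parents, bwd)


def conv1d_depthwise(x: Tensor, weight: Tensor, bias: Tensor | None,
                     padding: str = "causal", dilation: int = 1) -> Tensor:
    """Per-channel 1-D convolution. weight: (C, k)."""
    c, k = weight.shape
    k_eff = (k - 1) * dilation + 1
    pl, pr = _pad_amounts(k, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    win = _windows(xp, k_eff)[:, :, ::dilation, :]  # (B, T, k, C)
    out = np.einsum("btkc,ck->btc", win, weight.data, optimize=True)
    if bias is not None:
        out += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gw = np.einsum("btkc,btc->ck", win, g, optimize=True)
        T = x.data.shape[1]
        gxp = np.zeros_like(xp)
        for j in range(k):
            o = j * dilation
            gxp[:, o:o + g.shape[1], :] += g * weight.data[:, j]
        gx = gxp[:, pl:pl + T, :]
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 1))))
        return tuple(grads)

    return Tensor._make(out, parents, bwd)


def maxpool1d(x: Tensor, window: int = 2, stride: int = 2) -> Tensor:
    """Non-overlapping temporal max pooling (window == stride)."""
    if window != stride:
        raise ValueError("only window == stride pooling is supported")
    B, T, C = x.shape
    L = T // window
    if L == 0:
        raise ValueError(f"sequence of length {T} too short to pool by {window}")
    xt = x.data[:, :L * window, :].reshape(B, L, window, C)
    idx = xt.argmax(axis=2)
    out = np.take_along_axis(xt, idx[:, :, None, :], axis=2).squeeze(2)

    def bwd(g):
        gx = np.zeros((B, T, C), dtype=x.data.dtype)
        gxt = gx[:, :L * window, :].reshape(B, L, window, C)
        np.put_along_axis(gxt, idx[:, :, None, :], g[:, :, None, :], axis=2)
        return ((x, gx),)

    return Tensor._make(out, (x,), bwd)


def gather_time(x: Tensor, idx: np.ndarray) -> Tensor:
    """out[:, t, :] = x[:, idx[t], :] with scatter-add gradient."""
    B, L, C = x.shape
    idx = np.asarray(idx)
    out = x.data[:, idx, :]

    def bwd(g):
        gx_t = np.zeros((L, B, C), dtype=x.data.dtype)
        np.add.at(gx_t, idx, np.moveaxis(g, 1, 0))
        return ((x, np.moveaxis(gx_t, 0, 1)),)

    return Tensor._make(out, (x,), bwd)


def upsample_nearest(x: Tensor, target_len: int) -> Tensor:
    """Nearest-neighbour temporal resampling to `target_len` steps.

    Index map: source step floor(t * L / target_len), so doubling
    [a, b] -> [a, a, b, b].
    """
    L = x.shape[1]
    idx = (np.arange(target_len) * L) // target_len
    return gather_time(x, idx)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalise over the trailing (channel) axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data
    C = x.shape[-1]

    def bwd(g):
        gxhat = g * gamma.data
        gx = inv * (gxhat - gxhat.mean(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        ax = tuple(range(x.data.ndim - 1))
        return ((x, gx), (gamma, (g * xhat).sum(axis=ax)),
                (beta, g.sum(axis=ax)))

    return Tensor._make(out, (x, gamma, beta), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (batch, time) per channel; x: (B, T, C)."""
    if training:
        ax = (0, 1)
        mu = x.data.mean(axis=ax)
        xc = x.data - mu
        var = (xc * xc).mean(axis=ax)
        n = x.data.shape[0] * x.data.shape[1]
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
        xc = x.data - mu
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def bwd(g):
        gg = (g * xhat).sum(axis=(0, 1))
        gb = g.sum(axis=(0, 1))
        if training:
            m = x.data.shape[0] * x.data.shape[1]
            gxhat = g * gamma.data
            gx = inv * (gxhat - gxhat.mean(axis=(0, 1))
                        - xhat * (gxhat * xhat).mean(axis=(0, 1)))
        else:
            gx = g * (gamma.data * inv)
        return ((x, gx), (gamma, gg), (beta, gb))

    return Tensor._make(out, (x, gamma, beta), bwd)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
    return x * Tensor(mask)


def linear_recurrence(a: Tensor, b: Tensor) -> Tensor:
    """h_t = a_t * h_{t-1} + b_t with h_0 = 0, along axis 1.

    a, b: (B, T, D, N) elementwise (diagonal state transition).
    """
    h = recurrence_forward(a.data, b.data)

    def bwd(g):
        ga, gb = recurrence_backward(a.data, h, g)
        return ((a, ga), (b, gb))

    return Tensor._make(h, (a, b), bwd)
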