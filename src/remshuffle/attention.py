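"""Channel-attention operators for lightweight CNNs.

The central operator is EDCA (efficient dual channel attention): each channel
is summarized by its spatial mean *and* its spatial standard deviation, each
descriptor passes through its own bias-free 1-D convolution along the channel
axis (kernel size adapted to the channel count), the two responses are summed
and squashed by a sigmoid, and the resulting per-channel weight rescales the
input.  SE, ECA and SRM are provided as comparators:

* SE — global average pool, bottleneck MLP (reduction r), sigmoid.
* ECA — the average-pool path of EDCA alone (a single 1-D kernel).
* SRM — per-channel (mean, std) style vector, channel-wise fully connected
  (one 2-vector of weights per channel), sigmoid.

All operators preserve the input shape and emit weights strictly inside
(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.layers import Parameter
from .nn.tensor import Tensor

ATTENTION_KINDS = ("edca", "eca", "se", "srm", "none")


@dataclass(frozen=True)
class AttentionConfig:
    """Which channel attention to insert and its hyperparameters.

    gamma and b parameterize the adaptive kernel-size map
    K = |log2(C)/gamma + b/gamma|_odd; se_reduction is the SE bottleneck
    ratio (unused by the other kinds).
    """

    kind: str = "edca"
    gamma: float = 2.0
    b: float = 1.0
    se_reduction: int = 16

    def __post_init__(self):
        if self.kind not in ATTENTION_KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def channel_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel spatial mean and population standard deviation.

    x has shape (N, C, H, W); returns (avg, std) each of shape (N, C).
    The std uses the population formula (divisor H*W), so a spatially
    constant channel has std exactly 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("expected an (N, C, H, W) feature map")
    n, c, h, w = x.shape
    if h < 1 or w < 1:
        raise ValueError("empty spatial extent")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in feature map")
    avg = x.mean(axis=(2, 3))
    std = np.sqrt(((x - avg[:, :, None, None]) ** 2).mean(axis=(2, 3)))
    return avg, std


def adaptive_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Odd 1-D kernel size adapted to the channel count.

    Implements K = |log2(C)/gamma + b/gamma|_odd with the usual ECA
    convention: truncate toward zero, then bump even values up to the next
    odd integer.  For power-of-two channel counts this coincides with the
    nearest odd integer (ties at even integers resolve upward).
    """
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = int(abs(np.log2(channels) / gamma + b / gamma))
    k = t if t % 2 else t + 1
    return max(k, 1)


def _stats_tensors(x: Tensor) -> tuple[Tensor, Tensor]:
    """Autodiff-tracked per-channel (mean, std) descriptors, shape (N, C)."""
    n, c, h, w = x.data.shape
    m = x.mean(axis=(2, 3), keepdims=True)
    avg = m.reshape(n, c)
    xc = x - m
    var = (xc * xc).mean(axis=(2, 3))
    std = var.sqrt()
    return avg, std


class EDCA(nn.Module):
    """Efficient dual channel attention.

    Two independent bias-free 1-D kernels of adaptive length K act on the
    average-pool and std-pool channel descriptors; their sum passes through a
    sigmoid to give the per-channel weights.  Adds exactly 2*K parameters.
    """

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0):
        super().__init__()
        self.channels = channels
        self.kernel_size = adaptive_kernel_size(channels, gamma, b)
        init = 1.0 / self.kernel_size
        self.k_avg = Parameter(np.full(self.kernel_size, init))
        self.k_std = Parameter(np.full(self.kernel_size, init))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[:2]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        avg, std = _stats_tensors(x)
        omega = (F.conv1d_channels(avg, self.k_avg)
                 + F.conv1d_channels(std, self.k_std)).sigmoid()
        return x * omega.reshape(n, c, 1, 1)

    def weights(self, x: Tensor) -> np.ndarray:
        """The per-channel attention weights for an input, shape (N, C)."""
        avg, std = _stats_tensors(x)
        return (F.conv1d_channels(avg, self.k_avg)
                + F.conv1d_channels(std, self.k_std)).sigmoid().data


class ECA(nn.Module):
    """Efficient channel attention: the average-pool path of EDCA only."""

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0):
        super().__init__()
        self.channels = channels
        self.kernel_size = adaptive_kernel_size(channels, gamma, b)
        self.k_avg = Parameter(np.full(self.kernel_size, 1.0 / self.kernel_size))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[:2]
        avg, _ = _stats_tensors(x)
        omega = F.conv1d_channels(avg, self.k_avg).sigmoid()
        return x * omega.reshape(n, c, 1, 1)


class SE(nn.Module):
    """Squeeze-and-excitation: global average pool, bottleneck MLP, sigmoid."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[:2]
        s = x.mean(axis=(2, 3))
        omega = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * omega.reshape(n, c, 1, 1)


class SRM(nn.Module):
    """Style-based recalibration: per-channel (mean, std) descriptor mixed by
    a channel-wise fully connected layer (independent 2-vector per channel)."""

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        # one (w_avg, w_std) pair per channel; init favors the mean path
        self.w_avg = Parameter(np.ones(channels))
        self.w_std = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[:2]
        avg, std = _stats_tensors(x)
        z = avg * self.w_avg.reshape(1, c) + std * self.w_std.reshape(1, c)
        omega = z.sigmoid()
        return x * omega.reshape(n, c, 1, 1)


def make_attention(channels: int, cfg: AttentionConfig,
                   rng: np.random.Generator | None = None) -> nn.Module:
    """Build the attention module named by ``cfg.kind`` for a channel width."""
    kind = cfg.kind
    if kind == "edca":
        return EDCA(channels, cfg.gamma, cfg.b)
    if kind == "eca":
        return ECA(channels, cfg.gamma, cfg.b)
    if kind == "se":
        return SE(channels, cfg.se_reduction, rng=rng)
    if kind == "srm":
        return SRM(channels)
    if kind == "none":
        return nn.Identity()
    raise ValueError(f"unknown attention kind {kind!r}")


def edca_forward(x: np.ndarray, k_avg: np.ndarray, k_std: np.ndarray) -> np.ndarray:
    """Functional EDCA on plain arrays (no gradient tracking).

    Raises if the kernels are even-length or do not match the adaptive size
    for the input's channel count.
    """
    x = np.asarray(x, dtype=np.float64)
    k_avg = np.asarray(k_avg, dtype=np.float64)
    k_std = np.asarray(k_std, dtype=np.float64)
    c = x.shape[1]
    k = adaptive_kernel_size(c)
    if k_avg.shape != (k,) or k_std.shape != (k,):
        raise ValueError(f"kernels must have the adaptive length {k} for C={c}")
    mod = EDCA(c)
    mod.k_avg.data = k_avg
    mod.k_std.data = k_std
    return mod(Tensor(x)).data
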