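"""Channel (ECA) and spatial (CBAM-style) attention for 1-D feature maps.

The two modules in series form the dual "efficient channel and spatial
attention" recalibration stage appended to each feature-extraction block.
Both are parameter-frugal: the channel gate is a single bias-free 1-D
convolution over the globally pooled channel descriptor whose kernel size
adapts to the channel count, and the spatial gate is one bias-free
convolution over the 2-channel (channel-max, channel-mean) summary map.
Neither changes the shape of its input.
"""

from __future__ import annotations

import math

import numpy as np

from .layers import Conv1d, Module


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive kernel size for the channel-attention convolution.

    ``k = |log2(C)/gamma + b/gamma|_odd``: take the floor of the magnitude
    and bump even results up to the next odd integer, so the gate always has
    a centre tap.  For the default ``gamma=2, b=1`` this gives k=3 at C=64
    and k=5 at C=128.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    t = int(math.floor(abs(math.log2(channels) / gamma + b / gamma)))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


class ECA(Module):
    """Efficient channel attention: sigmoid(conv1d(GAP(F))) channel gates."""

    def __init__(self, channels: int, gamma: int = 2, b: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "eca"):
        super().__init__()
        self.channels = channels
        k = eca_kernel_size(channels, gamma, b)
        self.kernel_size = k
        self.conv = Conv1d(1, 1, k, padding=k // 2, bias=False, rng=rng,
                           dtype=dtype, name=f"{name}.conv")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        pooled = x.mean(axis=2)                       # (B, C)
        pre = self.conv(pooled[:, None, :])[:, 0, :]  # conv along channel axis
        coeff = 1.0 / (1.0 + np.exp(-pre))
        self._cache = (x, coeff, x.shape[2])
        return x * coeff[:, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, coeff, length = self._cache
        dx = grad * coeff[:, :, None]
        dcoeff = (grad * x).sum(axis=2)
        dpre = dcoeff * coeff * (1.0 - coeff)
        dpooled = self.conv.backward(dpre[:, None, :])[:, 0, :]
        dx += dpooled[:, :, None] / grad.dtype.type(length)
        return dx

    def coefficients(self, x: np.ndarray) -> np.ndarray:
        """Channel gates in (0, 1) for a given feature map, shape (B, C)."""
        pooled = x.mean(axis=2)
        pre = self.conv(pooled[:, None, :])[:, 0, :]
        return 1.0 / (1.0 + np.exp(-pre))


class SpatialAttention(Module):
    """Per-time-point gate from the (channel-max, channel-mean) summary.

    The single coefficient per position is shared by all channels, so the
    output/input ratio is constant down each temporal column.
    """

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "spatial"):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(
                f"spatial kernel must be odd to preserve length, got {kernel_size}")
        self.kernel_size = kernel_size
        self.conv = Conv1d(2, 1, kernel_size, padding=kernel_size // 2,
                           bias=False, rng=rng, dtype=dtype, name=f"{name}.conv")
        self._cache = None

    def _summary(self, x: np.ndarray):
        idx = x.argmax(axis=1)
        mx = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
        mn = x.mean(axis=1)
        return np.stack([mx, mn], axis=1), idx

    def forward(self, x: np.ndarray) -> np.ndarray:
        summary, idx = self._summary(x)
        pre = self.conv(summary)                       # (B, 1, L)
        coeff = 1.0 / (1.0 + np.exp(-pre))
        self._cache = (x, coeff, idx)
        return x * coeff

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, coeff, idx = self._cache
        channels = x.shape[1]
        dx = grad * coeff
        dcoeff = (grad * x).sum(axis=1, keepdims=True)
        dpre = dcoeff * coeff * (1.0 - coeff)
        dsummary = self.conv.backward(dpre)            # (B, 2, L)
        dx += dsummary[:, 1:2, :] / grad.dtype.type(channels)
        scatter = np.zeros_like(x)
        np.put_along_axis(scatter, idx[:, None, :], dsummary[:, 0:1, :], axis=1)
        return dx + scatter

    def coefficients(self, x: np.ndarray) -> np.ndarray:
        """Per-position gates in (0, 1), shape (B, 1, L)."""
        summary, _ = self._summary(x)
        pre = self.conv(summary)
        return 1.0 / (1.0 + np.exp(-pre))
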