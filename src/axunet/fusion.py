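"""Global–local fusion: attention-gated merging of the two encoder streams.

The transformer (global) stream produces two gates in the style of
convolutional block attention: a spatial map from channel-axis mean/max
pooling followed by a 7×7 convolution, and a per-channel gate from global
spatial average pooling followed by a two-layer bottleneck MLP.  Both gates
pass a sigmoid and multiply the convolutional (local) stream only; the
global stream is compressed by a convolution, concatenated with the gated
local stream, and a final convolution produces the fused output:

    f_out = conv(cat(conv(f_global), f_local · A_s · A_c))
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["SpatialAttention", "ChannelAttention", "GlobalLocalFusion"]


class SpatialAttention(nn.Module):
    """[B,C,H,W] -> [B,1,H,W] sigmoid gate from channel-pooled statistics."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2)

    def forward(self, f_global: Tensor) -> Tensor:
        mean_map = f_global.mean(axis=1, keepdims=True)
        # max over channels is non-smooth; the gradient flows via the mean path
        max_map = Tensor(f_global.data.max(axis=1, keepdims=True))
        pooled = ad.concatenate([mean_map, max_map], axis=1)
        return ad.sigmoid(self.conv(pooled))


class ChannelAttention(nn.Module):
    """[B,C,H,W] -> [B,C_out] sigmoid gate from global average pooling."""

    def __init__(self, in_channels: int, out_channels: int, reduction: int = 4):
        super().__init__()
        hidden = max(1, in_channels // reduction)
        self.fc1 = nn.Linear(in_channels, hidden)
        self.fc2 = nn.Linear(hidden, out_channels)

    def forward(self, f_global: Tensor) -> Tensor:
        pooled = nn.global_avg_pool(f_global)  # [B,C]
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(pooled))))


class _ConvBnRelu(nn.Module):
    def __init__(self, in_ch, out_ch, kernel=3):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, padding=kernel // 2, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class GlobalLocalFusion(nn.Module):
    """Fuse a (global, local) feature pair into ``out_channels`` features.

    The two inputs must share batch and spatial extents; channel counts may
    differ.  ``forward`` accepts ``gate_override`` — a (spatial, channel)
    pair of constants or arrays standing in for the learned gates — used by
    tests to probe the identity-gating and annihilation limits.
    """

    def __init__(self, global_channels: int, local_channels: int,
                 out_channels: int):
        super().__init__()
        self.spatial = SpatialAttention()
        self.channel = ChannelAttention(global_channels, local_channels)
        self.compress_global = _ConvBnRelu(global_channels, out_channels)
        self.fuse = _ConvBnRelu(out_channels + local_channels, out_channels)

    def forward(self, f_global: Tensor, f_local: Tensor,
                gate_override=None) -> Tensor:
        if f_global.shape[0] != f_local.shape[0] or f_global.shape[2:] != f_local.shape[2:]:
            raise ValueError(
                f"global/local extents differ: {f_global.shape} vs {f_local.shape}"
            )
        if gate_override is None:
            a_s = self.spatial(f_global)                       # [B,1,H,W]
            a_c = self.channel(f_global)                       # [B,C_local]
        else:
            a_s, a_c = (ad.astensor(g) for g in gate_override)
        B, C_local = f_local.shape[:2]
        if a_c.ndim == 2:
            a_c = a_c.reshape((B, C_local, 1, 1))
        gated = f_local * a_s * a_c
        merged = ad.concatenate([self.compress_global(f_global), gated], axis=1)
        return self.fuse(merged)
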