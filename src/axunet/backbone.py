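"""Residual convolutional backbone: the stem and per-unit local branches.

A standard 50-layer-style bottleneck residual design with five stages.  The
first two stages (plus the 7×7 stem convolution and max-pool) form the
*stem* that aggregates low-level features and records every intermediate
scale for the decoder's skip connections; stages 3 and 4 serve as the
convolutional branches of the two parallel encoder units.

Channel widths scale with a single base width ``w`` (64 at paper scale):
stage outputs are 4w, 8w, 16w, 32w with the usual 4× bottleneck expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["StageConfig", "BottleneckBlock", "ResStage", "Stem", "StemOutput"]


@dataclass
class StageConfig:
    in_channels: int
    out_channels: int
    blocks: int = 1
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.blocks < 1:
            raise ValueError("a stage needs at least one block")


@dataclass
class StemOutput:
    features: Tensor        # deepest stem features, H/8 × W/8
    skips: list             # [post-conv H/2, post-stage-1 H/4, post-stage-2 H/8]


class BottleneckBlock(nn.Module):
    """1×1 reduce → 3×3 (carries the stride) → 1×1 expand, plus shortcut."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x):
        h = ad.relu(self.bn1(self.conv1(x)))
        h = ad.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        return ad.relu(h + self.shortcut(x))


class ResStage(nn.Module):
    """A stack of bottleneck blocks; the first block carries the stride."""

    def __init__(self, cfg: StageConfig):
        super().__init__()
        self.cfg = cfg
        mid = max(1, cfg.out_channels // 4)
        blocks = [BottleneckBlock(cfg.in_channels, mid, cfg.out_channels, cfg.stride)]
        for _ in range(cfg.blocks - 1):
            blocks.append(BottleneckBlock(cfg.out_channels, mid, cfg.out_channels, 1))
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"stage expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        for b in self.blocks:
            x = b(x)
        return x


class Stem(nn.Module):
    """7×7 stride-2 conv + max-pool + residual stages 1–2; H/8 at the output.

    ``base_width`` is the stem conv width w; stage 1 emits 4w channels at
    H/4 and stage 2 emits 8w at H/8.  All three intermediate scales are kept
    as decoder skips.
    """

    def __init__(self, base_width: int = 64, in_channels: int = 3,
                 blocks: tuple[int, int] = (1, 1)):
        super().__init__()
        w = base_width
        self.base_width = w
        self.conv = nn.Conv2d(in_channels, w, 7, stride=2, padding=3, bias=False)
        self.bn = nn.BatchNorm2d(w)
        self.stage1 = ResStage(StageConfig(w, 4 * w, blocks=blocks[0], stride=1))
        self.stage2 = ResStage(StageConfig(4 * w, 8 * w, blocks=blocks[1], stride=2))

    def forward(self, image: Tensor) -> StemOutput:
        B, C, H, W = image.shape
        if H % 16 or W % 16:
            raise ValueError("stem input extent must be divisible by 16")
        x0 = ad.relu(self.bn(self.conv(image)))          # H/2
        x1 = self.stage1(ad.max_pool2d(x0, 3, 2, 1))     # H/4
        x2 = self.stage2(x1)                             # H/8
        return StemOutput(features=x2, skips=[x0, x1, x2])
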