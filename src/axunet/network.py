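"""The full U-shaped hybrid network.

Data flow: residual stem (stages 1–2, saving every scale for skips) →
``encoder_units`` parallel units, each pairing a masked-axial transformer
branch with a residual stage and merging them with global–local fusion →
a standard-transformer bottleneck → a convolution + bilinear-upsampling
decoder with skip connections → a 1-channel segmentation head and an
optional auxiliary edge head, both at input resolution.

All widths and depths are gathered in :class:`NetworkConfig`;
``NetworkConfig.tiny()`` gives a CPU desk-scale model used throughout the
test-suite, while the defaults mirror the 512×512 training regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .attention import AttentionConfig, TransformerBlock
from .autodiff import Tensor
from .backbone import ResStage, StageConfig, Stem
from .fusion import GlobalLocalFusion

__all__ = ["NetworkConfig", "SegOutput", "ParallelEncoderUnit", "Bottleneck",
           "Decoder", "SegNet"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    input_size        square input extent in pixels; divisible by 32
    base_width        stem conv width w (stage outputs scale as 4w, 8w, ...)
    encoder_units     number of parallel transformer/CNN units
    unit_channels     output width of each unit (defaults to 16w, 32w, ...)
    unit_depth        masked-axial transformer blocks per unit
    bottleneck_dim    token width of the standard-transformer bottleneck
    bottleneck_depth  standard transformer blocks in the bottleneck
    heads             attention heads (all transformer blocks)
    mlp_ratio         MLP hidden-width multiplier
    mask_k / mask_a_fraction  distance-mask curvature and cutoff fraction
    decoder_channels  widths of the encoder_units+3 decoder stages
    edge_head         emit auxiliary edge logits
    edge_source       "head" (1×1 conv on the last decoder feature) or
                      "gradient" (spatial-gradient magnitude of the
                      segmentation probability)
    """

    input_size: int = 512
    in_channels: int = 3
    base_width: int = 64
    encoder_units: int = 2
    unit_channels: Optional[Sequence[int]] = None
    unit_depth: int = 2
    unit_blocks: int = 1
    bottleneck_dim: int = 512
    bottleneck_depth: int = 4
    heads: int = 8
    mlp_ratio: float = 4.0
    mask_k: float = 0.5
    mask_a_fraction: float = 0.5
    clamp_mask: bool = False
    stem_blocks: tuple = (1, 1)
    decoder_channels: Optional[Sequence[int]] = None
    edge_head: bool = True
    edge_source: str = "head"

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.unit_channels is None:
            self.unit_channels = tuple(
                8 * self.base_width * 2 ** (i + 1) for i in range(self.encoder_units)
            )
        self.unit_channels = tuple(self.unit_channels)
        if len(self.unit_channels) != self.encoder_units:
            raise ValueError("unit_channels length must equal encoder_units")
        n_dec = self.encoder_units + 3
        if self.decoder_channels is None:
            top = max(16, self.unit_channels[-1] // 8)
            self.decoder_channels = tuple(
                max(8, top // 2**i) for i in range(n_dec)
            )
        self.decoder_channels = tuple(self.decoder_channels)
        if len(self.decoder_channels) != n_dec:
            raise ValueError(f"decoder_channels must list {n_dec} widths")
        if self.edge_source not in ("head", "gradient"):
            raise ValueError("edge_source must be 'head' or 'gradient'")

    @classmethod
    def tiny(cls, input_size: int = 64, **overrides) -> "NetworkConfig":
        """A CPU-scale configuration for tests and small experiments."""
        kwargs = dict(
            input_size=input_size,
            base_width=8,
            unit_channels=(32, 64),
            unit_depth=1,
            bottleneck_dim=64,
            bottleneck_depth=1,
            heads=2,
            mlp_ratio=2.0,
            decoder_channels=(32, 24, 16, 12, 8),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def attention_for(self, embed_dim: int) -> AttentionConfig:
        return AttentionConfig(
            embed_dim=embed_dim, heads=self.heads, mlp_ratio=self.mlp_ratio,
            mask_k=self.mask_k, mask_a_fraction=self.mask_a_fraction,
            clamp_mask=self.clamp_mask,
        )


@dataclass
class SegOutput:
    seg_logits: Tensor
    edge_logits: Optional[Tensor] = None


class ParallelEncoderUnit(nn.Module):
    """One encoder unit: masked-axial transformer ∥ residual stage → fusion.

    The transformer branch halves the spatial extent with 2×2 average
    pooling before tokenization so both branches land on the same grid.
    """

    def __init__(self, in_ch: int, out_ch: int, cfg: NetworkConfig):
        super().__init__()
        self.token_proj = nn.Conv2d(in_ch, out_ch, 1)
        att = cfg.attention_for(out_ch)
        self.blocks = nn.ModuleList(
            [TransformerBlock(att, "masked_axial") for _ in range(cfg.unit_depth)]
        )
        self.cnn = ResStage(StageConfig(in_ch, out_ch, blocks=cfg.unit_blocks, stride=2))
        self.glf = GlobalLocalFusion(out_ch, out_ch, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        tokens = self.token_proj(nn.avg_pool2x(x))
        for blk in self.blocks:
            tokens = blk(tokens)
        local = self.cnn(x)
        if tokens.shape[2:] != local.shape[2:]:
            raise RuntimeError(
                f"branch extents diverged: {tokens.shape} vs {local.shape}"
            )
        return self.glf(tokens, local)


class Bottleneck(nn.Module):
    """1×1 channel reduction + standard transformer blocks on the deep grid."""

    def __init__(self, in_ch: int, cfg: NetworkConfig):
        super().__init__()
        self.reduce = nn.Conv2d(in_ch, cfg.bottleneck_dim, 1)
        att = cfg.attention_for(cfg.bottleneck_dim)
        self.blocks = nn.ModuleList(
            [TransformerBlock(att, "standard") for _ in range(cfg.bottleneck_depth)]
        )

    def forward(self, x: Tensor) -> Tensor:
        x = self.reduce(x)
        for blk in self.blocks:
            x = blk(x)
        return x


class _DecoderStage(nn.Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x, skip=None):
        x = ad.upsample_bilinear(x, 2)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(
                    f"skip extent {skip.shape[2:]} does not match stage {x.shape[2:]}"
                )
            x = ad.concatenate([x, skip], axis=1)
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))


class Decoder(nn.Module):
    """Bilinear-upsampling decoder with skip concatenation and both heads."""

    def __init__(self, deep_ch: int, skip_channels: Sequence[int],
                 cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        widths = cfg.decoder_channels
        stages = []
        in_ch = deep_ch
        skips = list(skip_channels) + [0] * (len(widths) - len(skip_channels))
        for skip_ch, out_ch in zip(skips, widths):
            stages.append(_DecoderStage(in_ch, skip_ch, out_ch))
            in_ch = out_ch
        self.stages = nn.ModuleList(stages)
        self.seg_head = nn.Conv2d(widths[-1], 1, 1)
        self.edge_head = (
            nn.Conv2d(widths[-1], 1, 1)
            if cfg.edge_head and cfg.edge_source == "head"
            else None
        )

    def forward(self, deep: Tensor, skips: Sequence[Tensor]) -> SegOutput:
        """``skips`` ordered deep → shallow to match the upsampling stages."""
        x = deep
        skips = list(skips) + [None] * (len(self.stages) - len(skips))
        for stage, skip in zip(self.stages, skips):
            x = stage(x, skip)
        seg = self.seg_head(x)
        edge = None
        if self.cfg.edge_head:
            if self.edge_head is not None:
                edge = self.edge_head(x)
            else:
                edge = _gradient_edge_logits(seg)
        return SegOutput(seg_logits=seg, edge_logits=edge)


_SOBEL_X = np.array([[[[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]]], dtype=np.float32) / 4.0
_SOBEL_Y = np.transpose(_SOBEL_X, (0, 1, 3, 2)).copy()


def _gradient_edge_logits(seg_logits: Tensor) -> Tensor:
    """Edge logits from the spatial gradient of the segmentation probability."""
    p = ad.sigmoid(seg_logits)
    gx = ad.conv2d(p, Tensor(_SOBEL_X), stride=1, padding=1)
    gy = ad.conv2d(p, Tensor(_SOBEL_Y), stride=1, padding=1)
    mag = (gx * gx + gy * gy + 1e-8) ** 0.5
    prob = ad.clip(mag * 2.0, 1e-4, 1.0 - 1e-4)
    return (prob / (1.0 - prob)).log()


class SegNet(nn.Module):
    """Stem → parallel units → transformer bottleneck → decoder."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        self.stem = Stem(cfg.base_width, cfg.in_channels, cfg.stem_blocks)
        units = []
        in_ch = 8 * cfg.base_width
        for out_ch in cfg.unit_channels:
            units.append(ParallelEncoderUnit(in_ch, out_ch, cfg))
            in_ch = out_ch
        self.units = nn.ModuleList(units)
        self.bottleneck = Bottleneck(in_ch, cfg)
        # decoder skips, deep → shallow: unit outputs (except the deepest),
        # then the stem's three scales in reverse
        w = cfg.base_width
        skip_channels = list(cfg.unit_channels[:-1])[::-1] + [8 * w, 4 * w, w]
        self.decoder = Decoder(cfg.bottleneck_dim, skip_channels, cfg)

    def forward(self, image: Tensor) -> SegOutput:
        image = ad.astensor(image)
        if image.shape[2] != self.cfg.input_size or image.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}² input, got {image.shape[2:]}"
            )
        stem_out = self.stem(image)
        x = stem_out.features
        unit_outs = []
        for unit in self.units:
            x = unit(x)
            unit_outs.append(x)
        deep = self.bottleneck(x)
        skips = unit_outs[:-1][::-1] + stem_out.skips[::-1]
        return self.decoder(deep, skips)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        state = {f"param:{k}": v for k, v in self.state_dict().items()}
        state["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "SegNet":
        import json

        with np.load(path) as data:
            cfg = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
            net = cls(cfg)
            net.load_state_dict(
                {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
            )
        return net
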