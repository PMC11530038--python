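"""Densely connected encoder-decoder segmentation network.

Encoder: a 3x3 stem followed by four dense blocks (BN -> ReLU -> 3x3 conv
layers, each consuming the concatenation of the block input and all previous
layer outputs) separated by transitions (1x1 compression conv + 2x2 average
pooling). A fifth dense block forms the bottleneck. Decoder: four levels,
each upsampling the deeper feature (bilinear x2 + 3x3 conv), gating the
matching encoder skip with an attention gate, concatenating, recalibrating
with channel attention and fusing with a 3x3 conv. The four decoder outputs
feed a scale-attention fusion at the input resolution, followed by a 1x1
classification head.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Sequence, Tuple

from . import nn
from .attention import AttentionGate, ChannelAttention, ScaleAttention
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class ModelConfig:
    """Architecture hyperparameters; every width is overridable."""

    in_channels: int = 1
    n_classes: int = 2
    base_channels: int = 32
    growth_rate: int = 16
    block_layers: Tuple[int, int, int, int] = (4, 4, 4, 4)
    compression: float = 0.5
    reduction_r: int = 16
    decoder_channels: Tuple[int, int, int, int] = (128, 64, 32, 16)

    def __post_init__(self):
        if len(self.block_layers) != 4:
            raise ValueError("block_layers must have exactly four entries")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder_channels must have exactly four entries")
        if not (0 < self.compression <= 1):
            raise ValueError("compression must lie in (0, 1]")
        for name in ("in_channels", "n_classes", "base_channels", "growth_rate", "reduction_r"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale preset that trains in minutes on one CPU core."""
        return cls(
            base_channels=16,
            growth_rate=8,
            block_layers=(2, 2, 2, 2),
            reduction_r=8,
            decoder_channels=(32, 24, 16, 8),
        )

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelConfig":
        d = dict(d)
        for key in ("block_layers", "decoder_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def channel_plan(cfg: ModelConfig) -> Dict[str, List[int]]:
    """Channel counts at every junction, computed without building the model."""
    c = cfg.base_channels
    skips: List[int] = []
    trans: List[int] = []
    for n_layers in cfg.block_layers:
        c += n_layers * cfg.growth_rate
        skips.append(c)
        c = math.ceil(cfg.compression * c)
        trans.append(c)
    bottleneck = c + cfg.block_layers[-1] * cfg.growth_rate
    deep = [bottleneck] + list(cfg.decoder_channels[:-1])
    concat = [s + d for s, d in zip(reversed(skips), cfg.decoder_channels)]
    return {
        "skips": skips,
        "transitions": trans,
        "bottleneck": [bottleneck],
        "decoder_deep_in": deep,
        "decoder_concat": concat,
        "decoder_out": list(cfg.decoder_channels),
    }


class DenseLayer(nn.Module):
    """BN -> ReLU -> 3x3 conv producing ``growth_rate`` channels."""

    def __init__(self, in_channels: int, growth_rate: int):
        super().__init__()
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, growth_rate, 3, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.bn(x).relu())


class DenseBlock(nn.Module):
    """Each layer consumes the concatenation of all preceding feature maps."""

    def __init__(self, in_channels: int, n_layers: int, growth_rate: int):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = in_channels + n_layers * growth_rate
        self.layers = [
            DenseLayer(in_channels + i * growth_rate, growth_rate) for i in range(n_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        for layer in self.layers:
            inp = features[0] if len(features) == 1 else nn.concat(features, axis=1)
            features.append(layer(inp))
        if len(features) == 1:
            return x
        return nn.concat(features, axis=1)


class TransitionDown(nn.Module):
    """1x1 conv to ceil(compression*C) channels, then 2x2 average pooling."""

    def __init__(self, in_channels: int, compression: float):
        super().__init__()
        self.out_channels = math.ceil(compression * in_channels)
        self.conv = nn.Conv2d(in_channels, self.out_channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2(self.conv(x))


class DecoderLevel(nn.Module):
    """Upsample, gate the skip, concatenate, recalibrate, fuse."""

    def __init__(self, deep_channels: int, skip_channels: int, out_channels: int,
                 reduction: int):
        super().__init__()
        self.up_conv = nn.Conv2d(deep_channels, out_channels, 3, padding=1)
        self.gate = AttentionGate(skip_channels, out_channels)
        self.channel_attention = ChannelAttention(skip_channels + out_channels, reduction)
        self.fuse = nn.Conv2d(skip_channels + out_channels, out_channels, 3, padding=1)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        g = self.up_conv(F.upsample2(deep))
        if g.data.shape[2:] != skip.data.shape[2:]:
            g = F.bilinear_resize(g, skip.data.shape[2:])
        gated, _ = self.gate(skip, g)
        merged = nn.concat([gated, g], axis=1)
        return self.fuse(self.channel_attention(merged))


class DenseAttentionUNet(nn.Module):
    """Full network; input spatial dims must be divisible by 16."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        plan = channel_plan(cfg)
        self.stem = nn.Conv2d(cfg.in_channels, cfg.base_channels, 3, padding=1)
        self.enc_blocks: List[DenseBlock] = []
        self.transitions: List[TransitionDown] = []
        c = cfg.base_channels
        for n_layers in cfg.block_layers:
            block = DenseBlock(c, n_layers, cfg.growth_rate)
            self.enc_blocks.append(block)
            c = block.out_channels
            trans = TransitionDown(c, cfg.compression)
            self.transitions.append(trans)
            c = trans.out_channels
        self.bottleneck = DenseBlock(c, cfg.block_layers[-1], cfg.growth_rate)
        skips = plan["skips"]
        self.decoder_levels: List[DecoderLevel] = []
        deep_c = self.bottleneck.out_channels
        for i, out_c in enumerate(cfg.decoder_channels):
            skip_c = skips[3 - i]
            self.decoder_levels.append(
                DecoderLevel(deep_c, skip_c, out_c, cfg.reduction_r)
            )
            deep_c = out_c
        self.scale_attention = ScaleAttention(cfg.decoder_channels, reduction=4)
        self.head = nn.Conv2d(self.scale_attention.hybrid_channels, cfg.n_classes, 1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 16 != 0 or w % 16 != 0:
            raise ValueError(
                f"input spatial dims must be divisible by 16 (four halvings); got {h}x{w}"
            )
        feat = self.stem(x)
        skips: List[Tensor] = []
        for block, trans in zip(self.enc_blocks, self.transitions):
            feat = block(feat)
            skips.append(feat)
            feat = trans(feat)
        feat = self.bottleneck(feat)
        pyramid: List[Tensor] = []
        for i, level in enumerate(self.decoder_levels):
            feat = level(feat, skips[3 - i])
            pyramid.append(feat)
        fused = self.scale_attention(pyramid, (h, w))
        return self.head(fused)
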