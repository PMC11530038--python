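"""The three attention mechanisms used by the segmentation decoder.

* :class:`AttentionGate` — additive spatial gating of an encoder skip
  feature ``x`` by an upsampled decoder feature ``g``:
  ``alpha = sigmoid(psi(relu(Wx·x + Wg·g + bg)) + b_psi)``, output ``alpha·x``.
* :class:`ChannelAttention` — per-channel coefficients from global average
  and max pooling through a shared two-layer MLP, applied with a residual:
  ``y = x·beta + x``.
* :class:`ScaleAttention` — fuses the four decoder-scale outputs: each is
  bilinearly resized to the target grid, compressed to 4 channels and
  concatenated into a 16-channel hybrid map ``F``; a per-scale coefficient
  ``gamma`` (4 values, broadcast over each scale's 4 channels) and a
  per-pixel coefficient ``gamma_star`` then form
  ``y = F + F·gamma + F·gamma·gamma_star``.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


class AttentionGate(nn.Module):
    """Additive attention gate producing a one-channel coefficient map.

    ``g`` is bilinearly resampled to ``x``'s spatial grid when they differ,
    so the coefficient is always produced at the skip resolution.
    """

    def __init__(self, x_channels: int, g_channels: int, inter_channels: int | None = None):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(x_channels // 2, 1)
        if inter_channels < 1:
            raise ValueError("inter_channels must be >= 1")
        self.w_x = nn.Conv2d(x_channels, inter_channels, 1, bias=False)
        self.w_g = nn.Conv2d(g_channels, inter_channels, 1, bias=True)
        self.psi = nn.Conv2d(inter_channels, 1, 1, bias=True)

    def forward(self, x: Tensor, g: Tensor) -> Tuple[Tensor, Tensor]:
        if x.data.shape[0] != g.data.shape[0]:
            raise ValueError(
                f"batch mismatch: x has {x.data.shape[0]}, g has {g.data.shape[0]}"
            )
        if g.data.shape[2:] != x.data.shape[2:]:
            g = F.bilinear_resize(g, x.data.shape[2:])
        combined = (self.w_x(x) + self.w_g(g)).relu()
        alpha = self.psi(combined).sigmoid()
        return alpha * x, alpha


class ChannelAttention(nn.Module):
    """Dual-pooling channel attention with residual output ``x·beta + x``.

    The same two-layer MLP (C -> C/r -> C, ReLU between) is applied to the
    global-average and global-max pooled vectors; their sum passes through a
    sigmoid to give ``beta`` per channel.
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.reduction = reduction
        self.mlp_in = nn.Linear(channels, hidden)
        self.mlp_out = nn.Linear(hidden, channels)

    def _mlp(self, pooled: Tensor) -> Tensor:
        return self.mlp_out(self.mlp_in(pooled).relu())

    def coefficients(self, x: Tensor) -> Tensor:
        """beta: (N, C) in [0, 1]."""
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.data.shape[1]}, expected {self.channels}"
            )
        avg = F.global_avg_pool(x)
        mx = F.global_max_pool(x)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        beta = self.coefficients(x)
        n, c = beta.data.shape
        return x * beta.reshape(n, c, 1, 1) + x


class ScaleAttention(nn.Module):
    """Scale attention over a four-level decoder pyramid.

    The channel branch pools the 16-channel hybrid map and maps it through a
    shared two-layer MLP to 4 per-scale coefficients; the spatial branch is a
    3x3 conv -> ReLU -> 1x1 conv -> sigmoid applied to ``F·gamma``.
    """

    N_SCALES = 4
    CHANNELS_PER_SCALE = 4

    def __init__(self, pyramid_channels: Sequence[int], reduction: int = 4,
                 spatial_hidden: int = 8):
        super().__init__()
        if len(pyramid_channels) != self.N_SCALES:
            raise ValueError(f"expected {self.N_SCALES} pyramid levels, got {len(pyramid_channels)}")
        self.hybrid_channels = self.N_SCALES * self.CHANNELS_PER_SCALE  # 16
        self.compressors = [
            nn.Conv2d(c, self.CHANNELS_PER_SCALE, 1) for c in pyramid_channels
        ]
        hidden = max(self.hybrid_channels // reduction, 1)
        self.mlp_in = nn.Linear(self.hybrid_channels, hidden)
        self.mlp_out = nn.Linear(hidden, self.N_SCALES)
        self.spatial_conv1 = nn.Conv2d(self.hybrid_channels, spatial_hidden, 3, padding=1)
        self.spatial_conv2 = nn.Conv2d(spatial_hidden, 1, 1)

    def hybrid_map(self, pyramid: Sequence[Tensor], target_hw: Tuple[int, int]) -> Tensor:
        if len(pyramid) != self.N_SCALES:
            raise ValueError(f"expected {self.N_SCALES} pyramid levels, got {len(pyramid)}")
        compressed: List[Tensor] = []
        for feat, comp in zip(pyramid, self.compressors):
            resized = F.bilinear_resize(feat, tuple(target_hw))
            compressed.append(comp(resized))
        return nn.concat(compressed, axis=1)

    def _mlp(self, pooled: Tensor) -> Tensor:
        return self.mlp_out(self.mlp_in(pooled).relu())

    def scale_coefficients(self, hybrid: Tensor) -> Tensor:
        """gamma: (N, 4) in [0, 1], one coefficient per decoder scale."""
        avg = F.global_avg_pool(hybrid)
        mx = F.global_max_pool(hybrid)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()

    def forward(self, pyramid: Sequence[Tensor], target_hw: Tuple[int, int]) -> Tensor:
        hybrid = self.hybrid_map(pyramid, target_hw)
        n, c, h, w = hybrid.data.shape
        gamma = self.scale_coefficients(hybrid)
        # broadcast each scale coefficient over its 4 compressed channels
        grouped = hybrid.reshape(n, self.N_SCALES, self.CHANNELS_PER_SCALE, h, w)
        weighted = (grouped * gamma.reshape(n, self.N_SCALES, 1, 1, 1)).reshape(n, c, h, w)
        spatial = self.spatial_conv2(self.spatial_conv1(weighted).relu()).sigmoid()
        return hybrid + weighted + weighted * spatial
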