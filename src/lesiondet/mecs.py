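"""Median-enhanced channel and spatial attention (MECS).

Channel stage: the input is globally pooled three ways (average, max and
median), each pooled vector passes through one shared bottleneck MLP
(1x1 conv C -> C/r, ReLU, 1x1 conv C/r -> C), each branch is squashed with a
sigmoid, and the three sigmoided branches are *summed* -- so the channel
gate lives strictly in (0, 3).  The median branch is the distinguishing
ingredient: on cluttered leaf/soil backgrounds the median is robust to the
few extreme pixels that dominate max pooling.

Spatial stage: a 5x5 depthwise convolution extracts a base map, n separable
strip-convolution branches (1xk then kx1, depthwise) capture elongated
multi-scale context, the base and all branch outputs are summed, projected
with a 1x1 convolution, and multiplied elementwise onto the channel-gated
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, global_median_pool

__all__ = ["MECSConfig", "MECS", "global_pool_stats"]

#: default strip-branch kernel chain: each branch is (1,k) then (k,1) depthwise
DEFAULT_SPATIAL_BRANCHES: tuple[tuple[tuple[int, int], ...], ...] = (
    ((1, 7), (7, 1)),
    ((1, 11), (11, 1)),
    ((1, 21), (21, 1)),
)


@dataclass(frozen=True)
class MECSConfig:
    channels: int
    reduction: int = 16
    spatial_branches: tuple[tuple[tuple[int, int], ...], ...] = DEFAULT_SPATIAL_BRANCHES
    use_median: bool = True
    use_spatial: bool = True

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        if self.channels // self.reduction < 1:
            raise ValueError(
                f"channels/reduction must be >= 1 (got {self.channels}/{self.reduction})"
            )
        if self.use_spatial and len(self.spatial_branches) < 1:
            raise ValueError("at least one spatial branch is required")


def global_pool_stats(x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Global average/max/median pooling, each (B, C, 1, 1).

    The median is taken over all H*W values of a channel; for even counts it
    is the mean of the two middle values.
    """
    avg = x.mean(axis=(2, 3), keepdims=True)
    mx = x.max(axis=(2, 3), keepdims=True)
    med = global_median_pool(x)
    return avg, mx, med


class MECS(nn.Module):
    def __init__(self, cfg: MECSConfig | int, rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(cfg, int):
            cfg = MECSConfig(channels=cfg)
        self.cfg = cfg
        c = cfg.channels
        hidden = max(c // cfg.reduction, 1)
        rng = rng or np.random.default_rng(0)
        self.mlp = nn.Sequential(
            nn.Conv2d(c, hidden, 1, bias=True, rng=rng),
            nn.ReLU(),
            nn.Conv2d(hidden, c, 1, bias=True, rng=rng),
        )
        if cfg.use_spatial:
            self.base = nn.Conv2d(c, c, 5, groups=c, bias=True, rng=rng)
            self.branches = nn.ModuleList(
                nn.Sequential(*[
                    nn.Conv2d(c, c, k, groups=c, bias=True, rng=rng) for k in chain
                ])
                for chain in cfg.spatial_branches
            )
            self.proj = nn.Conv2d(c, c, 1, bias=True, rng=rng)
            # transparent start: the spatial map opens at exactly 1, so
            # stacked blocks do not compound activation magnitude before
            # training (the product F'' = map . F' is quadratic in F')
            self.proj.weight.data[:] = 0.0
            self.proj.bias.data[:] = 1.0

    # -- channel stage --------------------------------------------------
    def channel_attention(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        avg, mx, med = global_pool_stats(x)
        pools = [avg, mx] + ([med] if self.cfg.use_median else [])
        gate = None
        for p in pools:
            branch = self.mlp(p).sigmoid()
            gate = branch if gate is None else gate + branch
        return gate

    @staticmethod
    def apply_channel(x: Tensor, gate: Tensor) -> Tensor:
        return x * gate

    # -- spatial stage ---------------------------------------------------
    def spatial_attention(self, x: Tensor) -> Tensor:
        base = self.base(x)
        total = base
        for br in self.branches:
            total = total + br(base)
        return self.proj(total) * x

    def forward(self, x: Tensor) -> Tensor:
        y = self.apply_channel(x, self.channel_attention(x))
        if self.cfg.use_spatial:
            y = self.spatial_attention(y)
        return y
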