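"""Softmax-gated two-stream feature fusion (BFM).

The block fuses two same-shape feature maps (in this detector: the
top-down/upsampled deeper feature and the lateral backbone feature at a
neck fusion node; in change-detection settings, two time points).  Each
input first passes through a shared multi-scale extractor (3x3, 5x5 and
7x7 depthwise-separable convolutions summed).  From the extracted maps the
block computes

* a per-channel descriptor from four global statistics (average, max,
  standard deviation -- population convention -- and min), mapped through a
  shared bottleneck of 1x1 convolutions, and
* a per-pixel map from the same four statistics pooled across channels,
  mapped through a shared 2-D convolution.

The two inputs' channel logits are normalized with a softmax *across the
input axis*, and likewise the spatial logits, so the pairs of weights sum
to one per channel and per pixel.  The fused output is the weight-modulated
sum ``w_c1*w_s1*t1 + w_c2*w_s2*t2``.  Because every weight path is shared
between the two inputs, swapping the inputs exactly swaps the weights, and
identical inputs receive weight 1/2 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, stack

__all__ = ["BFMConfig", "BFM", "channel_descriptor_stats"]


@dataclass(frozen=True)
class BFMConfig:
    channels: int
    ms_kernels: tuple[int, ...] = (3, 5, 7)
    spatial_kernel: int = 7
    spatial_mid: int = 16

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if tuple(self.ms_kernels) != (3, 5, 7):
            raise ValueError("the multi-scale kernel set is fixed at (3, 5, 7)")


def channel_descriptor_stats(x: Tensor) -> Tensor:
    """Global avg/max/std/min per channel, concatenated to (B, 4C, 1, 1)."""
    avg = x.mean(axis=(2, 3), keepdims=True)
    mx = x.max(axis=(2, 3), keepdims=True)
    mn = -((-x).max(axis=(2, 3), keepdims=True))
    xc = x - avg  # two-pass variance avoids catastrophic cancellation
    std = (xc * xc).mean(axis=(2, 3), keepdims=True).clamp(lo=0.0).sqrt()
    return nn.concat([avg, mx, std, mn], axis=1)


def _spatial_stats(x: Tensor) -> Tensor:
    """The same four statistics pooled across channels -> (B, 4, H, W)."""
    avg = x.mean(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    mn = -((-x).max(axis=1, keepdims=True))
    xc = x - avg
    std = (xc * xc).mean(axis=1, keepdims=True).clamp(lo=0.0).sqrt()
    return nn.concat([avg, mx, std, mn], axis=1)


class _MultiScale(nn.Module):
    """Sum of 3x3/5x5/7x7 depthwise-separable convolutions (shape preserving)."""

    def __init__(self, c: int, kernels: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.paths = nn.ModuleList(
            nn.Sequential(
                nn.Conv2d(c, c, k, groups=c, bias=True, rng=rng),
                nn.Conv2d(c, c, 1, bias=True, rng=rng),
            )
            for k in kernels
        )

    def forward(self, x: Tensor) -> Tensor:
        out = None
        for p in self.paths:
            y = p(x)
            out = y if out is None else out + y
        return out


class BFM(nn.Module):
    def __init__(self, cfg: BFMConfig | int, rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(cfg, int):
            cfg = BFMConfig(channels=cfg)
        self.cfg = cfg
        c = cfg.channels
        rng = rng or np.random.default_rng(0)
        self.ms = _MultiScale(c, tuple(cfg.ms_kernels), rng)
        # channel weight path: 4 stats -> descriptor -> C logits (shared across
        # inputs); the second conv is two-grouped to keep the path lean
        self.ch_path = nn.Sequential(
            nn.Conv2d(4 * c, c, 1, bias=True, rng=rng),
            nn.ReLU(),
            nn.Conv2d(c, c, 1, groups=2 if c % 2 == 0 else 1, bias=True, rng=rng),
        )
        # spatial weight path: 4 channel-pooled maps -> mid -> 1 logit map
        self.sp_path = nn.Sequential(
            nn.Conv2d(4, cfg.spatial_mid, cfg.spatial_kernel, bias=True, rng=rng),
            nn.ReLU(),
            nn.Conv2d(cfg.spatial_mid, 1, cfg.spatial_kernel, bias=True, rng=rng),
        )

    # exposed for direct use/testing ------------------------------------
    def multiscale_features(self, x: Tensor) -> Tensor:
        return self.ms(x)

    def channel_descriptor(self, x: Tensor) -> Tensor:
        return self.ch_path(channel_descriptor_stats(x))

    def fuse(self, t1: Tensor, t2: Tensor) -> Tensor:
        if t1.shape != t2.shape:
            raise ValueError(f"BFM inputs must share a shape: {t1.shape} vs {t2.shape}")
        w_ch, w_sp = self.weights(t1, t2)
        return w_ch[0] * w_sp[0] * t1 + w_ch[1] * w_sp[1] * t2

    def weights(self, t1: Tensor, t2: Tensor) -> tuple[Tensor, Tensor]:
        """Softmax-normalized (channel, spatial) weight pairs, each summing to 1."""
        m1 = self.ms(t1)
        m2 = self.ms(t2)
        ch_logits = stack([self.channel_descriptor(m1), self.channel_descriptor(m2)], axis=0)
        sp_logits = stack([self.sp_path(_spatial_stats(m1)), self.sp_path(_spatial_stats(m2))], axis=0)
        return ch_logits.softmax(axis=0), sp_logits.softmax(axis=0)

    forward = fuse
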