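"""Lightweight convolution stack: GSConv, channel shuffle, GSBottleneck, GSC2f.

GSConv halves the cost of a standard convolution by computing only half the
output channels densely, deriving the other half with a depthwise pass over
the first, and mixing the two groups with a deterministic channel shuffle.
GSBottleneck chains two GSConvs (squeeze to C/2, expand back to C) with an
identity shortcut; GSC2f drops that bottleneck into the CSP-style C2f
topology used throughout the YOLOv8 family neck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ConvSpec",
    "ConvBnAct",
    "channel_shuffle",
    "GSConv",
    "GSBottleneck",
    "GSC2f",
    "complexity_bounds",
]


@dataclass(frozen=True)
class ConvSpec:
    """Dimensions of a convolution, as used by the analytic complexity forms."""

    in_channels: int
    out_channels: int
    kernel: tuple[int, int] = (3, 3)
    stride: int = 1
    groups: int = 1
    bias: bool = False

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.in_channels % self.groups:
            raise ValueError("groups must divide in_channels")


class ConvBnAct(nn.Module):
    """conv -> batch-norm -> SiLU, the family's standard convolution unit."""

    def __init__(self, c1: int, c2: int, k: int | tuple[int, int] = 1, s: int = 1,
                 groups: int = 1, norm: bool = True, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, groups=groups, bias=not norm, rng=rng)
        self.bn = nn.BatchNorm2d(c2) if norm else nn.Identity()
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels by the reshape-(g, C/g) -> transpose -> flatten rule."""
    b, c, h, w = x.shape
    if groups < 1 or c % groups:
        raise ValueError(f"groups={groups} does not divide channel count {c}")
    return (
        x.reshape(b, groups, c // groups, h, w)
        .transpose(0, 2, 1, 3, 4)
        .reshape(b, c, h, w)
    )


class GSConv(nn.Module):
    """Half standard conv, half depthwise conv, concatenated and shuffled.

    Branch 1 is a dense convolution C1 -> C2/2 at the requested stride;
    branch 2 is a depthwise convolution over branch 1's output (stride 1).
    The concatenated C2 channels are shuffled with groups=2 so dense and
    depthwise information interleaves.
    """

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 norm: bool = True, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c2 % 2:
            raise ValueError(f"GSConv requires an even output channel count, got {c2}")
        half = c2 // 2
        self.cv1 = ConvBnAct(c1, half, k, s, norm=norm, act=act, rng=rng)
        self.cv2 = ConvBnAct(half, half, k, 1, groups=half, norm=norm, act=act, rng=rng)
        self.out_channels = c2

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        b = self.cv2(a)
        return channel_shuffle(nn.concat([a, b], axis=1), groups=2)


class GSBottleneck(nn.Module):
    """Channel-preserving residual block made of two GSConvs (C -> C/2 -> C)."""

    def __init__(self, c: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = c // 2
        if mid < 2 or mid % 2:  # GSConv needs an even, nonzero output width
            mid = c
        self.gs1 = GSConv(c, mid, 3, 1, rng=rng)
        self.gs2 = GSConv(self.gs1.out_channels, c, 3, 1, rng=rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.gs2(self.gs1(x))
        if self.shortcut and y.shape == x.shape:
            return x + y
        return y


class GSC2f(nn.Module):
    """C2f topology with GSConv/GSBottleneck substituted for the dense parts.

    1x1 GSConv projects to 2c channels, the two halves are split, n
    GSBottlenecks run sequentially on the second half, and the split plus
    every intermediate are concatenated before a final 1x1 projection.
    """

    def __init__(self, c1: int, c2: int, n: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n < 1:
            raise ValueError("n must be >= 1")
        self.c = c2 // 2
        self.cv1 = GSConv(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBnAct((2 + n) * self.c, c2, 1, rng=rng)
        self.blocks = nn.ModuleList([GSBottleneck(self.c, rng=rng) for _ in range(n)])

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c :]
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(nn.concat(outs, axis=1))


def complexity_bounds(spec: ConvSpec, out_hw: tuple[int, int]) -> tuple[int, int, int]:
    """Analytic time-complexity terms for SC, DSC and GSConv.

    Returns the three products exactly in their published printed form
    (T_SC = Wout*Hout*Kh*C1*C2; T_DSC = Wout*Hout*Kh*C1;
    T_GSConv = Wout*Hout*Kw*Kh*C1).  The printed T_SC omits Kw and the
    printed T_GSConv omits C2; both idiosyncrasies are reproduced verbatim
    rather than corrected, so these values are ordering indicators, not
    FLOP counts (the profiler owns FLOPs).
    """
    wout, hout = out_hw
    if wout < 1 or hout < 1:
        raise ValueError("output dims must be positive")
    kh, kw = spec.kernel
    c1, c2 = spec.in_channels, spec.out_channels
    t_sc = wout * hout * kh * c1 * c2
    t_dsc = wout * hout * kh * c1
    t_gs = wout * hout * kw * kh * c1
    return t_sc, t_dsc, t_gs
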