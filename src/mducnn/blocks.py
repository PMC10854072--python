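"""Architectural primitives: multi-dimensional blocks and residual skip paths.

A *multi-dimensional block* chains three size-preserving 3-kernel
convolutions (widths ``n1 <= n2 <= n3`` from a :class:`~mducnn.schedule.
LevelAllocation`), concatenates their three outputs along channels — an
approximation of parallel 3x3/5x5/7x7 receptive fields at the cost of a
single 3x3 chain — and adds a 1-kernel projection of the block input.  The
projection width must equal ``n1+n2+n3`` for the addition to type-check.

A *skip path* replaces the plain U-Net shortcut with a chain of residual
units (3-kernel conv plus parallel 1-kernel shortcut, added), narrowing the
semantic gap between shallow encoder features and deep decoder features.
Shallower levels get more units; every unit in a path shares one width.

Both primitives exist for spatial rank 2 and 3; the rank is a constructor
argument and all kernels/pools/transposes follow it.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .schedule import LevelAllocation

__all__ = ["ConvBNRelu", "MultiDimBlock", "ResPathUnit", "SkipPath",
           "Downsample", "Upsample2x", "DoubleConv"]


class ConvBNRelu(nn.Module):
    """conv -> (batch-norm) -> relu, size-preserving."""

    def __init__(self, rank, in_ch, out_ch, kernel, rng, batch_norm=True):
        super().__init__()
        self.conv = nn.Conv(rank, in_ch, out_ch, kernel, rng)
        self.bn = nn.BatchNorm(out_ch) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return nn.relu(y)


class MultiDimBlock(nn.Module):
    """Three chained 3-kernel convs, concatenated, plus a 1-kernel residual.

    Output channels = ``alloc.res1_filters`` (= n1+n2+n3); spatial extents
    are preserved.  The residual addition is followed by its own batch-norm
    and ReLU.
    """

    def __init__(self, rank: int, in_channels: int, alloc: LevelAllocation,
                 rng: np.random.Generator, batch_norm: bool = True):
        super().__init__()
        n1, n2, n3 = alloc.conv3_filters
        if alloc.res1_filters != n1 + n2 + n3:
            raise ValueError(
                f"residual width {alloc.res1_filters} incompatible with triple sum {n1+n2+n3}")
        self.rank = rank
        self.in_channels = in_channels
        self.out_channels = alloc.res1_filters
        self.conv1 = ConvBNRelu(rank, in_channels, n1, 3, rng, batch_norm)
        self.conv2 = ConvBNRelu(rank, n1, n2, 3, rng, batch_norm)
        self.conv3 = ConvBNRelu(rank, n2, n3, 3, rng, batch_norm)
        self.res = nn.Conv(rank, in_channels, alloc.res1_filters, 1, rng)
        self.post_bn = nn.BatchNorm(alloc.res1_filters) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.conv1(x)
        y2 = self.conv2(y1)
        y3 = self.conv3(y2)
        cat = nn.concat([y1, y2, y3])
        out = nn.add(cat, self.res(x))
        if self.post_bn is not None:
            out = self.post_bn(out)
        return nn.relu(out)


class ResPathUnit(nn.Module):
    """One skip-path unit: 3-kernel conv + parallel 1-kernel shortcut, added,
    then batch-norm and ReLU.  Output channels = ``width``."""

    def __init__(self, rank: int, in_channels: int, width: int,
                 rng: np.random.Generator, batch_norm: bool = True):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, width
        self.conv = nn.Conv(rank, in_channels, width, 3, rng)
        self.shortcut = nn.Conv(rank, in_channels, width, 1, rng)
        self.bn = nn.BatchNorm(width) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        y = nn.add(self.conv(x), self.shortcut(x))
        if self.bn is not None:
            y = self.bn(y)
        return nn.relu(y)


class SkipPath(nn.Module):
    """A chain of ``unit_count`` residual units of one shared ``unit_width``."""

    def __init__(self, rank: int, in_channels: int, unit_count: int, unit_width: int,
                 rng: np.random.Generator, batch_norm: bool = True):
        super().__init__()
        if unit_count < 1:
            raise ValueError("a skip path needs at least one unit")
        self.out_channels = unit_width
        c = in_channels
        for i in range(unit_count):
            setattr(self, f"unit{i + 1}", ResPathUnit(rank, c, unit_width, rng, batch_norm))
            c = unit_width
        self.unit_count = unit_count

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.unit_count):
            x = getattr(self, f"unit{i + 1}")(x)
        return x


class Downsample(nn.Module):
    """Max-pool with window 2 and stride 2 on every spatial axis."""

    def forward(self, x: Tensor) -> Tensor:
        return nn.maxpool2x(x)


class Upsample2x(nn.Module):
    """Transposed convolution (kernel 2, stride 2) doubling spatial extents."""

    def __init__(self, rank: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.out_channels = out_channels
        self.up = nn.ConvTranspose2x(rank, in_channels, out_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.up(x)


class DoubleConv(nn.Module):
    """The classical U-Net stage: a pair of 3-kernel convolutions.

    ``mid_channels`` defaults to ``out_channels``; the 3D baseline doubles
    filters before pooling by setting ``out_channels = 2 * mid_channels``.
    """

    def __init__(self, rank, in_ch, out_ch, rng, batch_norm=True, mid_ch=None):
        super().__init__()
        mid = mid_ch if mid_ch is not None else out_ch
        self.out_channels = out_ch
        self.conv1 = ConvBNRelu(rank, in_ch, mid, 3, rng, batch_norm)
        self.conv2 = ConvBNRelu(rank, mid, out_ch, 3, rng, batch_norm)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x))
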