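"""Building blocks of the DCSA encoder.

The feature-extraction unit is an inverted-residual block in the MobileNetV3
mould: a 1x1 convolution expands the channel count fourfold, the expanded map
is split into two halves that are filtered by asymmetric depthwise
convolutions (Nx1 followed by 1xN) with *different* kernel lengths on the two
halves, the halves are re-concatenated and projected back down by a 1x1
convolution.  DCA-A keeps the resolution and adds a residual; DCA-B strides
by two in the depthwise pair, max-pools the block input in a parallel branch
and concatenates the two, halving the resolution and doubling the width.  A
channel shuffle after each block mixes information between the two branch
halves, which would otherwise each only ever see half of the channels.

Analytic per-layer cost formulas for standard, depthwise-separable and
asymmetric convolutions live here as well (``conv_flops``), together with an
exact trainable-scalar count (``count_params``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Var
from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    MaxPool2d,
    Module,
    Parameter,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = [
    "FeatureMapSpec",
    "ConvCost",
    "ShuffleSpec",
    "DCABlockConfig",
    "channel_shuffle",
    "shuffle_permutation",
    "conv_flops",
    "count_params",
    "AsymmetricDWConv",
    "ChannelAttention",
    "ChannelShuffle",
    "DCABlock",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FeatureMapSpec:
    """Shape contract (height, width, channels) of a feature map."""

    height: int
    width: int
    channels: int

    def __post_init__(self):
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class ConvCost:
    """Inputs to the analytic convolution-cost formulas.

    ``kernel_length`` is the spatial extent N of the (square or factorised)
    kernel; H and W are the *output* spatial dimensions.
    """

    kernel_length: int
    in_channels: int
    out_channels: int
    out_height: int
    out_width: int

    def __post_init__(self):
        if self.kernel_length < 1 or self.kernel_length % 2 == 0:
            raise ValueError(f"kernel_length must be odd and >= 1, got {self.kernel_length}")
        for name in ("in_channels", "out_channels", "out_height", "out_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class ShuffleSpec:
    """Grouping of a channel axis: ``total_channels = groups * channels_per_group``."""

    groups: int
    channels_per_group: int

    @property
    def total_channels(self):
        return self.groups * self.channels_per_group


@dataclass(frozen=True)
class DCABlockConfig:
    """Configuration of one DCA block.

    ``kernel_small``/``kernel_large`` are the two branch kernel lengths (the
    halves of the expanded map get different receptive fields); ``mode`` is
    "A" (shape-preserving, residual) or "B" (downsampling, width-doubling).
    """

    in_channels: int
    mode: str
    kernel_small: int = 3
    kernel_large: int = 7
    expansion_factor: int = 4
    use_shuffle: bool = True
    use_attention: bool = False
    attention_reduction: int = 4
    attention_on_expanded: bool = False
    shuffle_groups: int = 2

    def __post_init__(self):
        if self.mode not in ("A", "B"):
            raise ValueError(f"mode must be 'A' or 'B', got {self.mode!r}")
        for k in (self.kernel_small, self.kernel_large):
            if k % 2 == 0 or k < 1:
                raise ValueError(f"branch kernels must be odd, got {k}")
        expanded = self.expansion_factor * self.in_channels
        if expanded % 2:
            raise ValueError("expanded channel count must be even for the half/half split")


# ---------------------------------------------------------------------------
# channel shuffle


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index map of the reshape-(g,n), transpose, flatten channel shuffle.

    Output channel ``offset * g + group`` holds input channel
    ``group * n + offset`` with ``n = channels // groups``.
    """
    if channels % groups:
        raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def channel_shuffle(x, groups: int):
    """Shuffle the channel axis of an (N, C, H, W) array or ``Var``."""
    channels = x.shape[1]
    perm = shuffle_permutation(channels, groups)
    if isinstance(x, Var):
        return ag.take_channels(x, perm)
    return np.asarray(x)[:, perm]


class ChannelShuffle(Module):
    def __init__(self, groups=2):
        super().__init__()
        self.groups = groups

    def forward(self, x):
        return channel_shuffle(x, self.groups)


# ---------------------------------------------------------------------------
# analytic cost accounting


def conv_flops(cost: ConvCost, kind: str) -> int:
    """Multiply-accumulate count of one convolution under the stated formulas.

    standard:             H * W * N^2 * C1 * C2
    depthwise_separable:  H * W * N^2 * C1  +  H * W * C1 * C2
    asymmetric:           2 * H * W * N * C1 * C2   (Nx1 then 1xN, dense)
    """
    n, c1, c2 = cost.kernel_length, cost.in_channels, cost.out_channels
    hw = cost.out_height * cost.out_width
    if kind == "standard":
        return hw * n * n * c1 * c2
    if kind == "depthwise_separable":
        return hw * n * n * c1 + hw * c1 * c2
    if kind == "asymmetric":
        return 2 * hw * n * c1 * c2
    raise ValueError(f"unknown kind {kind!r}")


def count_params(module: Module) -> int:
    """Exact number of trainable scalars in a module tree."""
    return module.num_params()


# ---------------------------------------------------------------------------
# blocks


class AsymmetricDWConv(Module):
    """Depthwise Nx1 convolution followed by a depthwise 1xN convolution.

    The overall stride is applied once, on the first (Nx1) convolution, so a
    stride-2 instance halves both spatial dimensions.
    """

    def __init__(self, channels, kernel_length, stride=1, rng=None):
        super().__init__()
        if kernel_length % 2 == 0:
            raise ValueError(f"kernel length must be odd, got {kernel_length}")
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.vertical = DepthwiseConv2d(channels, (kernel_length, 1), stride=stride, rng=rng)
        self.horizontal = DepthwiseConv2d(channels, (1, kernel_length), stride=1, rng=rng)

    def forward(self, x):
        return self.horizontal(self.vertical(x))

    def out_shape(self, shape):
        return self.horizontal.out_shape(self.vertical.out_shape(shape))

    def macs(self, shape):
        mid = self.vertical.out_shape(shape)
        return self.vertical.macs(shape) + self.horizontal.macs(mid)


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global average pool, bottleneck, sigmoid."""

    def __init__(self, channels, reduction=4, rng=None):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        if channels % reduction:
            raise ValueError(f"channels ({channels}) not divisible by reduction ({reduction})")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.channels, self.hidden = channels, hidden
        scale1 = np.sqrt(2.0 / channels)
        scale2 = np.sqrt(2.0 / hidden)
        self.w1 = Parameter(rng.normal(0, scale1, (hidden, channels)).astype(np.float32))
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32))
        self.w2 = Parameter(rng.normal(0, scale2, (channels, hidden)).astype(np.float32))
        self.b2 = Parameter(np.zeros(channels, dtype=np.float32))

    def gate(self, x: Var) -> Var:
        pooled = ag.global_avg_pool(x)  # (N, C)
        h = ag.relu(_linear(pooled, self.w1, self.b1))
        return ag.sigmoid(_linear(h, self.w2, self.b2))

    def forward(self, x):
        return ag.scale_channels(x, self.gate(x))

    def macs(self, shape):
        return self.channels * self.hidden * 2


def _linear(x: Var, w: Parameter, b: Parameter) -> Var:
    data = x.data @ w.data.T + b.data

    def bwd(g):
        if w.requires_grad:
            w.accumulate(g.T @ x.data)
        if b.requires_grad:
            b.accumulate(g.sum(axis=0))
        if x.requires_grad:
            x.accumulate(g @ w.data)

    return Var(data, parents=(x, w, b), backward=bwd)


class DCABlock(Module):
    """The depthwise/channel-shuffle/asymmetric feature-extraction block.

    Mode A preserves shape; mode B halves the spatial dimensions and doubles
    the channel count (strided branches plus a max-pooled copy of the input,
    concatenated along channels).
    """

    def __init__(self, cfg: DCABlockConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c = cfg.in_channels
        expanded = cfg.expansion_factor * c
        half = expanded // 2
        stride = 1 if cfg.mode == "A" else 2

        self.expand = Conv2d(c, expanded, 1, rng=rng)
        self.expand_bn = BatchNorm2d(expanded)
        self.branch_small = AsymmetricDWConv(half, cfg.kernel_small, stride=stride, rng=rng)
        self.branch_small_bn = BatchNorm2d(half)
        self.branch_large = AsymmetricDWConv(half, cfg.kernel_large, stride=stride, rng=rng)
        self.branch_large_bn = BatchNorm2d(half)
        self.project = Conv2d(expanded, c, 1, rng=rng)
        self.project_bn = BatchNorm2d(c)
        if cfg.use_attention:
            att_c = expanded if cfg.attention_on_expanded else c
            self.attention = ChannelAttention(att_c, cfg.attention_reduction, rng=rng)
        else:
            self.attention = None
        if cfg.mode == "B":
            self.pool = MaxPool2d()
        out_c = c if cfg.mode == "A" else 2 * c
        self.shuffle = ChannelShuffle(cfg.shuffle_groups) if cfg.use_shuffle else None
        if self.shuffle is not None and out_c % cfg.shuffle_groups:
            raise ValueError("output channels not divisible by shuffle groups")
        self.out_channels = out_c

    # -- forward -----------------------------------------------------------
    def forward(self, x):
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} channels, got {x.shape[1]}")
        if cfg.mode == "B" and (x.shape[2] % 2 or x.shape[3] % 2):
            raise ValueError(f"DCA-B requires even spatial dims, got {x.shape[2:]}")

        y = ag.relu(self.expand_bn(self.expand(x)))
        x1, x2 = ag.split(y, 2, axis=1)
        b1 = ag.relu(self.branch_small_bn(self.branch_small(x1)))
        b2 = ag.relu(self.branch_large_bn(self.branch_large(x2)))
        y = ag.concat([b1, b2], axis=1)
        if self.attention is not None and cfg.attention_on_expanded:
            y = self.attention(y)
        y = self.project_bn(self.project(y))
        if self.attention is not None and not cfg.attention_on_expanded:
            y = self.attention(y)

        if cfg.mode == "A":
            y = ag.add(y, x)
        else:
            y = ag.concat([y, self.pool(x)], axis=1)
        if self.shuffle is not None:
            y = self.shuffle(y)
        return y

    # -- cost accounting ---------------------------------------------------
    def out_shape(self, shape):
        c, h, w = shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        if self.cfg.mode == "A":
            return (c, h, w)
        return (2 * c, h // 2, w // 2)

    def macs(self, shape):
        cfg = self.cfg
        c, h, w = shape
        expanded = cfg.expansion_factor * c
        half = expanded // 2
        total = self.expand.macs(shape)
        half_in = (half, h, w)
        total += self.branch_small.macs(half_in) + self.branch_large.macs(half_in)
        _, ho, wo = self.branch_small.out_shape(half_in)
        total += self.project.macs((expanded, ho, wo))
        if self.attention is not None:
            total += self.attention.macs(None)
        return total


def dca_a_block(x, cfg: DCABlockConfig, rng=None):
    """Functional form: run a freshly initialised DCA-A block on ``x``."""
    if cfg.mode != "A":
        raise ValueError(f"dca_a_block requires mode 'A', got {cfg.mode!r}")
    return DCABlock(cfg, rng=rng)(x)


def dca_b_block(x, cfg: DCABlockConfig, rng=None):
    """Functional form: run a freshly initialised DCA-B block on ``x``."""
    if cfg.mode != "B":
        raise ValueError(f"dca_b_block requires mode 'B', got {cfg.mode!r}")
    return DCABlock(cfg, rng=rng)(x)
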