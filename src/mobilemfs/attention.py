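"""Attention blocks: FSCA and the published baselines (SE, ECA, CBAM, CA).

FSCA (fused spatial-channel attention) is the block this package exists for.
It chains two gating stages:

1. a *directional* stage — average-pool the feature map along each spatial
   axis, concatenate the two pooled profiles into a 1x(H+W)xC strip,
   normalize it through a reduce-expand 1x1 convolution pair, split it back
   into per-row and per-column weight vectors, squash each through a sigmoid
   and multiply them onto the input (coordinate-attention style); then
2. a *cross-channel pooled* stage — take the per-location channel max and
   channel mean, stack them to an HxWx2 map, fuse with a single-output-channel
   convolution and a sigmoid, and multiply the resulting HxWx1 weight map
   onto the features (CBAM's spatial-gate construction).

Every block here is shape-preserving and multiplies its input by gates in
(0, 1).  ``gate_override`` on any block replaces the sigmoid outputs by a
constant, which turns the block into the identity at 1.0 — used by the
ablation harness and the test suite.

All blocks operate on NCHW :class:`~mobilemfs.nn.Tensor` batches; the
``apply_attention`` helper accepts plain HxWxC (or NxHxWxC) numpy arrays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import (BatchNorm2d, Conv2d, HardSwish, Identity, Module, Parameter,
                 Tensor)


@dataclass(frozen=True)
class AttentionConfig:
    """Hyper-parameters shared by the attention blocks.

    reduction_ratio
        Channel bottleneck divisor inside the directional (spatial) stage and
        inside stand-alone SE; the reduced width is
        ``max(C // reduction_ratio, min_reduced_channels)``.
    spatial_kernel
        Odd kernel size of the single-output-channel fusing convolution in the
        channel stage (and in CBAM's spatial gate).
    min_reduced_channels
        Floor on the reduced width so narrow maps keep a usable bottleneck.
    spatial_first
        Stage order inside FSCA; the directional stage runs first by default.
    """
    reduction_ratio: int = 32
    spatial_kernel: int = 7
    min_reduced_channels: int = 8
    spatial_first: bool = True

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be an odd positive integer")
        if self.min_reduced_channels < 1:
            raise ValueError("min_reduced_channels must be >= 1")

    def reduced(self, channels: int) -> int:
        return max(channels // self.reduction_ratio, self.min_reduced_channels)


def _check_nchw(x: Tensor) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected a 4-d NCHW tensor, got shape {x.shape}")


class _Gated(Module):
    """Mixin state for blocks whose sigmoid gates can be overridden."""

    def __init__(self):
        super().__init__()
        self.gate_override: float | None = None

    def _gate(self, pre: Tensor) -> Tensor:
        if self.gate_override is not None:
            return Tensor(np.full(pre.shape, self.gate_override, dtype=np.float32))
        return nn.sigmoid(pre)


class FSCASpatial(_Gated):
    """Directional (row/column) gating stage of FSCA.

    Pools along width and height, concatenates the H- and W-profiles into one
    1x(H+W) strip, passes it through a shared reduce convolution (with
    normalization and hard-swish) and two per-direction expand convolutions,
    and multiplies the sigmoid of each back onto the input.
    """

    def __init__(self, channels: int, cfg: AttentionConfig | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.cfg = cfg
        red = cfg.reduced(channels)
        self.reduce = Conv2d(channels, red, 1, bias=False, rng=rng)
        self.norm = BatchNorm2d(red)
        self.act = HardSwish()
        self.expand_h = Conv2d(red, channels, 1, bias=True, rng=rng)
        self.expand_w = Conv2d(red, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_nchw(x)
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"block built for {self.channels} channels, got {c}")
        pool_h = nn.mean(x, axis=3, keepdims=True)               # (N,C,H,1)
        pool_w = nn.transpose(nn.mean(x, axis=2, keepdims=True),
                              (0, 1, 3, 2))                      # (N,C,W,1)
        strip = nn.concat([pool_h, pool_w], axis=2)              # (N,C,H+W,1)
        strip = self.act(self.norm(self.reduce(strip)))
        part_h = nn.narrow(strip, 2, 0, h)
        part_w = nn.narrow(strip, 2, h, w)
        gate_h = self._gate(self.expand_h(part_h))               # (N,C,H,1)
        gate_w = self._gate(nn.transpose(self.expand_w(part_w),
                                         (0, 1, 3, 2)))          # (N,C,1,W)
        return nn.mul(nn.mul(x, gate_h), gate_w)


class FSCAChannel(_Gated):
    """Cross-channel pooled gating stage of FSCA.

    Per spatial location, the channel max and channel mean are stacked into a
    2-channel map, fused by a kxk single-output-channel convolution (with
    bias; no normalization follows) and squashed by a sigmoid into one weight
    per location, which scales every channel at that location.
    """

    def __init__(self, channels: int, cfg: AttentionConfig | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.cfg = cfg
        k = cfg.spatial_kernel
        self.fuse = Conv2d(2, 1, k, padding=k // 2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_nchw(x)
        cmax = nn.channel_max(x)                 # (N,1,H,W)
        cmean = nn.mean(x, axis=1, keepdims=True)
        stacked = nn.concat([cmax, cmean], axis=1)
        gate = self._gate(self.fuse(stacked))    # (N,1,H,W)
        return nn.mul(x, gate)


class FSCA(Module):
    """Fused spatial-channel attention: the two stages chained."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig()
        self.cfg = cfg
        self.spatial = FSCASpatial(channels, cfg, rng=rng)
        self.channel = FSCAChannel(channels, cfg, rng=rng)

    @property
    def gate_override(self):
        return self.spatial.gate_override

    @gate_override.setter
    def gate_override(self, value):
        self.spatial.gate_override = value
        self.channel.gate_override = value

    def forward(self, x: Tensor) -> Tensor:
        if self.cfg.spatial_first:
            return self.channel(self.spatial(x))
        return self.spatial(self.channel(x))


class SEBlock(_Gated):
    """Squeeze-and-Excitation: global average pool, two 1x1 FC convolutions
    (biased) with ReLU between, hard-sigmoid gate, channelwise multiply."""

    def __init__(self, channels: int, squeeze_channels: int | None = None,
                 cfg: AttentionConfig | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if squeeze_channels is None:
            cfg = cfg or AttentionConfig(reduction_ratio=4)
            squeeze_channels = cfg.reduced(channels)
        self.channels = channels
        self.squeeze_channels = squeeze_channels
        self.fc1 = Conv2d(channels, squeeze_channels, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(squeeze_channels, channels, 1, bias=True, rng=rng)

    def _gate(self, pre: Tensor) -> Tensor:  # SE uses the hard sigmoid
        if self.gate_override is not None:
            return Tensor(np.full(pre.shape, self.gate_override, dtype=np.float32))
        return nn.hardsigmoid(pre)

    def forward(self, x: Tensor) -> Tensor:
        _check_nchw(x)
        s = nn.mean(x, axis=(2, 3), keepdims=True)
        s = self.fc2(nn.relu(self.fc1(s)))
        return nn.mul(x, self._gate(s))


class ECABlock(_Gated):
    """Efficient channel attention: a k-tap 1-d convolution over the globally
    averaged channel profile, no dimensionality reduction."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None, *,
                 gamma: int = 2, b: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        t = int(abs(math.log2(channels) / gamma + b / gamma))
        self.kernel_size = t if t % 2 else t + 1
        self.weight = Parameter(rng.normal(
            0.0, 1.0 / math.sqrt(self.kernel_size),
            size=self.kernel_size).astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        _check_nchw(x)
        n, c, _, _ = x.shape
        prof = nn.reshape(nn.mean(x, axis=(2, 3), keepdims=True), (n, 1, c))
        k, p = self.kernel_size, self.kernel_size // 2
        # 1-d conv over channels as a sum of shifted, weighted slices
        padded = nn.concat([Tensor(np.zeros((n, 1, p), dtype=np.float32)), prof,
                            Tensor(np.zeros((n, 1, p), dtype=np.float32))], axis=2)
        acc = None
        for i in range(k):
            term = nn.mul(nn.narrow(padded, 2, i, c),
                          nn.narrow(nn.reshape(self.weight, (1, 1, k)), 2, i, 1))
            acc = term if acc is None else nn.add(acc, term)
        gate = self._gate(nn.reshape(acc, (n, c, 1, 1)))
        return nn.mul(x, gate)


class CBAMBlock(_Gated):
    """Convolutional block attention: a channel gate (shared MLP over global
    average- and max-pooled descriptors) followed by a spatial gate (channel
    mean/max stack through a kxk convolution)."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None, *,
                 reduction: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        red = max(channels // reduction, 1)
        self.mlp1 = Conv2d(channels, red, 1, bias=False, rng=rng)
        self.mlp2 = Conv2d(red, channels, 1, bias=False, rng=rng)
        k = cfg.spatial_kernel
        self.spatial_conv = Conv2d(2, 1, k, padding=k // 2, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_nchw(x)
        n, c, h, w = x.shape
        avg = nn.mean(x, axis=(2, 3), keepdims=True)
        mx = nn.amax(nn.reshape(x, (n, c, h * w, 1)), axis=2, keepdims=True)
        pre = nn.add(self.mlp2(nn.relu(self.mlp1(avg))),
                     self.mlp2(nn.relu(self.mlp1(mx))))
        x = nn.mul(x, self._gate(pre))
        smax = nn.channel_max(x)
        smean = nn.mean(x, axis=1, keepdims=True)
        sgate = self._gate(self.spatial_conv(nn.concat([smean, smax], axis=1)))
        return nn.mul(x, sgate)


class CoordinateAttention(FSCASpatial):
    """Coordinate attention: directional pooled gating only (the construction
    FSCA's first stage follows)."""


_REGISTRY = {
    "none": lambda channels, cfg, rng, squeeze: Identity(),
    "se": lambda channels, cfg, rng, squeeze: SEBlock(
        channels, squeeze_channels=squeeze, cfg=cfg, rng=rng),
    "eca": lambda channels, cfg, rng, squeeze: ECABlock(channels, cfg, rng=rng),
    "cbam": lambda channels, cfg, rng, squeeze: CBAMBlock(channels, cfg, rng=rng),
    "ca": lambda channels, cfg, rng, squeeze: CoordinateAttention(
        channels, cfg, rng=rng),
    "fsca": lambda channels, cfg, rng, squeeze: FSCA(channels, cfg, rng=rng),
}

ATTENTION_NAMES = tuple(_REGISTRY)


def attention_block(name: str, channels: int,
                    cfg: AttentionConfig | None = None, *,
                    squeeze_channels: int | None = None,
                    rng: np.random.Generator | None = None) -> Module:
    """Build a registered attention block by name.

    ``squeeze_channels`` pins SE's bottleneck width explicitly (the backbone
    builder uses this for parity with the published layer table); other blocks
    ignore it.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown attention block {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return factory(channels, cfg, rng, squeeze_channels)


def _to_nchw(x: np.ndarray) -> tuple[Tensor, bool]:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        return Tensor(x.transpose(2, 0, 1)[None]), True
    if x.ndim == 4:
        return Tensor(x.transpose(0, 3, 1, 2)), False
    raise ValueError(f"expected HxWxC or NxHxWxC input, got shape {x.shape}")


def apply_attention(block: Module, x: np.ndarray) -> np.ndarray:
    """Run an attention block on an HxWxC (or NxHxWxC) numpy feature map."""
    t, squeeze = _to_nchw(x)
    if not np.all(np.isfinite(t.data)):
        raise ValueError("feature map contains non-finite values")
    with nn.no_grad():
        y = block(t)
    out = y.data.transpose(0, 2, 3, 1)
    return out[0] if squeeze else out
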