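"""Multi-scale feature-extraction front end.

Four parallel convolutions with kernel sizes 1, 3, 5 and 7 run on the raw
input image at stride 1 with "same" padding, so each branch sees the same
spatial grid through a different receptive field.  The four branch outputs are
concatenated along the channel axis and fused by a 1x1 convolution into one
feature map, which replaces the raw image as the backbone stem's input.  The
module is strictly optional at build time so the backbone can be ablated with
and without it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import BatchNorm2d, Conv2d, HardSwish, Module, Tensor


@dataclass(frozen=True)
class MultiScaleConfig:
    """Widths and kernel ladder of the front end.

    kernel_sizes
        Parallel branch kernels; all odd so "same" padding preserves H and W.
    branch_channels
        Output width of every branch; the concatenated map then has
        ``4 * branch_channels`` channels under the default ladder.
    fuse_channels
        Width after the 1x1 fusing convolution — the width handed to the stem.
    concat_only
        Skip the fusing convolution and hand the raw concatenation onward
        (ablation mode).
    """
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    branch_channels: int = 8
    fuse_channels: int = 16
    concat_only: bool = False

    def __post_init__(self):
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive, got {k}")
        if self.branch_channels < 1 or self.fuse_channels < 1:
            raise ValueError("channel widths must be positive")

    @property
    def out_channels(self) -> int:
        if self.concat_only:
            return len(self.kernel_sizes) * self.branch_channels
        return self.fuse_channels


class MultiScaleFrontend(Module):
    """Parallel multi-kernel branches, channel concat, 1x1 fuse.

    Each branch is convolution + batch normalization + hard-swish by default;
    ``norm_act=False`` builds purely linear branches (no normalization or
    activation), which the test harness uses to probe the wiring with
    hand-set kernels.
    """

    def __init__(self, cfg: MultiScaleConfig | None = None, *,
                 in_channels: int = 3, norm_act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or MultiScaleConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.in_channels = in_channels
        self.norm_act = norm_act
        self.branches = [
            Conv2d(in_channels, cfg.branch_channels, k, padding=k // 2,
                   bias=not norm_act, rng=rng)
            for k in cfg.kernel_sizes]
        cat_c = len(cfg.kernel_sizes) * cfg.branch_channels
        if norm_act:
            # one per-channel norm over the concatenated branches is exactly
            # per-branch normalization, without the split/concat round trip
            self.branch_norm = BatchNorm2d(cat_c)
            self.branch_act = HardSwish()
        else:
            self.branch_norm = None
            self.branch_act = None
        if cfg.concat_only:
            self.fuse = None
        else:
            fconv = Conv2d(cat_c, cfg.fuse_channels, 1, bias=not norm_act, rng=rng)
            if norm_act:
                self.fuse = nn.Sequential(fconv, BatchNorm2d(cfg.fuse_channels),
                                          HardSwish())
            else:
                self.fuse = nn.Sequential(fconv)

    @property
    def out_channels(self) -> int:
        return self.cfg.out_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"front end built for {self.in_channels} input channels, "
                f"got {x.shape[1]}")
        if nn._TALLY_STACK:
            # per-branch path so complexity accounting sees true kernel sizes
            out = nn.concat([branch(x) for branch in self.branches], axis=1)
        else:
            # fused path: one shared im2col + one GEMM for all branches
            out = nn.multi_conv2d(x, [c.weight for c in self.branches],
                                  [c.bias for c in self.branches],
                                  list(self.cfg.kernel_sizes))
        if self.branch_norm is not None:
            out = self.branch_act(self.branch_norm(out))
        if self.fuse is not None:
            out = self.fuse(out)
        return out
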