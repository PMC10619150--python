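"""Declarative assembly of MobileNet v3-Large and MobileNet-MFS.

The backbone is a chain of inverted-residual bottlenecks: a 1x1 expansion
convolution widens the representation, a kxk depthwise convolution filters it
spatially, an optional attention block gates the expanded representation, and
a linear 1x1 projection narrows it again; a residual shortcut is added when
stride is 1 and the input and output widths match.  MobileNet-MFS is the same
layout with (a) the multi-scale front end ahead of the stem and (b) every SE
site replaced by an FSCA block.

`count_params` and `count_macs` provide the complexity accounting: trainable
scalar totals (batch-norm affine pairs included) and multiply-accumulates at a
stated input size (one MAC counted once; normalization/activation excluded).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import AttentionConfig, attention_block
from .multiscale import MultiScaleConfig, MultiScaleFrontend
from .nn import (BatchNorm2d, Conv2d, Dropout, Flatten, GlobalAvgPool,
                 HardSwish, Identity, Linear, Module, ReLU, Sequential, Tensor)

_ACTIVATIONS = {"relu": ReLU, "hswish": HardSwish}


def make_divisible(v: float, divisor: int = 8, min_value: int | None = None) -> int:
    """Round a channel width to the nearest multiple of ``divisor`` without
    dropping more than 10% (the MobileNet width convention)."""
    if min_value is None:
        min_value = divisor
    new_v = max(min_value, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


@dataclass(frozen=True)
class BottleneckSpec:
    """One inverted-residual block."""
    in_channels: int
    expand_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    activation: str = "relu"
    attention: str = "none"

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if min(self.in_channels, self.expand_channels, self.out_channels) < 1:
            raise ValueError("channel widths must be positive")

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


class Bottleneck(Module):
    """expand (1x1, omitted when widths match) -> depthwise kxk -> attention
    on the expanded representation -> linear 1x1 projection [+ residual]."""

    def __init__(self, spec: BottleneckSpec,
                 attention_cfg: AttentionConfig | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        act = _ACTIVATIONS[spec.activation]
        self.spec = spec
        if spec.expand_channels != spec.in_channels:
            self.expand = Sequential(
                Conv2d(spec.in_channels, spec.expand_channels, 1, bias=False,
                       rng=rng),
                BatchNorm2d(spec.expand_channels), act())
        else:
            self.expand = Identity()
        self.depthwise = Sequential(
            Conv2d(spec.expand_channels, spec.expand_channels, spec.kernel,
                   stride=spec.stride, padding=spec.kernel // 2,
                   groups=spec.expand_channels, bias=False, rng=rng),
            BatchNorm2d(spec.expand_channels), act())
        # SE bottleneck width follows the published layer table
        squeeze = make_divisible(spec.expand_channels // 4, 8)
        self.attention = attention_block(spec.attention, spec.expand_channels,
                                         attention_cfg, squeeze_channels=squeeze,
                                         rng=rng)
        self.project = Sequential(
            Conv2d(spec.expand_channels, spec.out_channels, 1, bias=False,
                   rng=rng),
            BatchNorm2d(spec.out_channels))

    def forward(self, x: Tensor) -> Tensor:
        out = self.project(self.attention(self.depthwise(self.expand(x))))
        if self.spec.has_residual:
            out = nn.add(out, x)
        return out


# published v3-Large layer table: (in, expand, out, kernel, stride,
# attention site, activation)
V3_LARGE_TABLE: tuple[tuple[int, int, int, int, int, bool, str], ...] = (
    (16, 16, 16, 3, 1, False, "relu"),
    (16, 64, 24, 3, 2, False, "relu"),
    (24, 72, 24, 3, 1, False, "relu"),
    (24, 72, 40, 5, 2, True, "relu"),
    (40, 120, 40, 5, 1, True, "relu"),
    (40, 120, 40, 5, 1, True, "relu"),
    (40, 240, 80, 3, 2, False, "hswish"),
    (80, 200, 80, 3, 1, False, "hswish"),
    (80, 184, 80, 3, 1, False, "hswish"),
    (80, 184, 80, 3, 1, False, "hswish"),
    (80, 480, 112, 3, 1, True, "hswish"),
    (112, 672, 112, 3, 1, True, "hswish"),
    (112, 672, 160, 5, 2, True, "hswish"),
    (160, 960, 160, 5, 1, True, "hswish"),
    (160, 960, 160, 5, 1, True, "hswish"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Full network description: optional front end, stem, bottleneck chain,
    head widths and the classifier."""
    bottlenecks: tuple[BottleneckSpec, ...]
    num_classes: int
    frontend: MultiScaleConfig | None = None
    stem_channels: int = 16
    last_channels: int = 960
    hidden_channels: int = 1280
    dropout: float = 0.2
    attention_cfg: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        prev = self.stem_channels
        for i, b in enumerate(self.bottlenecks):
            if b.in_channels != prev:
                raise ValueError(
                    f"bottleneck {i} expects {b.in_channels} input channels "
                    f"but the chain carries {prev}")
            prev = b.out_channels

    def to_json(self) -> str:
        d = {
            "num_classes": self.num_classes,
            "stem_channels": self.stem_channels,
            "last_channels": self.last_channels,
            "hidden_channels": self.hidden_channels,
            "dropout": self.dropout,
            "frontend": None if self.frontend is None else {
                "kernel_sizes": list(self.frontend.kernel_sizes),
                "branch_channels": self.frontend.branch_channels,
                "fuse_channels": self.frontend.fuse_channels,
                "concat_only": self.frontend.concat_only,
            },
            "attention_cfg": {
                "reduction_ratio": self.attention_cfg.reduction_ratio,
                "spatial_kernel": self.attention_cfg.spatial_kernel,
                "min_reduced_channels": self.attention_cfg.min_reduced_channels,
                "spatial_first": self.attention_cfg.spatial_first,
            },
            "bottlenecks": [
                [b.in_channels, b.expand_channels, b.out_channels, b.kernel,
                 b.stride, b.activation, b.attention]
                for b in self.bottlenecks
            ],
        }
        return json.dumps(d)

    @staticmethod
    def from_json(s: str) -> "ModelSpec":
        d = json.loads(s)
        frontend = None
        if d["frontend"] is not None:
            f = d["frontend"]
            frontend = MultiScaleConfig(
                kernel_sizes=tuple(f["kernel_sizes"]),
                branch_channels=f["branch_channels"],
                fuse_channels=f["fuse_channels"],
                concat_only=f["concat_only"])
        return ModelSpec(
            bottlenecks=tuple(
                BottleneckSpec(b[0], b[1], b[2], b[3], b[4], b[5], b[6])
                for b in d["bottlenecks"]),
            num_classes=d["num_classes"], frontend=frontend,
            stem_channels=d["stem_channels"], last_channels=d["last_channels"],
            hidden_channels=d["hidden_channels"], dropout=d["dropout"],
            attention_cfg=AttentionConfig(**d["attention_cfg"]))


class MobileNetClassifier(Module):
    """Assembled network: [front end ->] stem -> bottlenecks -> 1x1 conv ->
    global average pool -> hidden FC (hard-swish, dropout) -> logits."""

    def __init__(self, spec: ModelSpec, *, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        if spec.frontend is not None:
            self.frontend = MultiScaleFrontend(spec.frontend, rng=rng)
            stem_in = spec.frontend.out_channels
        else:
            self.frontend = None
            stem_in = 3
        self.stem = Sequential(
            Conv2d(stem_in, spec.stem_channels, 3, stride=2, padding=1,
                   bias=False, rng=rng),
            BatchNorm2d(spec.stem_channels), HardSwish())
        self.blocks = [Bottleneck(b, spec.attention_cfg, rng=rng)
                       for b in spec.bottlenecks]
        last_in = spec.bottlenecks[-1].out_channels
        self.last_conv = Sequential(
            Conv2d(last_in, spec.last_channels, 1, bias=False, rng=rng),
            BatchNorm2d(spec.last_channels), HardSwish())
        self.pool = GlobalAvgPool()
        self.flatten = Flatten()
        self.classifier = Sequential(
            Linear(spec.last_channels, spec.hidden_channels, rng=rng),
            HardSwish(), Dropout(spec.dropout, rng=np.random.default_rng(seed + 1)),
            Linear(spec.hidden_channels, spec.num_classes, rng=rng))

    # ordered feature maps available to Grad-CAM
    def feature_layer_names(self) -> list[str]:
        names = []
        if self.frontend is not None:
            names.append("frontend")
        names.append("stem")
        names.extend(f"bneck{i}" for i in range(len(self.blocks)))
        names.append("last_conv")
        return names

    def forward(self, x: Tensor, *, return_activations: bool = False):
        acts: dict[str, Tensor] = {}
        if self.frontend is not None:
            x = self.frontend(x)
            acts["frontend"] = x
        x = self.stem(x)
        acts["stem"] = x
        for i, block in enumerate(self.blocks):
            x = block(x)
            acts[f"bneck{i}"] = x
        x = self.last_conv(x)
        acts["last_conv"] = x
        logits = self.classifier(self.flatten(self.pool(x)))
        if return_activations:
            return logits, acts
        return logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities for an (N,3,H,W) float array."""
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(images), batch_size):
                logits = self.forward(Tensor(images[i:i + batch_size]))
                out.append(nn.softmax(logits.data))
        return np.concatenate(out, axis=0)


def v3_large_spec(num_classes: int, attention: str = "se",
                  frontend: MultiScaleConfig | None = None,
                  attention_cfg: AttentionConfig | None = None) -> ModelSpec:
    """The published v3-Large layout with the attention sites of its layer
    table filled by ``attention``."""
    bottlenecks = tuple(
        BottleneckSpec(cin, exp, cout, k, s,
                       activation=act,
                       attention=attention if att_site else "none")
        for cin, exp, cout, k, s, att_site, act in V3_LARGE_TABLE)
    return ModelSpec(bottlenecks=bottlenecks, num_classes=num_classes,
                     frontend=frontend,
                     attention_cfg=attention_cfg or AttentionConfig())


def build_mobilenet_v3_large(num_classes: int, *, seed: int = 0) -> MobileNetClassifier:
    """Standard MobileNet v3-Large (SE attention, no front end)."""
    return MobileNetClassifier(v3_large_spec(num_classes), seed=seed)


def build_mobilenet_mfs(num_classes: int, *,
                        frontend: MultiScaleConfig | None | str = "default",
                        attention: str = "fsca",
                        attention_cfg: AttentionConfig | None = None,
                        seed: int = 0) -> MobileNetClassifier:
    """MobileNet-MFS: v3-Large with the multi-scale front end ahead of the
    stem and FSCA at every SE site.

    ``frontend="default"`` uses the standard :class:`MultiScaleConfig`;
    ``frontend=None`` drops the front end entirely (ablation).  ``attention``
    in {se, eca, cbam, ca, fsca, none} selects the block at the attention
    sites for the attention-mechanism sweep.
    """
    if frontend == "default":
        frontend = MultiScaleConfig()
    return MobileNetClassifier(
        v3_large_spec(num_classes, attention=attention, frontend=frontend,
                      attention_cfg=attention_cfg),
        seed=seed)


# compact preset used for desk-scale end-to-end runs on synthetic data
COMPACT_TABLE: tuple[tuple[int, int, int, int, int, bool, str], ...] = (
    (16, 32, 16, 3, 2, True, "relu"),
    (16, 64, 24, 3, 2, True, "hswish"),
    (24, 72, 24, 3, 1, True, "hswish"),
    (24, 96, 40, 5, 2, True, "hswish"),
    (40, 120, 40, 5, 1, True, "hswish"),
)


def compact_mfs_spec(num_classes: int, attention: str = "fsca",
                     frontend: MultiScaleConfig | None = MultiScaleConfig(
                         branch_channels=4, fuse_channels=16)) -> ModelSpec:
    """A narrow, shallow MobileNet-MFS preset (same block family: multi-scale
    front end + FSCA-gated inverted residuals) sized for CPU training on
    small synthetic images."""
    bottlenecks = tuple(
        BottleneckSpec(cin, exp, cout, k, s, activation=act,
                       attention=attention if att_site else "none")
        for cin, exp, cout, k, s, att_site, act in COMPACT_TABLE)
    return ModelSpec(bottlenecks=bottlenecks, num_classes=num_classes,
                     frontend=frontend, last_channels=160,
                     hidden_channels=128)


def build_compact_mfs(num_classes: int, *, attention: str = "fsca",
                      with_frontend: bool = True, seed: int = 0) -> MobileNetClassifier:
    frontend = MultiScaleConfig(branch_channels=4, fuse_channels=16) \
        if with_frontend else None
    return MobileNetClassifier(
        compact_mfs_spec(num_classes, attention=attention, frontend=frontend),
        seed=seed)


MODEL_PRESETS = {
    "mobilenet_v3": lambda num_classes, seed=0: build_mobilenet_v3_large(
        num_classes, seed=seed),
    "mobilenet_mfs": lambda num_classes, seed=0: build_mobilenet_mfs(
        num_classes, seed=seed),
    "mobilenet_mfs_small": lambda num_classes, seed=0: build_compact_mfs(
        num_classes, seed=seed),
}


# --------------------------------------------------------------------------
# complexity accounting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelStats:
    param_count: int
    mac_count: int
    input_hw: tuple[int, int]
    per_layer: tuple[dict, ...] = ()

    @property
    def params_millions(self) -> float:
        return self.param_count / 1e6

    @property
    def mac_mflops(self) -> float:
        return self.mac_count / 1e6


def count_params(model: Module) -> int:
    """Total trainable scalars (convolution/linear weights and biases plus the
    two affine scalars of every normalized channel)."""
    return int(sum(p.data.size for p in model.parameters()))


def count_macs(model: MobileNetClassifier, input_hw: tuple[int, int] = (224, 224),
               in_channels: int = 3) -> int:
    """Multiply-accumulates of one forward pass at ``input_hw``.

    Counted over convolutions (out_H*out_W*out_C*in_C*k*k / groups) and fully
    connected layers; one MAC counted once; elementwise, normalization and
    activation ops excluded.
    """
    return model_stats(model, input_hw, in_channels=in_channels).mac_count


def model_stats(model: MobileNetClassifier,
                input_hw: tuple[int, int] = (224, 224),
                in_channels: int = 3) -> ModelStats:
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, in_channels, *input_hw), dtype=np.float32))
    with nn.no_grad(), nn.mac_tally() as tally:
        model(x)
    model.train(was_training)
    return ModelStats(param_count=count_params(model), mac_count=tally.total,
                      input_hw=tuple(input_hw), per_layer=tuple(tally.records))


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: MobileNetClassifier, path) -> None:
    """Serialize weights + buffers with an embedded spec snapshot."""
    state = model.state_dict()
    np.savez(path, __spec__=np.frombuffer(
        model.spec.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path, *, model: MobileNetClassifier | None = None,
                    strict: bool = True):
    """Rebuild (or update) a model from a checkpoint.

    Returns ``(model, summary)`` where summary lists loaded and skipped
    tensors; with ``strict=False`` mismatching names/shapes are skipped
    tensor-by-tensor, which is the transfer-learning path.
    """
    with np.load(path) as data:
        spec_json = bytes(data["__spec__"]).decode()
        state = {k: data[k] for k in data.files if k != "__spec__"}
    if model is None:
        model = MobileNetClassifier(ModelSpec.from_json(spec_json))
    summary = model.load_state_dict(state, strict=strict)
    return model, summary
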