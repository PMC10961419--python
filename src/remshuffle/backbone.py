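"""Channel-shuffle CNN units and the REM-ShuffleNetV2 assembly.

The backbone follows the ShuffleNetV2 design: each stage opens with a
downsampling unit (two stride-2 branches, concatenated and shuffled) followed
by a run of basic units (channel split, one depthwise-separable branch,
concat, shuffle).  The REM variant adds, relative to the stock network:

* re-tuned stage repeats [2, 3, 2] and widths [96, 192, 384, 1024];
* a residual shortcut in every unit — identity in basic units, and in
  downsampling units a projected shortcut (max pool + 1x1 conv by default);
* an EDCA channel-attention block at the tail of each unit's conv branch;
* a multi-scale stem (MSFEM) and a multi-scale deep block (MDFEM) between
  the last stage and the final pointwise convolution.

Every constructor takes a numpy Generator so weight initialization is fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import AttentionConfig, make_attention
from .nn import functional as F
from .nn.layers import conv_bn_relu
from .nn.tensor import Tensor

RESIDUAL_KINDS = ("none", "rm", "ra", "rc")
STEM_KINDS = ("a", "b", "c", "msfem")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageConfig:
    """Basic-unit repetitions per stage and the stage/final channel widths."""

    repeats: tuple[int, int, int] = (2, 3, 2)
    out_channels: tuple[int, int, int, int] = (96, 192, 384, 1024)

    def __post_init__(self):
        if len(self.repeats) != 3 or any(r < 1 for r in self.repeats):
            raise ValueError("repeats must be 3 positive integers")
        if len(self.out_channels) != 4 or any(c < 1 for c in self.out_channels):
            raise ValueError("out_channels must be 4 positive integers")
        if any(c % 2 for c in self.out_channels[:3]):
            raise ValueError("stage channels must be even (channel split)")


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture specification."""

    stage: StageConfig = field(default_factory=StageConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    residual: str = "rm"
    stem: str = "msfem"
    use_mdfem: bool = True
    num_classes: int = 22
    input_size: int = 224

    def __post_init__(self):
        if self.residual not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual kind {self.residual!r}")
        if self.stem not in STEM_KINDS:
            raise ValueError(f"unknown stem kind {self.stem!r}")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_size % 4:
            raise ValueError("input size must be divisible by 4")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "stage" in d and isinstance(d["stage"], dict):
            s = d["stage"]
            d["stage"] = StageConfig(tuple(s["repeats"]), tuple(s["out_channels"]))
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionConfig(**d["attention"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def rem_preset(num_classes: int = 22, input_size: int = 224) -> ModelConfig:
    """The full REM configuration: [2,3,2] repeats, [96,192,384,1024] widths,
    EDCA attention, max-pool residual shortcut, multi-scale stem and deep
    block."""
    return ModelConfig(num_classes=num_classes, input_size=input_size)


def baseline_preset(num_classes: int = 22,
                    repeats=(3, 7, 3),
                    out_channels=(116, 232, 464, 1024)) -> ModelConfig:
    """Stock ShuffleNetV2-1.0: no attention, no residual, plain stem."""
    return ModelConfig(
        stage=StageConfig(tuple(repeats), tuple(out_channels)),
        attention=AttentionConfig(kind="none"),
        residual="none", stem="a", use_mdfem=False, num_classes=num_classes,
    )


def tiny_preset(num_classes: int = 4, input_size: int = 64) -> ModelConfig:
    """A desk-scale REM variant (all REM features, narrow widths) for CPU
    experiments and the synthetic learning-sanity run."""
    return ModelConfig(
        stage=StageConfig((1, 1, 1), (24, 48, 96, 256)),
        num_classes=num_classes, input_size=input_size,
    )


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The channel-shuffle permutation: position (g, i) -> (i, g)."""
    if channels % groups:
        raise ValueError(f"channels {channels} not divisible by groups {groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def channel_shuffle(x, groups: int):
    """Interleave channel groups (reshape–transpose–flatten permutation).

    Accepts a Tensor (gradient-tracked) or a plain array.
    """
    if isinstance(x, Tensor):
        return F.take_channels(x, shuffle_permutation(x.data.shape[1], groups))
    x = np.asarray(x)
    return x[:, shuffle_permutation(x.shape[1], groups)]


def channel_split(x):
    """Split a feature map into two half-channel maps; concat restores it."""
    c = x.data.shape[1] if isinstance(x, Tensor) else x.shape[1]
    if c % 2:
        raise ValueError(f"cannot split odd channel count {c}")
    h = c // 2
    if isinstance(x, Tensor):
        return F.slice_channels(x, 0, h), F.slice_channels(x, h, c)
    return x[:, :h], x[:, h:]


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

class BasicUnit(nn.Module):
    """Stride-1 unit: split, depthwise-separable right branch with optional
    attention at its tail, concat, shuffle, optional identity residual."""

    def __init__(self, channels: int, attention: AttentionConfig,
                 residual: bool, rng: np.random.Generator):
        super().__init__()
        if channels % 2:
            raise ValueError("basic unit needs an even channel count")
        self.channels = channels
        half = channels // 2
        self.pw1 = conv_bn_relu(half, half, 1, rng=rng)
        self.dw = conv_bn_relu(half, half, 3, padding=1, groups=half,
                               relu=False, rng=rng)
        self.pw2 = conv_bn_relu(half, half, 1, rng=rng)
        self.attn = make_attention(half, attention, rng=rng)
        self.residual = residual

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.data.shape[1]}")
        left, right = channel_split(x)
        right = self.attn(self.pw2(self.dw(self.pw1(right))))
        out = channel_shuffle(F.concat_channels([left, right]), 2)
        if self.residual:
            out = out + x
        return out


class DownUnit(nn.Module):
    """Stride-2 stage opener: two stride-2 branches concatenated and
    shuffled, with optional attention on the conv branch tail and an optional
    projected residual shortcut (rm: max pool, ra: avg pool, rc: 3x3 conv)."""

    def __init__(self, in_c: int, out_c: int, attention: AttentionConfig,
                 residual: str, rng: np.random.Generator):
        super().__init__()
        if residual not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual kind {residual!r}")
        if out_c % 2:
            raise ValueError("downsampling unit needs an even output width")
        self.in_c, self.out_c = in_c, out_c
        half = out_c // 2
        # left branch: depthwise stride 2, then pointwise
        self.left_dw = conv_bn_relu(in_c, in_c, 3, stride=2, padding=1,
                                    groups=in_c, relu=False, rng=rng)
        self.left_pw = conv_bn_relu(in_c, half, 1, rng=rng)
        # right branch: pointwise, depthwise stride 2, pointwise, attention
        self.right_pw1 = conv_bn_relu(in_c, half, 1, rng=rng)
        self.right_dw = conv_bn_relu(half, half, 3, stride=2, padding=1,
                                     groups=half, relu=False, rng=rng)
        self.right_pw2 = conv_bn_relu(half, half, 1, rng=rng)
        self.attn = make_attention(half, attention, rng=rng)
        self.residual = residual
        if residual in ("rm", "ra"):
            self.shortcut_proj = conv_bn_relu(in_c, out_c, 1, relu=False, rng=rng)
        elif residual == "rc":
            self.shortcut_proj = conv_bn_relu(in_c, out_c, 3, stride=2,
                                              padding=1, relu=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        left = self.left_pw(self.left_dw(x))
        right = self.attn(self.right_pw2(self.right_dw(self.right_pw1(x))))
        out = channel_shuffle(F.concat_channels([left, right]), 2)
        if self.residual == "rm":
            out = out + self.shortcut_proj(F.max_pool2d(x, 3, 2, 1))
        elif self.residual == "ra":
            out = out + self.shortcut_proj(F.avg_pool2d(x, 3, 2, 1))
        elif self.residual == "rc":
            out = out + self.shortcut_proj(x)
        return out


# ---------------------------------------------------------------------------
# stems (all: 3 channels -> 24 channels, overall stride 4)
# ---------------------------------------------------------------------------

STEM_CHANNELS = 24


class _StemBase(nn.Module):
    def _check(self, x: Tensor) -> None:
        h, w = x.data.shape[2:]
        if h % 4 or w % 4:
            raise ValueError("stem input spatial size must be divisible by 4")


class StemA(_StemBase):
    """3x3 conv stride 2 + 3x3 max pool stride 2 (stock shuffle-net stem)."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = conv_bn_relu(3, STEM_CHANNELS, 3, stride=2, padding=1, rng=rng)

    def forward(self, x):
        self._check(x)
        return F.max_pool2d(self.conv(x), 3, 2, 1)


class StemB(_StemBase):
    """7x7 conv stride 2 + 3x3 max pool stride 2 (ResNet-style stem)."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = conv_bn_relu(3, STEM_CHANNELS, 7, stride=2, padding=3, rng=rng)

    def forward(self, x):
        self._check(x)
        return F.max_pool2d(self.conv(x), 3, 2, 1)


class StemC(_StemBase):
    """Three stacked 3x3 convs (first stride 2) + 3x3 max pool stride 2
    (Inception-ResNet-style factorized 7x7)."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.convs = nn.Sequential(
            conv_bn_relu(3, STEM_CHANNELS // 2, 3, stride=2, padding=1, rng=rng),
            conv_bn_relu(STEM_CHANNELS // 2, STEM_CHANNELS // 2, 3, padding=1, rng=rng),
            conv_bn_relu(STEM_CHANNELS // 2, STEM_CHANNELS, 3, padding=1, rng=rng),
        )

    def forward(self, x):
        self._check(x)
        return F.max_pool2d(self.convs(x), 3, 2, 1)


class MSFEM(_StemBase):
    """Multi-scale shallow feature extraction: a shared 3x3 stride-2 conv
    feeds a max-pool branch and a stacked-conv branch; the branches are
    concatenated and fused by a 1x1 conv to the stem width."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        c = STEM_CHANNELS
        self.shared = conv_bn_relu(3, c, 3, stride=2, padding=1, rng=rng)
        self.branch_conv = nn.Sequential(
            conv_bn_relu(c, c, 3, padding=1, rng=rng),
            conv_bn_relu(c, c, 3, stride=2, padding=1, relu=False, rng=rng),
        )
        self.fuse = conv_bn_relu(2 * c, c, 1, rng=rng)

    def forward(self, x):
        self._check(x)
        s = self.shared(x)
        pooled = F.max_pool2d(s, 3, 2, 1)
        conved = self.branch_conv(s)
        return self.fuse(F.concat_channels([pooled, conved]))


def build_stem(kind: str, rng: np.random.Generator) -> nn.Module:
    """Construct a stem by kind; every stem maps (N,3,H,W) -> (N,24,H/4,W/4)."""
    table = {"a": StemA, "b": StemB, "c": StemC, "msfem": MSFEM}
    if kind not in table:
        raise ValueError(f"unknown stem kind {kind!r}")
    return table[kind](rng)


class MDFEM(nn.Module):
    """Multi-scale deep feature extraction: parallel 3x3 and 5x5 branches
    (half-width each) concatenated and fused back to the input width by a
    1x1 conv; shape preserving."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        half = channels // 2
        self.b3 = conv_bn_relu(channels, half, 3, padding=1, rng=rng)
        self.b5 = conv_bn_relu(channels, half, 5, padding=2, rng=rng)
        self.fuse = conv_bn_relu(2 * half, channels, 1, rng=rng)

    def forward(self, x):
        return self.fuse(F.concat_channels([self.b3(x), self.b5(x)]))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class RemShuffleNet(nn.Module):
    """stem -> 3 stages (down unit + basic units) -> optional MDFEM ->
    final 1x1 conv -> global average pool -> linear classifier."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem = build_stem(cfg.stem, rng)
        in_c = STEM_CHANNELS
        res_basic = cfg.residual != "none"
        for i, (reps, out_c) in enumerate(
                zip(cfg.stage.repeats, cfg.stage.out_channels[:3]), start=2):
            units = [DownUnit(in_c, out_c, cfg.attention, cfg.residual, rng)]
            units += [BasicUnit(out_c, cfg.attention, res_basic, rng)
                      for _ in range(reps)]
            setattr(self, f"stage{i}", nn.Sequential(*units))
            in_c = out_c
        self.mdfem = MDFEM(in_c, rng) if cfg.use_mdfem else None
        self.final_conv = conv_bn_relu(in_c, cfg.stage.out_channels[3], 1, rng=rng)
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(cfg.stage.out_channels[3], cfg.num_classes, rng=rng)

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        x = self.stem(x)
        x = self.stage2(x)
        x = self.stage3(x)
        x = self.stage4(x)
        if self.mdfem is not None:
            x = self.mdfem(x)
        return self.head(self.pool(self.final_conv(x)))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class predictions in eval mode, batched."""
        was_training = self.training
        self.eval()
        preds = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(Tensor(x[i:i + batch_size])).data
            preds.append(logits.argmax(axis=1))
        if was_training:
            self.train()
        return np.concatenate(preds)


def build_model(cfg: ModelConfig, seed: int = 0) -> RemShuffleNet:
    """Build a model with reproducible (seeded) initialization."""
    return RemShuffleNet(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterReport:
    total_params: int
    fp32_bytes: int
    per_component: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def count_parameters(model: nn.Module) -> ParameterReport:
    """Exact trainable-parameter count with a per-top-level-child breakdown."""
    per: dict[str, int] = {}
    total = 0
    for name, p in model.named_parameters():
        comp = name.split(".", 1)[0]
        n = int(p.data.size)
        per[comp] = per.get(comp, 0) + n
        total += n
    return ParameterReport(total_params=total, fp32_bytes=4 * total,
                           per_component=per)


def parameter_manifest(model: nn.Module) -> list[dict]:
    """(name, shape) listing of every trainable parameter, for export."""
    return [{"name": n, "shape": list(p.data.shape)}
            for n, p in model.named_parameters()]
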