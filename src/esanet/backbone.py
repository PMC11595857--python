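"""Network assembly: depthwise-separable primitives, residual blocks, the
ESA-ResNet34 classifier, and reference builders for the comparison models.

ESA-ResNet34 is a ResNet-34 in which every 3×3 convolution inside the
residual blocks is replaced by a depthwise 3×3 convolution (which carries the
block's stride and leaves the channel count unchanged) followed by a 1×1
pointwise convolution (which mixes channels). The 7×7 stem and the 1×1
downsample projections on the skip paths are left as standard convolutions.
An ESA channel gate is inserted per :class:`~esanet.attention.EsaConfig`
placement, and a Dropout layer sits between global average pooling and the
classifier head.

The replacement is a drop-in swap: each former 3×3 convolution becomes the
depthwise/pointwise pair and keeps the single batch-norm that followed the
original convolution (``separable_norm="post_pointwise"``, the calibrated
default). A MobileNet-style variant with an extra norm + ReLU between the
two convolutions is available as ``separable_norm="dual"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import EffectiveSpatialAttention, EsaConfig

SEPARABLE_NORMS = ("post_pointwise", "dual")

REFERENCE_MODELS = ("alexnet", "vgg16", "densenet121", "resnet18", "resnet34",
                    "resnet50", "resnet101", "resnet152", "mobilenet")


# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    """Shape contract of a single convolution."""

    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    padding: int = 0
    groups: int = 1

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.kernel,
               self.stride, self.groups) < 1 or self.padding < 0:
            raise ValueError(f"invalid convolution spec: {self}")
        if self.in_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} does not divide in_channels={self.in_channels}")

    @property
    def is_depthwise(self) -> bool:
        return (self.groups == self.in_channels
                and self.out_channels == self.in_channels)

    @property
    def is_pointwise(self) -> bool:
        return self.kernel == 1 and self.groups == 1


@dataclass
class ArchitectureSpec:
    """Declarative description of the classifier.

    With ``use_esa=False, use_depthwise=False, dropout_rate=0.0`` this spec
    denotes a standard ResNet-34.
    """

    stage_block_counts: tuple[int, int, int, int] = (3, 4, 6, 3)
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    num_classes: int = 61
    use_esa: bool = True
    use_depthwise: bool = True
    dropout_rate: float = 0.5
    esa: EsaConfig = field(default_factory=EsaConfig)
    separable_norm: str = "post_pointwise"

    def validate(self) -> None:
        if len(self.stage_block_counts) != 4 or len(self.stage_widths) != 4:
            raise ValueError("exactly four stages are required")
        if any(n < 1 for n in self.stage_block_counts):
            raise ValueError("stage block counts must all be >= 1 "
                             f"(got {self.stage_block_counts})")
        w = self.stage_widths
        if any(w[i + 1] != 2 * w[i] for i in range(3)):
            raise ValueError("stage widths must be strictly increasing and "
                             f"doubling (got {w})")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.separable_norm not in SEPARABLE_NORMS:
            raise ValueError(f"separable_norm must be one of {SEPARABLE_NORMS}, "
                             f"got {self.separable_norm!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_block_counts"] = list(self.stage_block_counts)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        if "esa" in d and isinstance(d["esa"], dict):
            d["esa"] = EsaConfig(**d["esa"])
        for key in ("stage_block_counts", "stage_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Functional separable-convolution primitives
# ---------------------------------------------------------------------------


def depthwise_conv2d(x: np.ndarray, kernels: np.ndarray, stride: int = 1,
                     padding: int = 0, bias: np.ndarray | None = None) -> np.ndarray:
    """Depthwise convolution: one k×k filter per input channel.

    ``kernels`` has shape ``(C, k, k)``; output channel ``c`` depends only on
    input channel ``c``, and the channel count is preserved.
    """
    x = np.asarray(x, dtype=np.float32)
    kernels = np.asarray(kernels, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"expected N×C×H×W input, got shape {x.shape}")
    if kernels.ndim != 3 or kernels.shape[0] != x.shape[1]:
        raise ValueError(
            f"need one filter per input channel: {x.shape[1]} channels but "
            f"kernels of shape {kernels.shape}")
    if kernels.shape[1] != kernels.shape[2] or kernels.shape[1] % 2 == 0:
        raise ValueError("depthwise kernels must be square with odd extent")
    c, k = kernels.shape[0], kernels.shape[1]
    conv = nn.Conv2d(c, c, k, stride=stride, padding=padding, groups=c,
                     bias=bias is not None)
    conv.weight.value = kernels.reshape(c, 1, k, k)
    if bias is not None:
        conv.bias.value = np.asarray(bias, dtype=np.float32)
    return conv(x)


def pointwise_conv2d(x: np.ndarray, kernels: np.ndarray,
                     bias: np.ndarray | None = None) -> np.ndarray:
    """Pointwise (1×1) convolution mixing channels at each pixel.

    ``kernels`` is the mixing matrix, shape ``(C_out, C_in)`` or
    ``(C_out, C_in, 1, 1)``.
    """
    x = np.asarray(x, dtype=np.float32)
    kernels = np.asarray(kernels, dtype=np.float32)
    if kernels.ndim == 4:
        if kernels.shape[2:] != (1, 1):
            raise ValueError("pointwise filters must be 1×1 over space")
        kernels = kernels[:, :, 0, 0]
    if kernels.ndim != 2 or kernels.shape[1] != x.shape[1]:
        raise ValueError(
            f"mixing matrix of shape {kernels.shape} does not match "
            f"{x.shape[1]} input channels")
    cout, cin = kernels.shape
    conv = nn.Conv2d(cin, cout, 1, bias=bias is not None)
    conv.weight.value = kernels.reshape(cout, cin, 1, 1)
    if bias is not None:
        conv.bias.value = np.asarray(bias, dtype=np.float32)
    return conv(x)


def _separable(in_ch: int, out_ch: int, stride: int, norm: str) -> list[nn.Module]:
    """The depthwise(3×3, strided) → pointwise(1×1) pair replacing one 3×3 conv."""
    mods: list[nn.Module] = [
        nn.Conv2d(in_ch, in_ch, 3, stride=stride, padding=1, groups=in_ch)]
    if norm == "dual":
        mods += [nn.BatchNorm2d(in_ch), nn.ReLU()]
    mods.append(nn.Conv2d(in_ch, out_ch, 1))
    return mods


def _conv3x3(in_ch: int, out_ch: int, stride: int,
             depthwise: bool, norm: str) -> list[nn.Module]:
    if depthwise:
        return _separable(in_ch, out_ch, stride, norm)
    return [nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1)]


# ---------------------------------------------------------------------------
# Residual blocks
# ---------------------------------------------------------------------------


class Residual(nn.Module):
    """``relu(branch(x) + downsample(x))`` with explicit backward."""

    def __init__(self, branch: nn.Sequential,
                 downsample: nn.Sequential | None = None):
        super().__init__()
        self.branch = branch
        self.downsample = downsample
        self.relu = nn.ReLU()

    def forward(self, x):
        b = self.branch(x)
        s = self.downsample(x) if self.downsample is not None else x
        return self.relu(b + s)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        dx = self.branch.backward(dy)
        if self.downsample is not None:
            dx = dx + self.downsample.backward(dy)
        else:
            dx = dx + dy
        return dx

    def out_shape(self, in_shape):
        return self.branch.out_shape(in_shape)

    def profile_rows(self, in_shape, prefix=""):
        rows, out = self.branch.profile_rows(in_shape, prefix + "branch.")
        if self.downsample is not None:
            r, _ = self.downsample.profile_rows(in_shape, prefix + "downsample.")
            rows += r
        return rows, out


def make_ds_block(in_ch: int, out_ch: int, stride: int,
                  spec: ArchitectureSpec) -> Residual:
    """One basic residual block, with the spec's separable/ESA surgery applied.

    Both 3×3 convolutions of the block body are replaced by depthwise +
    pointwise pairs when ``spec.use_depthwise`` (the depthwise convolution
    carries the stride); the 1×1 skip projection is retained unchanged. When
    ``spec.use_esa`` and the placement is per-block, the gate acts on the
    branch output just before the skip addition.
    """
    if stride not in (1, 2):
        raise ValueError(f"stride must be 1 or 2, got {stride}")
    mods: list[nn.Module] = []
    mods += _conv3x3(in_ch, out_ch, stride, spec.use_depthwise, spec.separable_norm)
    mods += [nn.BatchNorm2d(out_ch), nn.ReLU()]
    mods += _conv3x3(out_ch, out_ch, 1, spec.use_depthwise, spec.separable_norm)
    mods += [nn.BatchNorm2d(out_ch)]
    if spec.use_esa and spec.esa.placement == "per_block_pre_add":
        mods.append(EffectiveSpatialAttention(spec.esa))
    downsample = None
    if stride != 1 or in_ch != out_ch:
        downsample = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 1, stride=stride),
            nn.BatchNorm2d(out_ch))
    return Residual(nn.Sequential(*mods), downsample)


# ---------------------------------------------------------------------------
# The classifier
# ---------------------------------------------------------------------------


class Classifier(nn.Sequential):
    """A sequential image classifier that remembers its architecture spec."""

    def __init__(self, *modules, spec: ArchitectureSpec | None = None,
                 name: str = ""):
        super().__init__(*modules)
        object.__setattr__(self, "spec", spec)
        object.__setattr__(self, "name", name)


def build_esa_resnet34(spec: ArchitectureSpec) -> Classifier:
    """Assemble the classifier described by ``spec``.

    Layout: 7×7 stride-2 stem convolution → BN → ReLU → 3×3 stride-2 max
    pool → four residual stages → global average pooling → Dropout →
    linear head. With all enhancement flags off and ``dropout_rate=0`` the
    result is a standard ResNet-34.
    """
    spec.validate()
    mods: list[nn.Module] = [
        nn.Conv2d(3, spec.stage_widths[0], 7, stride=2, padding=3),
        nn.BatchNorm2d(spec.stage_widths[0]),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, 1),
    ]
    in_ch = spec.stage_widths[0]
    for si, (count, width) in enumerate(zip(spec.stage_block_counts,
                                            spec.stage_widths)):
        for b in range(count):
            stride = 2 if (si > 0 and b == 0) else 1
            mods.append(make_ds_block(in_ch, width, stride, spec))
            in_ch = width
        if spec.use_esa and spec.esa.placement == "per_stage_exit":
            mods.append(EffectiveSpatialAttention(spec.esa))
    mods.append(nn.GlobalAvgPool())
    if spec.dropout_rate > 0:
        mods.append(nn.Dropout(spec.dropout_rate))
    mods.append(nn.Linear(in_ch, spec.num_classes))
    return Classifier(*mods, spec=spec, name="esa_resnet34")


# ---------------------------------------------------------------------------
# Reference architectures (standard published layouts, resizable heads)
# ---------------------------------------------------------------------------


def _basic_block(in_ch, out_ch, stride):
    branch = nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1),
        nn.BatchNorm2d(out_ch), nn.ReLU(),
        nn.Conv2d(out_ch, out_ch, 3, padding=1),
        nn.BatchNorm2d(out_ch))
    down = None
    if stride != 1 or in_ch != out_ch:
        down = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride),
                             nn.BatchNorm2d(out_ch))
    return Residual(branch, down)


def _bottleneck(in_ch, width, stride):
    out_ch = width * 4
    branch = nn.Sequential(
        nn.Conv2d(in_ch, width, 1), nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, padding=1),
        nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, out_ch, 1), nn.BatchNorm2d(out_ch))
    down = None
    if stride != 1 or in_ch != out_ch:
        down = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride),
                             nn.BatchNorm2d(out_ch))
    return Residual(branch, down)


_RESNET_CFG = {
    "resnet18": ([2, 2, 2, 2], "basic"),
    "resnet34": ([3, 4, 6, 3], "basic"),
    "resnet50": ([3, 4, 6, 3], "bottleneck"),
    "resnet101": ([3, 4, 23, 3], "bottleneck"),
    "resnet152": ([3, 8, 36, 3], "bottleneck"),
}


def _resnet(name: str, num_classes: int) -> Classifier:
    blocks, kind = _RESNET_CFG[name]
    widths = [64, 128, 256, 512]
    mods: list[nn.Module] = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3), nn.BatchNorm2d(64),
        nn.ReLU(), nn.MaxPool2d(3, 2, 1)]
    in_ch = 64
    for si, (count, width) in enumerate(zip(blocks, widths)):
        for b in range(count):
            stride = 2 if (si > 0 and b == 0) else 1
            if kind == "basic":
                mods.append(_basic_block(in_ch, width, stride))
                in_ch = width
            else:
                mods.append(_bottleneck(in_ch, width, stride))
                in_ch = width * 4
    mods += [nn.GlobalAvgPool(), nn.Linear(in_ch, num_classes)]
    return Classifier(*mods, name=name)


def _vgg16(num_classes: int) -> Classifier:
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]
    mods: list[nn.Module] = []
    in_ch = 3
    for v in cfg:
        if v == "M":
            mods.append(nn.MaxPool2d(2, 2))
        else:
            mods += [nn.Conv2d(in_ch, v, 3, padding=1, bias=True), nn.ReLU()]
            in_ch = v
    mods += [nn.AdaptiveAvgPool2d(7), nn.Flatten(),
             nn.Linear(512 * 7 * 7, 4096), nn.ReLU(), nn.Dropout(0.5),
             nn.Linear(4096, 4096), nn.ReLU(), nn.Dropout(0.5),
             nn.Linear(4096, num_classes)]
    return Classifier(*mods, name="vgg16")


def _alexnet(num_classes: int) -> Classifier:
    mods = [
        nn.Conv2d(3, 64, 11, stride=4, padding=2, bias=True), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(64, 192, 5, padding=2, bias=True), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(192, 384, 3, padding=1, bias=True), nn.ReLU(),
        nn.Conv2d(384, 256, 3, padding=1, bias=True), nn.ReLU(),
        nn.Conv2d(256, 256, 3, padding=1, bias=True), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.AdaptiveAvgPool2d(6), nn.Flatten(),
        nn.Dropout(0.5), nn.Linear(256 * 6 * 6, 4096), nn.ReLU(),
        nn.Dropout(0.5), nn.Linear(4096, 4096), nn.ReLU(),
        nn.Linear(4096, num_classes)]
    return Classifier(*mods, name="alexnet")


class _DenseLayer(nn.Module):
    """BN→ReLU→1×1→BN→ReLU→3×3, output concatenated onto the input."""

    def __init__(self, in_ch: int, growth: int = 32, bn_size: int = 4):
        super().__init__()
        self.body = nn.Sequential(
            nn.BatchNorm2d(in_ch), nn.ReLU(),
            nn.Conv2d(in_ch, bn_size * growth, 1),
            nn.BatchNorm2d(bn_size * growth), nn.ReLU(),
            nn.Conv2d(bn_size * growth, growth, 3, padding=1))
        self.in_ch, self.growth = in_ch, growth

    def forward(self, x):
        return np.concatenate([x, self.body(x)], axis=1)

    def backward(self, dy):
        dx = dy[:, :self.in_ch]
        return dx + self.body.backward(dy[:, self.in_ch:])

    def out_shape(self, in_shape):
        n, c, h, w = in_shape
        return (n, c + self.growth, h, w)

    def profile_rows(self, in_shape, prefix=""):
        rows, _ = self.body.profile_rows(in_shape, prefix + "body.")
        return rows, self.out_shape(in_shape)


def _densenet121(num_classes: int) -> Classifier:
    growth = 32
    mods: list[nn.Module] = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3), nn.BatchNorm2d(64),
        nn.ReLU(), nn.MaxPool2d(3, 2, 1)]
    ch = 64
    for bi, n_layers in enumerate([6, 12, 24, 16]):
        for _ in range(n_layers):
            mods.append(_DenseLayer(ch, growth))
            ch += growth
        if bi < 3:  # transition
            mods += [nn.BatchNorm2d(ch), nn.ReLU(),
                     nn.Conv2d(ch, ch // 2, 1), nn.AvgPool2d(2)]
            ch //= 2
    mods += [nn.BatchNorm2d(ch), nn.ReLU(), nn.GlobalAvgPool(),
             nn.Linear(ch, num_classes)]
    return Classifier(*mods, name="densenet121")


def _mobilenet_v2(num_classes: int) -> Classifier:
    def cbr(cin, cout, k, stride, groups=1):
        return [nn.Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
                          groups=groups),
                nn.BatchNorm2d(cout), nn.ReLU(max_value=6.0)]

    mods: list[nn.Module] = cbr(3, 32, 3, 2)
    cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
           (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    in_ch = 32
    for t, c, n, s in cfg:
        for i in range(n):
            stride = s if i == 0 else 1
            hidden = in_ch * t
            body: list[nn.Module] = []
            if t != 1:
                body += cbr(in_ch, hidden, 1, 1)
            body += cbr(hidden, hidden, 3, stride, groups=hidden)
            body += [nn.Conv2d(hidden, c, 1), nn.BatchNorm2d(c)]
            if stride == 1 and in_ch == c:
                mods.append(_InvertedResidual(nn.Sequential(*body)))
            else:
                mods += body
            in_ch = c
    mods += cbr(320, 1280, 1, 1)
    mods += [nn.GlobalAvgPool(), nn.Dropout(0.2), nn.Linear(1280, num_classes)]
    return Classifier(*mods, name="mobilenet")


class _InvertedResidual(nn.Module):
    """Identity-skip inverted residual (no final activation)."""

    def __init__(self, body: nn.Sequential):
        super().__init__()
        self.body = body

    def forward(self, x):
        return x + self.body(x)

    def backward(self, dy):
        return dy + self.body.backward(dy)

    def out_shape(self, in_shape):
        return in_shape

    def profile_rows(self, in_shape, prefix=""):
        return self.body.profile_rows(in_shape, prefix + "body.")


_BUILDERS = {
    "alexnet": _alexnet,
    "vgg16": _vgg16,
    "densenet121": _densenet121,
    "mobilenet": _mobilenet_v2,
    **{name: (lambda nc, _n=name: _resnet(_n, nc)) for name in _RESNET_CFG},
}


def build_reference_model(name: str, num_classes: int = 61) -> Classifier:
    """Build one of the standard comparison architectures.

    The published layouts are reproduced exactly (parameter totals equal the
    canonical 1000-class counts when ``num_classes=1000``) with the final
    classification layer resized to ``num_classes``.
    """
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(sorted(_BUILDERS))}")
    if num_classes < 2:
        raise ValueError(f"num_classes must be >= 2, got {num_classes}")
    return _BUILDERS[name](num_classes)


# ---------------------------------------------------------------------------
# Structural comparison
# ---------------------------------------------------------------------------


def layer_signature(model: nn.Module) -> list[tuple[str, tuple[int, ...]]]:
    """Ordered ``(kind, weight-shape)`` list of all learnable tensors.

    Two models are weight-for-weight isomorphic iff their signatures match.
    """
    sig = []
    for name, p in model.named_parameters():
        kind = name.rsplit(".", 1)[-1]
        sig.append((kind, tuple(p.value.shape)))
    return sig
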