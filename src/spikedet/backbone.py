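"""ShuffleNetV2-style feature extractor with two attention insertion points.

The backbone has a stem (3x3 stride-2 convolution + 2x2 max pool) and three
shuffle stages, named after their role in the detector: *foundation*
(stem + first stage), *transition* (second stage) and *output* (third
stage).  Attention can be inserted at two points — after the foundation
stage ("base", suffix 1) and after the output stage (suffix 2) — without
altering the shapes of the two feature taps the detection head consumes:
the stride-16 transition tap and the stride-32 output tap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionConfig, build_attention
from .nn import (
    Tensor, Module, Sequential, Conv2d, BatchNorm2d, ReLU,
    mac_counter, no_grad,
)

__all__ = [
    "BackboneConfig", "BackboneOutput", "ShuffleV2Backbone", "build_backbone",
    "channel_shuffle", "count_parameters", "count_flops",
]


@dataclass
class BackboneConfig:
    stem_channels: int = 24
    stage_channels: tuple = (48, 96, 192)
    stage_repeats: tuple = (4, 8, 4)
    attention_base: AttentionConfig = field(default_factory=AttentionConfig)
    attention_output: AttentionConfig = field(default_factory=AttentionConfig)
    input_size: int = 352
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_channels) != 3 or len(self.stage_repeats) != 3:
            raise ValueError("stage_channels and stage_repeats must each have 3 entries")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


@dataclass
class BackboneOutput:
    """The two feature taps fed to the detection head."""

    mid: Tensor   # stride-16 (transition stage)
    deep: Tensor  # stride-32 (output stage)


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """ShuffleNetV2 channel permutation (zero parameters, invertible)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError("channels must be divisible by groups")
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


def _conv_bn_relu(cin, cout, k, stride, rng, groups=1) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
               groups=groups, bias=False, rng=rng),
        BatchNorm2d(cout), ReLU())


def _conv_bn(cin, cout, k, stride, rng, groups=1) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
               groups=groups, bias=False, rng=rng),
        BatchNorm2d(cout))


class ShuffleUnit(Module):
    """Basic unit: channel split, right-branch 1x1 -> dw3x3 -> 1x1, shuffle."""

    def __init__(self, channels: int, rng):
        super().__init__()
        if channels % 2:
            raise ValueError("shuffle unit needs an even channel count")
        half = channels // 2
        self.half = half
        self.branch = Sequential(
            _conv_bn_relu(half, half, 1, 1, rng),
            _conv_bn(half, half, 3, 1, rng, groups=half),
            _conv_bn_relu(half, half, 1, 1, rng))

    def forward(self, x: Tensor) -> Tensor:
        left = x[:, :self.half]
        right = x[:, self.half:]
        out = Tensor.concat([left, self.branch(right)], axis=1)
        return channel_shuffle(out, 2)


class ShuffleDownUnit(Module):
    """Stride-2 unit: both branches downsample, concatenation doubles width."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        half = cout // 2
        self.left = Sequential(
            _conv_bn(cin, cin, 3, 2, rng, groups=cin),
            _conv_bn_relu(cin, half, 1, 1, rng))
        self.right = Sequential(
            _conv_bn_relu(cin, half, 1, 1, rng),
            _conv_bn(half, half, 3, 2, rng, groups=half),
            _conv_bn_relu(half, half, 1, 1, rng))

    def forward(self, x: Tensor) -> Tensor:
        out = Tensor.concat([self.left(x), self.right(x)], axis=1)
        return channel_shuffle(out, 2)


class ShuffleV2Backbone(Module):
    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = _conv_bn_relu(3, cfg.stem_channels, 3, 2, rng)
        cin = cfg.stem_channels
        stages = []
        for cout, reps in zip(cfg.stage_channels, cfg.stage_repeats):
            units = [ShuffleDownUnit(cin, cout, rng)]
            units += [ShuffleUnit(cout, rng) for _ in range(reps - 1)]
            stages.append(Sequential(*units))
            cin = cout
        self.stage1, self.stage2, self.stage3 = stages
        self.att_base = build_attention(cfg.stage_channels[0], cfg.attention_base, rng=rng)
        self.att_output = build_attention(cfg.stage_channels[2], cfg.attention_output, rng=rng)

    @property
    def tap_channels(self) -> tuple:
        return self.cfg.stage_channels[1], self.cfg.stage_channels[2]

    def forward(self, image: Tensor) -> BackboneOutput:
        n, c, h, w = image.shape
        if c != 3:
            raise ValueError("backbone expects 3-channel input")
        if h != w:
            raise ValueError("backbone expects square input")
        if h != self.cfg.input_size:
            raise ValueError(
                f"input spatial size {h} != configured input_size {self.cfg.input_size}")
        x = self.stem(image)          # stride 2
        x = x.maxpool2x2()            # stride 4
        x = self.stage1(x)            # stride 8 — foundation
        x = self.att_base(x)
        mid = self.stage2(x)          # stride 16 — transition tap
        deep = self.stage3(mid)       # stride 32
        deep = self.att_output(deep)  # output tap (post-attention)
        return BackboneOutput(mid=mid, deep=deep)


def build_backbone(cfg: BackboneConfig) -> ShuffleV2Backbone:
    return ShuffleV2Backbone(cfg)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars in a model."""
    return model.num_parameters()


def count_flops(model, *inputs) -> int:
    """Multiply-accumulate count of one forward pass.

    Runs the model on the given input tensors with a global MAC counter
    armed; every convolution/matmul op reports its products.  Returns MACs
    (multiply GFLOPs conventions by 2 if additions are counted separately).
    """
    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    mac_counter.reset()
    mac_counter.active = True
    try:
        with no_grad():
            model(*inputs)
    finally:
        mac_counter.active = False
        if hasattr(model, "train") and was_training:
            model.train(True)
    return mac_counter.total
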