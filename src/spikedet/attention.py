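"""Channel/spatial attention operators for the detector backbone.

Three shape-preserving feature-map transforms are provided, each a
multiplicative gating of its input:

* **ECA** (efficient channel attention): global average pooling followed by
  a 1-D convolution across the channel axis whose kernel size adapts to the
  channel count, then a sigmoid gate per channel.
* **LSKA** (large separable kernel attention): a large depthwise kernel
  decomposed into cascaded horizontal/vertical 1-D depthwise convolutions
  (a short dense pair plus a dilated pair), closed by a 1x1 channel-mixing
  convolution; the result gates the input element-wise.
* **EMA** (efficient multi-scale attention): channels are folded into
  grouped batch entries; a 1x1 branch encodes directional channel attention
  from height- and width-wise pooling, a 3x3 branch captures local context,
  and cross-branch pooled descriptors are softmax-normalised and combined
  by matrix products into a spatial gate.

All operators preserve the (batch, channels, height, width) shape and map
the all-zeros input to the all-zeros output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Conv2d, GroupNorm

__all__ = [
    "AttentionConfig", "eca_kernel_size", "build_attention",
    "ECAAttention", "LSKAAttention", "EMAAttention",
    "eca_forward", "lska_forward", "ema_forward",
]

_KINDS = ("NONE", "ECA", "LSKA", "EMA")


@dataclass
class AttentionConfig:
    """Hyperparameters of one attention insertion point.

    ``kind`` selects the operator (``NONE`` disables the insertion).
    ``eca_gamma``/``eca_b`` parameterise the adaptive 1-D kernel-size rule;
    ``lska_kernel`` is the effective large-kernel size (odd), realised with
    dilation ``lska_dilation``; ``ema_groups`` is the channel-group count.
    """

    kind: str = "NONE"
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    lska_kernel: int = 23
    lska_dilation: int = 3
    ema_groups: int = 8

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}; expected one of {_KINDS}")
        if self.lska_kernel % 2 == 0 or self.lska_kernel < 3:
            raise ValueError("lska_kernel must be odd and >= 3")
        if self.ema_groups < 1:
            raise ValueError("ema_groups must be >= 1")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "eca_gamma": self.eca_gamma, "eca_b": self.eca_b,
                "lska_kernel": self.lska_kernel, "lska_dilation": self.lska_dilation,
                "ema_groups": self.ema_groups}

    @classmethod
    def from_dict(cls, d) -> "AttentionConfig":
        if d is None:
            return cls()
        if isinstance(d, str):
            return cls(kind=d)
        return cls(**d)


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size: nearest odd of |log2(C) + b| / gamma.

    Monotone nondecreasing in ``channels`` and always odd (>= 1).
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = int(math.floor(abs((math.log2(channels) + b) / gamma)))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


class ECAAttention(Module):
    """Channel gate: GAP -> 1-D conv over channels -> sigmoid -> scale."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig(kind="ECA")
        self.channels = channels
        self.kernel_size = eca_kernel_size(channels, cfg.eca_gamma, cfg.eca_b)
        # 1-D conv realised as a 2-D conv over a (N,1,1,C) layout
        self.conv = Conv2d(1, 1, (1, self.kernel_size),
                           padding=(0, (self.kernel_size - 1) // 2),
                           bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = x.mean(axis=(2, 3))                       # (N, C) pooled descriptor
        y = self.conv(y.reshape(n, 1, 1, c))          # local cross-channel interaction
        w_ch = y.sigmoid().reshape(n, c, 1, 1)
        return x * w_ch


def _same_pad(k: int, d: int = 1) -> int:
    return ((k - 1) * d) // 2


class LSKAAttention(Module):
    """Separable large-kernel gate.

    The effective k x k depthwise kernel is decomposed into a dense
    (2d-1)-tap horizontal+vertical pair followed by a dilation-d pair of
    m taps, with (2d-1) + (m-1)*d = k, then a 1x1 mixing convolution.
    For the default k=23, d=3 this is 1x5, 5x1, dilated 1x7, 7x1.
    """

    def __init__(self, channels: int, cfg: AttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig(kind="LSKA")
        k, d = cfg.lska_kernel, cfg.lska_dilation
        if k % 2 == 0:
            raise ValueError("lska_kernel must be odd")
        self.channels, self.kernel, self.dilation = channels, k, d
        k0 = 2 * d - 1
        m = max(1, math.ceil((k - k0) / d) + 1)
        self.conv0h = Conv2d(channels, channels, (1, k0), padding=(0, _same_pad(k0)),
                             groups=channels, bias=False, rng=rng)
        self.conv0v = Conv2d(channels, channels, (k0, 1), padding=(_same_pad(k0), 0),
                             groups=channels, bias=False, rng=rng)
        self.convdh = Conv2d(channels, channels, (1, m), padding=(0, _same_pad(m, d)),
                             dilation=(1, d), groups=channels, bias=False, rng=rng)
        self.convdv = Conv2d(channels, channels, (m, 1), padding=(_same_pad(m, d), 0),
                             dilation=(d, 1), groups=channels, bias=False, rng=rng)
        self.conv1 = Conv2d(channels, channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        attn = self.conv0h(x)
        attn = self.conv0v(attn)
        attn = self.convdh(attn)
        attn = self.convdv(attn)
        attn = self.conv1(attn)
        return x * attn


class EMAAttention(Module):
    """Grouped cross-spatial attention with parallel 1x1 and 3x3 routes."""

    def __init__(self, channels: int, cfg: AttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AttentionConfig(kind="EMA")
        g = cfg.ema_groups
        if channels % g:
            raise ValueError(f"channels ({channels}) not divisible by ema_groups ({g})")
        self.channels, self.groups = channels, g
        cg = channels // g
        self.gn = GroupNorm(cg, cg)
        self.conv1x1 = Conv2d(cg, cg, 1, rng=rng)
        self.conv3x3 = Conv2d(cg, cg, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g, cg = self.groups, c // self.groups
        xg = x.reshape(n * g, cg, h, w)

        # 1x1 route: directional (H- and W-wise) pooled descriptors
        ph = xg.mean(axis=3, keepdims=True)                       # (ng, cg, H, 1)
        pw = xg.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (ng, cg, W, 1)
        hw = self.conv1x1(Tensor.concat([ph, pw], axis=2))
        xh = hw[:, :, :h, :]
        xw = hw[:, :, h:, :].transpose(0, 1, 3, 2)
        x1 = self.gn(xg * xh.sigmoid() * xw.sigmoid())

        # 3x3 route: local multi-scale context
        x2 = self.conv3x3(xg)

        # cross-route aggregation: pooled softmax descriptors x flattened maps
        d1 = x1.mean(axis=(2, 3)).reshape(n * g, 1, cg).softmax(axis=2)
        d2 = x2.mean(axis=(2, 3)).reshape(n * g, 1, cg).softmax(axis=2)
        f1 = x2.reshape(n * g, cg, h * w)
        f2 = x1.reshape(n * g, cg, h * w)
        weights = (d1 @ f1 + d2 @ f2).reshape(n * g, 1, h, w)
        return (xg * weights.sigmoid()).reshape(n, c, h, w)


def build_attention(channels: int, cfg: AttentionConfig,
                    rng: np.random.Generator | None = None) -> Module:
    """Instantiate the operator named by ``cfg.kind`` (Identity for NONE)."""
    from .nn import Identity

    if cfg.kind == "NONE":
        return Identity()
    if cfg.kind == "ECA":
        return ECAAttention(channels, cfg, rng=rng)
    if cfg.kind == "LSKA":
        return LSKAAttention(channels, cfg, rng=rng)
    if cfg.kind == "EMA":
        return EMAAttention(channels, cfg, rng=rng)
    raise ValueError(f"unknown attention kind {cfg.kind!r}")


def _ensure4d(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if t.ndim != 4:
        raise ValueError("feature map must be rank-4 (batch, channels, height, width)")
    return t


def eca_forward(x, cfg: AttentionConfig | None = None,
                module: ECAAttention | None = None) -> Tensor:
    """Functional ECA on a feature map (builds a fresh module if none given)."""
    x = _ensure4d(x)
    mod = module or ECAAttention(x.shape[1], cfg or AttentionConfig(kind="ECA"))
    return mod(x)


def lska_forward(x, cfg: AttentionConfig | None = None,
                 module: LSKAAttention | None = None) -> Tensor:
    x = _ensure4d(x)
    mod = module or LSKAAttention(x.shape[1], cfg or AttentionConfig(kind="LSKA"))
    return mod(x)


def ema_forward(x, cfg: AttentionConfig | None = None,
                module: EMAAttention | None = None) -> Tensor:
    x = _ensure4d(x)
    mod = module or EMAAttention(x.shape[1], cfg or AttentionConfig(kind="EMA"))
    return mod(x)
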