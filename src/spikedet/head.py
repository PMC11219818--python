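"""Two-scale lightweight detection head and anchor-based decode.

The head consumes the backbone's stride-16 and stride-32 taps.  The deep
tap is processed at stride 32 and also upsampled (nearest, x2) and fused
with the mid tap at stride 16.  Each scale runs a 1x1 + depthwise stack
into three branches: box regression (4 channels per anchor), objectness
(1 per anchor) and class scores — the class branch is a single module
shared by both scales (parameter sharing by identity).

``fpn_kind="simlight"`` swaps every plain convolution block in the fusion
path for :class:`SimConv`, a conv+BN+ReLU block that supports exact
inference-time folding of the batch norm into the convolution weights
(``y = ReLU(BN(x*w))`` becomes ``y = ReLU(x*w')`` with algebraically
folded ``w'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DetectionBox
from .nn import Tensor, Module, Sequential, Conv2d, BatchNorm2d

__all__ = [
    "HeadConfig", "RawPrediction", "SimConv", "ConvBNReLU", "fuse_conv_bn",
    "simconv_forward", "LightFPNHead", "build_head", "decode_predictions",
    "DEFAULT_ANCHORS",
]

# k-means presets over the synthetic generator's box distribution at the
# reference 352-px resolution; override via HeadConfig for other inputs.
DEFAULT_ANCHORS = (
    (38.0, 52.0), (52.0, 72.0), (70.0, 96.0),      # stride 16
    (92.0, 126.0), (120.0, 96.0), (156.0, 200.0),  # stride 32
)


@dataclass
class HeadConfig:
    fpn_kind: str = "light"
    head_channels: int = 96
    anchors_per_scale: int = 3
    anchor_sizes: tuple = DEFAULT_ANCHORS
    num_classes: int = 1
    seed: int = 1

    def __post_init__(self):
        if self.fpn_kind not in ("light", "simlight"):
            raise ValueError("fpn_kind must be 'light' or 'simlight'")
        if len(self.anchor_sizes) != 2 * self.anchors_per_scale:
            raise ValueError(
                f"anchor_sizes must list {2 * self.anchors_per_scale} (w,h) pairs "
                f"(2 scales x {self.anchors_per_scale}), got {len(self.anchor_sizes)}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    def anchors_for_scale(self, scale_idx: int) -> np.ndarray:
        a = self.anchors_per_scale
        return np.asarray(self.anchor_sizes[scale_idx * a:(scale_idx + 1) * a],
                          dtype=np.float32)


@dataclass
class RawPrediction:
    """Per-scale raw head outputs (logit space), shallow scale first."""

    box: tuple      # (stride16, stride32) tensors, 4*A channels
    obj: tuple      # A channels
    cls: tuple      # num_classes channels (shared branch)
    strides: tuple = (16, 32)


class ConvBNReLU(Module):
    """Plain convolution block: conv -> BN -> ReLU (no fused path)."""

    def __init__(self, cin, cout, k=1, stride=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


def fuse_conv_bn(weight: np.ndarray, bias: np.ndarray | None,
                 gamma: np.ndarray, beta: np.ndarray,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 eps: float = 1e-5) -> tuple:
    """Fold inference-mode batch norm into convolution weights.

    ``w' = w * gamma / sqrt(var + eps)``;
    ``b' = beta + (b - mean) * gamma / sqrt(var + eps)``.
    Exact in real arithmetic.
    """
    denom = running_var + eps
    if np.any(denom <= 0):
        raise FloatingPointError("running_var + eps must be positive")
    scale = gamma / np.sqrt(denom)
    w = weight * scale.reshape(-1, 1, 1, 1)
    b0 = bias if bias is not None else np.zeros_like(running_mean)
    b = beta + (b0 - running_mean) * scale
    return w.astype(weight.dtype), b.astype(weight.dtype)


class SimConv(Module):
    """Conv + BN + ReLU with an exact BN-folded inference path.

    Training/unfused mode evaluates ``ReLU(BN(conv(x)))``; after
    :meth:`fuse`, the folded path evaluates ``ReLU(conv'(x))`` with the BN
    absorbed into the kernel and bias.
    """

    def __init__(self, cin, cout, k=1, stride=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.fused = False
        self._fused_w = None
        self._fused_b = None

    def fuse(self):
        """Fold the BN statistics into the convolution (inference only)."""
        w, b = fuse_conv_bn(self.conv.weight.data, None,
                            self.bn.gamma.data, self.bn.beta.data,
                            self.bn.running_mean, self.bn.running_var,
                            self.bn.eps)
        self._fused_w, self._fused_b = Tensor(w), Tensor(b)
        self.fused = True
        return self

    def unfuse(self):
        self.fused = False
        self._fused_w = self._fused_b = None
        return self

    def forward(self, x: Tensor) -> Tensor:
        if self.fused:
            if self.training:
                raise RuntimeError("fused SimConv cannot run in training mode")
            y = x.conv2d(self._fused_w, self._fused_b, self.conv.stride,
                         self.conv.padding, self.conv.dilation, self.conv.groups)
            return y.relu()
        return self.bn(self.conv(x)).relu()

    def forward_fuse(self, x: Tensor) -> Tensor:
        if not self.fused:
            raise RuntimeError("call fuse() before forward_fuse()")
        return self.forward(x)


def simconv_forward(x, module: SimConv, fused: bool = False) -> Tensor:
    """Run one SimConv block in the requested mode (module must be in eval)."""
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if fused:
        if not module.fused:
            raise RuntimeError("fused forward requested before folding")
        return module.forward_fuse(x)
    was_fused = module.fused
    module.fused = False
    try:
        return module(x)
    finally:
        module.fused = was_fused


def _dw_block(block_cls, c, rng):
    """Depthwise 5x5 + pointwise 1x1 stack (the head's cost primitive)."""
    return Sequential(block_cls(c, c, 5, groups=c, rng=rng),
                      block_cls(c, c, 1, rng=rng))


class LightFPNHead(Module):
    def __init__(self, cfg: HeadConfig, in_channels: tuple = (96, 192)):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        block = SimConv if cfg.fpn_kind == "simlight" else ConvBNReLU
        c = cfg.head_channels
        cmid, cdeep = in_channels
        a, nc = cfg.anchors_per_scale, cfg.num_classes

        self.deep_in = block(cdeep, c, 1, rng=rng)
        self.mid_in = block(cmid + c, c, 1, rng=rng)  # mid tap ++ upsampled deep
        self.deep_feat = _dw_block(block, c, rng)
        self.mid_feat = _dw_block(block, c, rng)

        self.box_mid = Conv2d(c, 4 * a, 1, rng=rng)
        self.box_deep = Conv2d(c, 4 * a, 1, rng=rng)
        self.obj_mid = Conv2d(c, a, 1, rng=rng)
        self.obj_deep = Conv2d(c, a, 1, rng=rng)
        self.cls_shared = Conv2d(c, nc, 1, rng=rng)  # one storage, both scales

    def forward(self, mid: Tensor, deep: Tensor) -> RawPrediction:
        d = self.deep_in(deep)
        m = Tensor.concat([mid, d.upsample2x()], axis=1)
        m = self.mid_in(m)
        fm = self.mid_feat(m)
        fd = self.deep_feat(d)
        return RawPrediction(
            box=(self.box_mid(fm), self.box_deep(fd)),
            obj=(self.obj_mid(fm), self.obj_deep(fd)),
            cls=(self.cls_shared(fm), self.cls_shared(fd)),
        )

    def fuse(self):
        for m in self.modules():
            if isinstance(m, SimConv):
                m.fuse()
        return self


def build_head(cfg: HeadConfig, in_channels: tuple = (96, 192)) -> LightFPNHead:
    return LightFPNHead(cfg, in_channels)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def decode_predictions(raw: RawPrediction, cfg: HeadConfig,
                       conf_threshold: float = 0.25,
                       input_size: int | None = None) -> list:
    """Decode raw logit maps into scored pixel-space boxes.

    Per cell and anchor: ``center = (cell + 2*sigmoid(t_xy) - 0.5) * stride``,
    ``size = anchor * (2*sigmoid(t_wh))**2``,
    ``score = sigmoid(obj) * sigmoid(cls)``.  Boxes scoring below
    ``conf_threshold`` are dropped; survivors are clipped to image bounds.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in [0, 1]")
    a = cfg.anchors_per_scale
    out: list[DetectionBox] = []
    for si, stride in enumerate(raw.strides):
        box = raw.box[si].data if isinstance(raw.box[si], Tensor) else np.asarray(raw.box[si])
        obj = raw.obj[si].data if isinstance(raw.obj[si], Tensor) else np.asarray(raw.obj[si])
        cls = raw.cls[si].data if isinstance(raw.cls[si], Tensor) else np.asarray(raw.cls[si])
        n, _, gh, gw = box.shape
        if n != 1:
            raise ValueError("decode_predictions expects a single-image batch")
        bound = input_size if input_size is not None else stride * gh
        anchors = cfg.anchors_for_scale(si)

        box = box.reshape(a, 4, gh, gw)
        obj = obj.reshape(a, gh, gw)
        cls = cls.reshape(cfg.num_classes, gh, gw)

        gy, gx = np.mgrid[0:gh, 0:gw].astype(np.float32)
        for ai in range(a):
            tx, ty, tw, th = box[ai]
            cx = (gx + 2.0 * _sigmoid(tx) - 0.5) * stride
            cy = (gy + 2.0 * _sigmoid(ty) - 0.5) * stride
            bw = anchors[ai, 0] * (2.0 * _sigmoid(tw)) ** 2
            bh = anchors[ai, 1] * (2.0 * _sigmoid(th)) ** 2
            pobj = _sigmoid(obj[ai])
            for ci in range(cfg.num_classes):
                score = pobj * _sigmoid(cls[ci])
                keep = score >= conf_threshold
                ys, xs = np.nonzero(keep)
                for y, x in zip(ys, xs):
                    x0 = float(np.clip(cx[y, x] - bw[y, x] / 2, 0, bound))
                    x1 = float(np.clip(cx[y, x] + bw[y, x] / 2, 0, bound))
                    y0 = float(np.clip(cy[y, x] - bh[y, x] / 2, 0, bound))
                    y1 = float(np.clip(cy[y, x] + bh[y, x] / 2, 0, bound))
                    if x1 > x0 and y1 > y0:
                        out.append(DetectionBox(x0, y0, x1, y1,
                                                score=float(score[y, x]),
                                                class_id=ci))
    out.sort(key=lambda b: -b.score)
    return out
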