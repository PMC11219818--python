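"""Detector assembly and the model-variant naming grammar.

Variant names follow the family convention
``YOLO-FastestV2[-SimLightFPN][-ATT1 | -ATT2 | -ATTBASE-ATTOUT]``:

* a ``1`` suffix inserts the named attention operator after the backbone's
  foundation stage only, a ``2`` suffix after the output stage only;
* a two-token form (e.g. ``ECA-EMA``) places the first operator at the
  foundation stage and the second at the output stage;
* the ``SimLightFPN`` token selects the SimConv-based detection head.

``build_variant("YOLO-FastestV2-SimLightFPN-ECA-EMA")`` therefore yields
the hybrid with ECA at the base stage, EMA at the output stage and the
SimLightFPN head.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

import numpy as np

from .attention import AttentionConfig
from .backbone import (
    BackboneConfig, build_backbone, count_parameters, count_flops,
)
from .head import HeadConfig, RawPrediction, build_head, decode_predictions
from .metrics import nms
from .nn import Module, Tensor, no_grad

__all__ = [
    "Detector", "ModelVariant", "parse_variant_name", "build_variant",
    "canonical_name", "ALL_VARIANT_NAMES", "save_checkpoint", "load_checkpoint",
]

BASE_NAME = "YOLO-FastestV2"
_ATT = ("ECA", "LSKA", "EMA")

# the 14 variants of the published comparison, in table order
ALL_VARIANT_NAMES = (
    "YOLO-FastestV2",
    "YOLO-FastestV2-ECA1",
    "YOLO-FastestV2-ECA2",
    "YOLO-FastestV2-LSKA1",
    "YOLO-FastestV2-LSKA2",
    "YOLO-FastestV2-EMA1",
    "YOLO-FastestV2-EMA2",
    "YOLO-FastestV2-ECA-LSKA",
    "YOLO-FastestV2-ECA-EMA",
    "YOLO-FastestV2-LSKA-LSKA",
    "YOLO-FastestV2-LSKA-EMA",
    "YOLO-FastestV2-SimLightFPN",
    "YOLO-FastestV2-SimLightFPN-LSKA-EMA",
    "YOLO-FastestV2-SimLightFPN-ECA-EMA",
)


class VariantNameError(ValueError):
    pass


def parse_variant_name(name: str) -> dict:
    """Parse a variant name into (attention_base, attention_output, fpn_kind)."""
    if not name.startswith(BASE_NAME):
        raise VariantNameError(
            f"variant must start with {BASE_NAME!r}; got {name!r}")
    rest = name[len(BASE_NAME):]
    fpn_kind = "light"
    if rest.startswith("-SimLightFPN"):
        fpn_kind = "simlight"
        rest = rest[len("-SimLightFPN"):]
    base_att, out_att = "NONE", "NONE"
    if rest:
        tokens = rest.lstrip("-").split("-")
        if len(tokens) == 1:
            m = re.fullmatch(r"(ECA|LSKA|EMA)([12])", tokens[0])
            if not m:
                raise VariantNameError(
                    f"bad attention token {tokens[0]!r} in {name!r}; expected "
                    f"one of {_ATT} with stage suffix 1|2, or ATT-ATT")
            if m.group(2) == "1":
                base_att = m.group(1)
            else:
                out_att = m.group(1)
        elif len(tokens) == 2:
            for t in tokens:
                if t not in _ATT:
                    raise VariantNameError(
                        f"bad attention token {t!r} in {name!r}; valid: {_ATT}")
            base_att, out_att = tokens
        else:
            raise VariantNameError(
                f"cannot parse {name!r}: expected at most two attention tokens")
    return {"attention_base": base_att, "attention_output": out_att,
            "fpn_kind": fpn_kind}


def canonical_name(attention_base: str, attention_output: str,
                   fpn_kind: str) -> str:
    name = BASE_NAME
    if fpn_kind == "simlight":
        name += "-SimLightFPN"
    b, o = attention_base, attention_output
    if b != "NONE" and o != "NONE":
        name += f"-{b}-{o}"
    elif b != "NONE":
        name += f"-{b}1"
    elif o != "NONE":
        name += f"-{o}2"
    return name


class Detector(Module):
    """Backbone + head; the trainable end-to-end wheat-spike detector."""

    def __init__(self, backbone_cfg: BackboneConfig, head_cfg: HeadConfig):
        super().__init__()
        self.backbone_cfg = backbone_cfg
        self.head_cfg = head_cfg
        self.backbone = build_backbone(backbone_cfg)
        self.head = build_head(head_cfg, in_channels=self.backbone.tap_channels)

    @property
    def input_size(self) -> int:
        return self.backbone_cfg.input_size

    def forward(self, image: Tensor) -> RawPrediction:
        taps = self.backbone(image)
        return self.head(taps.mid, taps.deep)

    def predict(self, image: np.ndarray, conf_threshold: float = 0.25,
                nms_iou: float = 0.45) -> list:
        """Detect on one HWC uint8 (or [0,1] float) image; returns boxes."""
        x = np.asarray(image)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        x = x.transpose(2, 0, 1)[None]
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                raw = self.forward(Tensor(x))
        finally:
            if was_training:
                self.train(True)
        boxes = decode_predictions(raw, self.head_cfg, conf_threshold,
                                   input_size=self.input_size)
        return nms(boxes, nms_iou)

    def count_parameters(self) -> int:
        return count_parameters(self)

    def count_macs(self, input_size: int | None = None) -> int:
        size = input_size or self.input_size
        if size != self.input_size:
            raise ValueError("Detector is built for a fixed input size")
        x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
        return count_flops(self, x)


@dataclass
class ModelVariant:
    """A named, fully resolved detector configuration."""

    name: str
    backbone_cfg: BackboneConfig
    head_cfg: HeadConfig

    @property
    def canonical(self) -> str:
        return canonical_name(self.backbone_cfg.attention_base.kind,
                              self.backbone_cfg.attention_output.kind,
                              self.head_cfg.fpn_kind)

    def build(self) -> Detector:
        return Detector(self.backbone_cfg, self.head_cfg)


def build_variant(name: str,
                  backbone_cfg: BackboneConfig | None = None,
                  head_cfg: HeadConfig | None = None,
                  attention_overrides: dict | None = None) -> ModelVariant:
    """Resolve a variant name into a concrete configuration.

    ``backbone_cfg``/``head_cfg`` supply the family-wide settings (input
    size, widths, anchors); the name decides attention placement and head
    kind.  ``attention_overrides`` may carry non-default attention
    hyperparameters keyed ``base``/``output``.
    """
    parsed = parse_variant_name(name)
    bcfg = backbone_cfg or BackboneConfig()
    hcfg = head_cfg or HeadConfig()
    over = attention_overrides or {}

    def att(kind: str, key: str) -> AttentionConfig:
        base = over.get(key)
        if base is not None:
            return replace(base, kind=kind)
        return AttentionConfig(kind=kind)

    bcfg = replace(bcfg,
                   attention_base=att(parsed["attention_base"], "base"),
                   attention_output=att(parsed["attention_output"], "output"))
    hcfg = replace(hcfg, fpn_kind=parsed["fpn_kind"])
    return ModelVariant(name=name, backbone_cfg=bcfg, head_cfg=hcfg)


# -- checkpointing --------------------------------------------------------

def save_checkpoint(path, detector: Detector, extra: dict | None = None):
    """Serialize weights + configs to an .npz container."""
    meta = {
        "backbone_cfg": _cfg_to_jsonable(detector.backbone_cfg),
        "head_cfg": _cfg_to_jsonable(detector.head_cfg),
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v for k, v in detector.state_dict().items()}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        sd = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    bcfg = _backbone_cfg_from_jsonable(meta["backbone_cfg"])
    hcfg = _head_cfg_from_jsonable(meta["head_cfg"])
    det = Detector(bcfg, hcfg)
    det.load_state_dict(sd)
    return det


def _cfg_to_jsonable(cfg) -> dict:
    from dataclasses import asdict
    d = asdict(cfg)

    def conv(v):
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        if isinstance(v, list):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in d.items()}


def _backbone_cfg_from_jsonable(d: dict) -> BackboneConfig:
    d = dict(d)
    d["attention_base"] = AttentionConfig(**d["attention_base"])
    d["attention_output"] = AttentionConfig(**d["attention_output"])
    d["stage_channels"] = tuple(d["stage_channels"])
    d["stage_repeats"] = tuple(d["stage_repeats"])
    return BackboneConfig(**d)


def _head_cfg_from_jsonable(d: dict) -> HeadConfig:
    d = dict(d)
    d["anchor_sizes"] = tuple(tuple(a) for a in d["anchor_sizes"])
    return HeadConfig(**d)
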