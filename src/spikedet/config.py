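"""Serializable experiment configuration (YAML round-trip).

An :class:`ExperimentConfig` fully determines a model graph: loading a
saved config rebuilds the identical architecture with the identical
parameter count (weights come from checkpoints, not configs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .attention import AttentionConfig
from .backbone import BackboneConfig
from .head import HeadConfig
from .train import TrainConfig

__all__ = ["EvalConfig", "ExperimentConfig"]


@dataclass
class EvalConfig:
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    decode_threshold: float = 0.05
    iou_grid_start: float = 0.5
    iou_grid_stop: float = 0.95
    iou_grid_step: float = 0.05


@dataclass
class ExperimentConfig:
    variant: str = "YOLO-FastestV2"
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    trainer: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    dataset_dir: str = ""
    output_dir: str = ""

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        # attention blocks live under explicit keys in the backbone section
        d["backbone"]["attention"] = {
            "base": d["backbone"].pop("attention_base"),
            "output": d["backbone"].pop("attention_output"),
        }
        text = yaml.safe_dump(_tuples_to_lists(d), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = Path(source).read_text() if isinstance(source, (str, Path)) \
            and "\n" not in str(source) else str(source)
        d = yaml.safe_load(text)
        b = dict(d.get("backbone", {}))
        att = b.pop("attention", {})
        b["attention_base"] = AttentionConfig.from_dict(att.get("base"))
        b["attention_output"] = AttentionConfig.from_dict(att.get("output"))
        b["stage_channels"] = tuple(b.get("stage_channels", (48, 96, 192)))
        b["stage_repeats"] = tuple(b.get("stage_repeats", (4, 8, 4)))
        h = dict(d.get("head", {}))
        if "anchor_sizes" in h:
            h["anchor_sizes"] = tuple(tuple(a) for a in h["anchor_sizes"])
        return cls(
            variant=d.get("variant", "YOLO-FastestV2"),
            backbone=BackboneConfig(**b),
            head=HeadConfig(**h),
            trainer=TrainConfig(**d.get("trainer", {})),
            eval=EvalConfig(**d.get("eval", {})),
            dataset_dir=d.get("dataset_dir", ""),
            output_dir=d.get("output_dir", ""),
        )


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_tuples_to_lists(v) for v in obj]
    return obj
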