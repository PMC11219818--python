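"""Variant grammar, target assignment, loss behaviour, CLI and config I/O."""

import numpy as np
import pytest

import spikedet as sd
from spikedet.backbone import BackboneConfig
from spikedet.cli import main as cli_main
from spikedet.config import ExperimentConfig
from spikedet.head import HeadConfig
from spikedet.metrics import GroundTruthBox
from spikedet.nn import Tensor
from spikedet.train import (
    TrainConfig, assign_targets, kmeans_anchors, training_loss,
)
from spikedet.variants import (
    ALL_VARIANT_NAMES, VariantNameError, build_variant, parse_variant_name,
)


class TestVariantGrammar:
    def test_baseline_has_no_attention(self):
        p = parse_variant_name("YOLO-FastestV2")
        assert p == {"attention_base": "NONE", "attention_output": "NONE",
                     "fpn_kind": "light"}

    def test_stage_suffix_one_targets_base(self):
        p = parse_variant_name("YOLO-FastestV2-ECA1")
        assert p["attention_base"] == "ECA"
        assert p["attention_output"] == "NONE"

    def test_stage_suffix_two_targets_output(self):
        p = parse_variant_name("YOLO-FastestV2-EMA2")
        assert p["attention_base"] == "NONE"
        assert p["attention_output"] == "EMA"

    def test_two_token_form(self):
        p = parse_variant_name("YOLO-FastestV2-LSKA-EMA")
        assert p["attention_base"] == "LSKA"
        assert p["attention_output"] == "EMA"

    def test_simlightfpn_token(self):
        p = parse_variant_name("YOLO-FastestV2-SimLightFPN-ECA-EMA")
        assert p["fpn_kind"] == "simlight"
        assert p["attention_base"] == "ECA"

    @pytest.mark.parametrize("bad", [
        "YOLOv5", "YOLO-FastestV2-FOO1", "YOLO-FastestV2-ECA3",
        "YOLO-FastestV2-ECA-EMA-LSKA",
    ])
    def test_invalid_names_rejected_with_guidance(self, bad):
        with pytest.raises(VariantNameError):
            parse_variant_name(bad)

    def test_all_fourteen_names_round_trip(self):
        for name in ALL_VARIANT_NAMES:
            assert build_variant(name).canonical == name


class TestTargetAssignment:
    def _cfg(self):
        return HeadConfig(anchors_per_scale=1, anchor_sizes=((32, 32), (64, 64)),
                          seed=0)

    def test_anchor_sized_box_is_positive_with_neighbours(self):
        cfg = self._cfg()
        gt = GroundTruthBox(24, 24, 56, 56)  # 32x32 box centered at (40, 40)
        t16, t32 = assign_targets([[gt]], cfg, 128)
        # exact anchor match at stride 16: containing cell + 2 neighbours
        assert len(t16.img) == 3
        assert (2, 2) in set(zip(t16.gx, t16.gy))
        # stride-32 anchor 64x64: ratio 0.5 within the gate -> also positive
        assert len(t32.img) == 3

    def test_ratio_gate_excludes_oversized_boxes(self):
        cfg = HeadConfig(anchors_per_scale=1, anchor_sizes=((8, 8), (12, 12)),
                         seed=0)
        gt = GroundTruthBox(0, 0, 120, 120)  # 10x the larger anchor
        t16, t32 = assign_targets([[gt]], cfg, 128)
        assert len(t16.img) == 0 and len(t32.img) == 0
        # a 4:1 width ratio sits exactly on the gate and is excluded too
        gt2 = GroundTruthBox(32, 32, 80, 80)  # 48px: ratio 4 vs 12px anchor
        _, t32b = assign_targets([[gt2]], cfg, 128)
        assert len(t32b.img) == 0

    def test_assigned_cell_contains_center_within_one_stride(self, rng):
        cfg = self._cfg()
        for _ in range(50):
            cx, cy = rng.uniform(20, 108, 2)
            w, h = rng.uniform(24, 48, 2)
            gt = GroundTruthBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            for tgt, stride in zip(assign_targets([[gt]], cfg, 128), (16, 32)):
                for gx, gy in zip(tgt.gx, tgt.gy):
                    assert abs((gx + 0.5) * stride - cx) <= 1.5 * stride
                    assert abs((gy + 0.5) * stride - cy) <= 1.5 * stride


class TestTrainingLoss:
    def _setup(self, rng, fill=None):
        cfg = HeadConfig(anchors_per_scale=1, anchor_sizes=((32, 32), (64, 64)),
                         seed=0)
        shapes = {"box": [(1, 4, 8, 8), (1, 4, 4, 4)],
                  "obj": [(1, 1, 8, 8), (1, 1, 4, 4)],
                  "cls": [(1, 1, 8, 8), (1, 1, 4, 4)]}
        def t(s):
            if fill is None:
                return Tensor(rng.normal(size=s).astype(np.float32),
                              requires_grad=True)
            return Tensor(np.full(s, fill, np.float32), requires_grad=True)
        raw = sd.RawPrediction(box=tuple(t(s) for s in shapes["box"]),
                               obj=tuple(t(s) for s in shapes["obj"]),
                               cls=tuple(t(s) for s in shapes["cls"]))
        gt = GroundTruthBox(24, 24, 56, 56)
        targets = assign_targets([[gt]], cfg, 128)
        return raw, targets, cfg

    def test_components_nonnegative_on_random_batches(self, rng):
        raw, targets, cfg = self._setup(rng)
        loss = training_loss(raw, targets, cfg, 128)
        assert loss.box >= 0 and loss.obj >= 0 and loss.cls >= 0
        assert float(loss.total.data) >= 0

    def test_box_weight_scales_box_component_linearly(self, rng):
        raw, targets, cfg = self._setup(rng)
        l1 = training_loss(raw, targets, cfg, 128, TrainConfig(box_weight=0.05))
        l2 = training_loss(raw, targets, cfg, 128, TrainConfig(box_weight=0.10))
        contrib1 = float(l1.total.data) - (1.0 * l1.obj + 0.5 * l1.cls)
        contrib2 = float(l2.total.data) - (1.0 * l2.obj + 0.5 * l2.cls)
        assert contrib2 == pytest.approx(2 * contrib1, rel=1e-4)

    def test_no_positives_leaves_objectness_only(self, rng):
        cfg = HeadConfig(anchors_per_scale=1, anchor_sizes=((32, 32), (64, 64)),
                        seed=0)
        raw, _, _ = self._setup(rng)
        targets = assign_targets([[]], cfg, 128)
        loss = training_loss(raw, targets, cfg, 128)
        assert loss.box == 0.0 and loss.cls == 0.0 and loss.obj > 0

    def test_loss_vanishes_when_predictions_sit_on_targets(self, rng):
        """Logits pushed toward the exact target geometry drive loss down."""
        raw, targets, cfg = self._setup(rng, fill=0.0)
        base = training_loss(raw, targets, cfg, 128)
        # gradient step on the raw maps should reduce the total loss
        base.total.backward()
        for group in (raw.box, raw.obj, raw.cls):
            for t in group:
                t.data -= 0.5 * t.grad
        after = training_loss(raw, targets, cfg, 128)
        assert float(after.total.data) < float(base.total.data)

    def test_gradients_flow_to_all_heads(self, rng):
        raw, targets, cfg = self._setup(rng)
        training_loss(raw, targets, cfg, 128).total.backward()
        for group in (raw.box, raw.obj, raw.cls):
            assert any(t.grad is not None and np.abs(t.grad).sum() > 0
                       for t in group)


class TestDetectorAssembly:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path, rng):
        v = build_variant("YOLO-FastestV2",
                          backbone_cfg=BackboneConfig(
                              stem_channels=8, stage_channels=(16, 32, 64),
                              stage_repeats=(2, 2, 2), input_size=96),
                          head_cfg=HeadConfig(head_channels=16, seed=0))
        det = v.build()
        img = rng.integers(0, 255, (96, 96, 3), dtype=np.uint8)
        before = det.predict(img, conf_threshold=0.0)
        sd.save_checkpoint(tmp_path / "ck.npz", det)
        det2 = sd.load_checkpoint(tmp_path / "ck.npz")
        after = det2.predict(img, conf_threshold=0.0)
        assert len(before) == len(after)
        for a, b in zip(before, after):
            assert a.score == pytest.approx(b.score, abs=1e-6)

    def test_config_reproduces_parameter_count(self):
        cfg = ExperimentConfig(variant="YOLO-FastestV2-ECA1")
        text = cfg.to_yaml()
        cfg2 = ExperimentConfig.from_yaml(text)
        v1 = build_variant(cfg.variant, cfg.backbone, cfg.head)
        v2 = build_variant(cfg2.variant, cfg2.backbone, cfg2.head)
        assert v1.build().count_parameters() == v2.build().count_parameters()


def test_kmeans_anchors_cover_box_distribution(rng):
    gts = [[GroundTruthBox(0, 0, w, h)]
           for w, h in rng.uniform(10, 60, size=(80, 2))]
    anchors = kmeans_anchors(gts, 4, seed=0)
    assert anchors.shape == (4, 2)
    areas = anchors.prod(axis=1)
    assert (np.diff(areas) >= 0).all()
    assert anchors.min() >= 10 * 0.5 and anchors.max() <= 60 * 1.5


class TestCli:
    def test_rank_prints_fourteen_rows(self, capsys):
        assert cli_main(["rank"]) == 0
        out = capsys.readouterr().out
        assert out.count("YOLO-FastestV2") == 14
        assert "Rank" in out and "GPI" in out

    def test_info_reports_counts(self, capsys):
        assert cli_main(["info", "YOLO-FastestV2", "--input-size", "96"]) == 0
        out = capsys.readouterr().out
        assert "parameters" in out and "MACs" in out

    def test_unknown_variant_fails_cleanly(self):
        assert cli_main(["info", "YOLO-FastestV2-XYZ1"]) == 1

    def test_unknown_subcommand_exits_2(self):
        assert cli_main(["frobnicate"]) == 2

    def test_generate_writes_dataset(self, tmp_path, capsys):
        rc = cli_main(["generate", str(tmp_path / "ds"), "--n-images", "3",
                       "--image-size", "96", "--easy", "--seed", "5"])
        assert rc == 0
        assert (tmp_path / "ds" / "manifest.json").exists()
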