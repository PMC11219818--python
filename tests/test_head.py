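"""Detection head: SimConv BN folding, FPN shapes, shared class branch, decode."""

import numpy as np
import pytest

from spikedet.head import (
    HeadConfig, RawPrediction, SimConv, build_head, decode_predictions,
    fuse_conv_bn, simconv_forward,
)
from spikedet.nn import Tensor, no_grad


def _random_simconv(rng, cin=6, cout=8, k=3):
    m = SimConv(cin, cout, k, rng=rng)
    m.bn.gamma.data[:] = rng.uniform(0.5, 1.5, cout)
    m.bn.beta.data[:] = rng.normal(0, 0.3, cout)
    m.bn.running_mean[:] = rng.normal(0, 0.5, cout)
    m.bn.running_var[:] = rng.uniform(0.3, 2.0, cout)
    return m.eval()


class TestSimConvFusion:
    def test_identity_bn_keeps_weights(self, rng):
        m = SimConv(4, 4, 1, rng=rng).eval()
        m.bn.eps = 0.0
        m.fuse()
        assert np.allclose(m._fused_w.data, m.conv.weight.data)
        assert np.allclose(m._fused_b.data, 0.0)

    def test_fused_equals_unfused(self, rng):
        m = _random_simconv(rng)
        x = Tensor(rng.normal(size=(2, 6, 7, 7)).astype(np.float32))
        with no_grad():
            y_plain = simconv_forward(x, m, fused=False)
            m.fuse()
            y_fused = simconv_forward(x, m, fused=True)
        assert np.abs(y_plain.data - y_fused.data).max() < 1e-5

    def test_zero_gamma_gives_constant_relu_beta(self, rng):
        m = SimConv(3, 3, 1, rng=rng).eval()
        m.bn.gamma.data[:] = 0.0
        m.bn.beta.data[:] = np.array([-1.0, 0.5, 2.0])
        x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
        with no_grad():
            y = m(x)
        expect = np.maximum(m.bn.beta.data, 0.0).reshape(1, 3, 1, 1)
        assert np.allclose(y.data, np.broadcast_to(expect, y.shape), atol=1e-6)

    def test_fused_forward_requires_folding(self, rng):
        m = SimConv(3, 3, 1, rng=rng).eval()
        with pytest.raises(RuntimeError):
            simconv_forward(Tensor(np.zeros((1, 3, 2, 2), np.float32)), m,
                            fused=True)

    def test_fused_training_mode_is_an_error(self, rng):
        m = _random_simconv(rng).fuse()
        m.train(True)
        with pytest.raises(RuntimeError):
            m(Tensor(np.zeros((1, 6, 4, 4), np.float32)))


class TestFuseConvBn:
    def test_algebraic_cancellation_gives_zero_bias(self, rng):
        w = rng.normal(size=(4, 2, 1, 1)).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        _, b2 = fuse_conv_bn(w, b, gamma=np.ones(4, np.float32),
                             beta=np.zeros(4, np.float32),
                             running_mean=b, running_var=np.ones(4, np.float32),
                             eps=0.0)
        assert np.allclose(b2, 0.0, atol=1e-7)

    def test_folding_matches_sequential_path_on_random_inputs(self, rng):
        w = rng.normal(size=(5, 3, 3, 3))
        gamma = rng.uniform(0.5, 2, 5)
        beta = rng.normal(size=5)
        mean = rng.normal(size=5)
        var = rng.uniform(0.2, 3, 5)
        wf, bf = fuse_conv_bn(w, None, gamma, beta, mean, var, eps=1e-5)
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 3, 6, 6)))
            seq = (Tensor(x.data).conv2d(Tensor(w), None, padding=1).data
                   - mean.reshape(1, 5, 1, 1)) / np.sqrt(
                       var.reshape(1, 5, 1, 1) + 1e-5)
            seq = seq * gamma.reshape(1, 5, 1, 1) + beta.reshape(1, 5, 1, 1)
            fused = x.conv2d(Tensor(wf), Tensor(bf), padding=1).data
            assert np.abs(seq - fused).max() < 1e-5

    def test_negative_variance_is_an_error(self):
        with pytest.raises(FloatingPointError):
            fuse_conv_bn(np.ones((1, 1, 1, 1), np.float32), None,
                         np.ones(1), np.zeros(1), np.zeros(1),
                         np.array([-1.0]), eps=0.0)


class TestHeadStructure:
    @pytest.mark.parametrize("kind", ["light", "simlight"])
    def test_output_shapes_follow_taps(self, kind, rng):
        cfg = HeadConfig(fpn_kind=kind, head_channels=24, seed=0)
        head = build_head(cfg, in_channels=(96, 192)).eval()
        mid = Tensor(rng.normal(size=(1, 96, 22, 22)).astype(np.float32))
        deep = Tensor(rng.normal(size=(1, 192, 11, 11)).astype(np.float32))
        with no_grad():
            raw = head(mid, deep)
        assert raw.box[0].shape == (1, 12, 22, 22)
        assert raw.box[1].shape == (1, 12, 11, 11)
        assert raw.obj[0].shape == (1, 3, 22, 22)
        assert raw.cls[0].shape == (1, 1, 22, 22)
        assert raw.cls[1].shape == (1, 1, 11, 11)

    def test_light_and_simlight_have_identical_shapes(self, rng):
        mid = Tensor(rng.normal(size=(1, 96, 12, 12)).astype(np.float32))
        deep = Tensor(rng.normal(size=(1, 192, 6, 6)).astype(np.float32))
        shapes = []
        for kind in ("light", "simlight"):
            head = build_head(HeadConfig(fpn_kind=kind, head_channels=24,
                                         seed=0), (96, 192)).eval()
            with no_grad():
                raw = head(mid, deep)
            shapes.append([t.shape for t in (*raw.box, *raw.obj, *raw.cls)])
        assert shapes[0] == shapes[1]

    def test_class_branch_parameters_are_shared_storage(self):
        head = build_head(HeadConfig(head_channels=24, seed=0), (96, 192))
        assert head.cls_shared.weight is not None
        # same module applied at both scales: exactly one class-conv storage
        cls_params = [p for name, p in head.named_parameters()
                      if name.startswith("cls_shared")]
        assert len({id(p) for p in cls_params}) == len(cls_params)
        # and the prediction at each scale reacts to the same weight
        w_id = id(head.cls_shared.weight)
        assert sum(1 for _, p in head.named_parameters() if id(p) == w_id) == 1

    def test_anchor_list_length_validation(self):
        with pytest.raises(ValueError):
            HeadConfig(anchor_sizes=((10, 10),) * 5)


def _raw_single_cell(cfg, fill=0.0):
    z16 = np.full((1, 4 * cfg.anchors_per_scale, 2, 2), fill, np.float32)
    z32 = np.full((1, 4 * cfg.anchors_per_scale, 1, 1), fill, np.float32)
    o16 = np.full((1, cfg.anchors_per_scale, 2, 2), fill, np.float32)
    o32 = np.full((1, cfg.anchors_per_scale, 1, 1), fill, np.float32)
    c16 = np.full((1, cfg.num_classes, 2, 2), fill, np.float32)
    c32 = np.full((1, cfg.num_classes, 1, 1), fill, np.float32)
    return RawPrediction(box=(Tensor(z16), Tensor(z32)),
                         obj=(Tensor(o16), Tensor(o32)),
                         cls=(Tensor(c16), Tensor(c32)))


class TestDecode:
    def setup_method(self):
        self.cfg = HeadConfig(anchors_per_scale=1,
                              anchor_sizes=((32, 32), (32, 32)), seed=0)

    def test_zero_logits_decode_to_cell_centers(self):
        raw = _raw_single_cell(self.cfg)
        boxes = decode_predictions(raw, self.cfg, conf_threshold=0.0,
                                   input_size=32)
        deep = [b for b in boxes if b.width == pytest.approx(32, abs=1e-3)]
        b = next(b for b in deep if b.center[0] == pytest.approx(16, abs=1e-3))
        # stride-32 cell (0,0): center (16,16), size (32,32), score 0.25
        assert b.center == (pytest.approx(16, abs=1e-3), pytest.approx(16, abs=1e-3))
        assert b.score == pytest.approx(0.25, abs=1e-6)

    def test_threshold_one_empties_output(self):
        raw = _raw_single_cell(self.cfg, fill=5.0)
        assert decode_predictions(raw, self.cfg, conf_threshold=1.0) == []

    def test_decode_is_monotone_in_threshold(self, rng):
        cfg = self.cfg
        raw = RawPrediction(
            box=(Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32)),
                 Tensor(rng.normal(size=(1, 4, 1, 1)).astype(np.float32))),
            obj=(Tensor(rng.normal(size=(1, 1, 2, 2)).astype(np.float32)),
                 Tensor(rng.normal(size=(1, 1, 1, 1)).astype(np.float32))),
            cls=(Tensor(rng.normal(size=(1, 1, 2, 2)).astype(np.float32)),
                 Tensor(rng.normal(size=(1, 1, 1, 1)).astype(np.float32))))
        sizes = [len(decode_predictions(raw, cfg, t, input_size=32))
                 for t in (0.0, 0.1, 0.2, 0.4, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_boxes_clipped_to_image(self, rng):
        raw = _raw_single_cell(self.cfg, fill=4.0)  # pushes boxes outward
        for b in decode_predictions(raw, self.cfg, 0.0, input_size=32):
            assert 0 <= b.x_min < b.x_max <= 32
            assert 0 <= b.y_min < b.y_max <= 32
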