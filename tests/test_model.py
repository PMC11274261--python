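"""Architecture contracts: pyramid shapes, fusion/attention behaviour,
ablation reduction and evaluation-mode determinism."""

import numpy as np
import pytest

from dmfnet.model import (HCAM, MFFM, BackboneConfig, DMFNet, ModelConfig,
                          build_backbone)
from dmfnet.nn.autograd import Tensor
from dmfnet.nn import autograd as ag


@pytest.fixture(scope="module")
def small_model():
    return DMFNet(ModelConfig(seed=3)).build_for_input(64).eval()


def _inputs(rng, n=2, size=64):
    return (rng.random((n, 9, size, size), dtype=np.float32),
            rng.random((n, 6, size, size), dtype=np.float32))


class TestBackbone:
    def test_pyramid_shapes_at_224(self):
        bb = build_backbone(BackboneConfig(in_channels=3)).eval()
        x = np.random.default_rng(0).random((1, 3, 224, 224), dtype=np.float32)
        pyr = bb(Tensor(x))
        assert [t.shape[1:] for t in pyr] == [(64, 56, 56), (128, 28, 28),
                                              (256, 14, 14), (512, 7, 7)]

    def test_trimmed_backbone_parameter_count(self):
        # closed-form layer-wise sum: stem 9408+128, stages 73984 + 230144
        # + 919040 + 3673088
        bb = build_backbone(BackboneConfig(in_channels=3))
        assert bb.num_params() == 4_905_792

    def test_nine_channel_stem_weight_count(self):
        bb = build_backbone(BackboneConfig(in_channels=9))
        assert bb.stem_conv.weight.data.size == 7 * 7 * 9 * 64

    def test_zero_input_finite_in_eval(self):
        bb = build_backbone(BackboneConfig(in_channels=3)).eval()
        pyr = bb(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        assert all(np.isfinite(t.data).all() for t in pyr)

    def test_paths_do_not_share_weights(self):
        m = DMFNet(ModelConfig(seed=0))
        assert not np.array_equal(m.fem1.stage1_0.conv1.weight.data,
                                  m.fem2.stage1_0.conv1.weight.data)


class TestMFFM:
    def _pyramid(self, rng, size=224):
        shapes = [(1, 64, size // 4, size // 4), (1, 128, size // 8, size // 8),
                  (1, 256, size // 16, size // 16), (1, 512, size // 32, size // 32)]
        return [Tensor(rng.random(s, dtype=np.float32), requires_grad=True)
                for s in shapes]

    def test_fused_shape_at_224(self, rng):
        out = MFFM()(self._pyramid(rng))
        assert out.shape == (1, 512, 14, 14)

    def test_gradient_reaches_every_scale(self, rng):
        pyr = self._pyramid(rng, size=64)
        out = MFFM()(pyr)
        ag.tsum(ag.mul(out, out)).backward()
        for t in pyr:
            assert t.grad is not None and np.abs(t.grad).max() > 0

    def test_deterministic(self, rng):
        pyr = self._pyramid(rng, size=64)
        m = MFFM()
        np.testing.assert_array_equal(m(pyr).data, m(pyr).data)


class TestHCAM:
    def test_output_shape_equals_input_shape(self, rng):
        x = Tensor(rng.random((2, 32, 6, 6), dtype=np.float32))
        assert HCAM(32)(x).shape == (2, 32, 6, 6)

    def test_attention_weights_strictly_in_unit_interval(self, rng):
        x = Tensor(rng.normal(size=(2, 16, 5, 5)).astype(np.float32))
        maps = HCAM(16).attention_maps(x)
        assert set(maps) == {"A_H", "A_W", "A_col", "A_row"}
        for arr in maps.values():
            assert (arr > 0).all() and (arr < 1).all()

    def test_deterministic(self, rng):
        x = Tensor(rng.random((1, 8, 4, 4), dtype=np.float32))
        h = HCAM(8)
        np.testing.assert_array_equal(h(x).data, h(x).data)


class TestHeadsAndForward:
    def test_constant_feature_map_gaps_to_constant(self):
        x = Tensor(np.full((1, 4, 3, 3), 0.7, dtype=np.float32))
        gap = ag.global_avg_pool(x)
        np.testing.assert_allclose(gap.data, 0.7, rtol=1e-6)

    def test_identity_projection_returns_gap_vector(self, rng):
        m = DMFNet(ModelConfig(seed=0, d_z=512, use_mffm=True, use_hcam=False)).eval()
        m.cpp.weight.data = np.eye(512, dtype=np.float32)
        m.cpp.bias.data = np.zeros(512, dtype=np.float32)
        x1, x2 = _inputs(rng, n=1, size=32)
        out = m.forward(x1, x2)
        np.testing.assert_allclose(out.z_cpp[0].data, out.f_gap[0].data, rtol=1e-5)

    @pytest.mark.parametrize("batch", [1, 3])
    def test_shape_pipeline(self, small_model, rng, batch):
        x1, x2 = _inputs(rng, n=batch)
        out = small_model.forward(x1, x2)
        assert out.p.shape == (batch,)
        assert ((out.p.data > 0) & (out.p.data < 1)).all()
        for z in (*out.z_cpp, *out.z_csp):
            assert z.shape == (batch, 128)
            assert np.isfinite(z.data).all()
        assert out.f_gap[0].shape == (batch, 512)

    def test_channel_count_mismatch_rejected(self, small_model, rng):
        x1, x2 = _inputs(rng)
        with pytest.raises(ValueError):
            small_model.forward(x2, x1)

    def test_eval_mode_bitwise_determinism(self, small_model, rng):
        x1, x2 = _inputs(rng)
        p1 = small_model.forward(x1, x2).p.data
        p2 = small_model.forward(x1, x2).p.data
        np.testing.assert_array_equal(p1, p2)


class TestAblationReduction:
    def test_baseline_has_no_fusion_or_attention_parameters(self):
        base = DMFNet(ModelConfig(use_mffm=False, use_hcam=False, seed=0))
        names = [n for n, _ in base.named_parameters()]
        assert not any("mffm" in n or "hcam" in n for n in names)
        full = DMFNet(ModelConfig(seed=0)).build_for_input(64)
        full_names = [n for n, _ in full.named_parameters()]
        assert any("mffm" in n for n in full_names)
        assert any("hcam" in n for n in full_names)

    def test_baseline_forward_works(self, rng):
        base = DMFNet(ModelConfig(use_mffm=False, use_hcam=False, seed=0)).eval()
        x1, x2 = _inputs(rng, n=1, size=32)
        out = base.forward(x1, x2)
        assert 0 < float(out.p.data[0]) < 1

    def test_state_dict_roundtrip(self, rng):
        m = DMFNet(ModelConfig(seed=5)).build_for_input(32).eval()
        x1, x2 = _inputs(rng, n=1, size=32)
        ref = m.forward(x1, x2).p.data.copy()
        state = m.state_dict()
        m2 = DMFNet(ModelConfig(seed=6)).build_for_input(32).eval()
        m2.load_state_dict(state)
        np.testing.assert_array_equal(m2.forward(x1, x2).p.data, ref)
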