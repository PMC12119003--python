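"""MECS attention: pooled statistics, gate bounds, wiring of the median branch."""

import numpy as np
import pytest

from lesiondet.mecs import MECS, MECSConfig, global_pool_stats
from lesiondet.nn import Tensor

from oracles import median_by_sort


def _rand(shape, seed=0):
    return Tensor(np.random.default_rng(seed).normal(size=shape).astype(np.float32))


class TestGlobalPoolStats:
    def test_constant_plane_collapses_all_three(self):
        x = Tensor(np.full((2, 3, 4, 4), 1.7, np.float32))
        for v in global_pool_stats(x):
            assert v.shape == (2, 3, 1, 1)
            assert np.allclose(v.data, 1.7)

    def test_two_by_two_plane(self):
        x = Tensor(np.array([1.0, 2.0, 3.0, 4.0], np.float32).reshape(1, 1, 2, 2))
        avg, mx, med = global_pool_stats(x)
        assert avg.data.item() == 2.5
        assert mx.data.item() == 4.0
        assert med.data.item() == 2.5  # even count: mean of the middle pair

    def test_median_matches_full_sort_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(2, 3, 5, 7)).astype(np.float32)
        _, _, med = global_pool_stats(Tensor(x))
        for b in range(2):
            for c in range(3):
                assert med.data[b, c, 0, 0] == pytest.approx(
                    median_by_sort(x[b, c]), abs=1e-6)


class TestChannelAttention:
    def test_constant_input_gives_equal_branches(self):
        m = MECS(MECSConfig(channels=8, reduction=2))
        x = Tensor(np.full((1, 8, 6, 6), 0.4, np.float32))
        gate = m.channel_attention(x)
        v = Tensor(np.full((1, 8, 1, 1), 0.4, np.float32))
        single = m.mlp(v).sigmoid()
        assert np.allclose(gate.data, 3 * single.data, atol=1e-6)

    def test_zeroed_mlp_output_layer_gives_three_halves(self, rng):
        m = MECS(MECSConfig(channels=8, reduction=2))
        m.mlp.m2.weight.data[:] = 0.0
        m.mlp.m2.bias.data[:] = 0.0
        gate = m.channel_attention(_rand((2, 8, 5, 5)))
        assert np.allclose(gate.data, 1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gate_strictly_inside_zero_three(self, seed):
        m = MECS(MECSConfig(channels=16, reduction=4),
                 rng=np.random.default_rng(seed + 100))
        gate = m.channel_attention(_rand((2, 16, 7, 7), seed)).data
        assert np.all(gate > 0.0) and np.all(gate < 3.0)

    def test_channel_mismatch_rejected(self):
        m = MECS(MECSConfig(channels=8, reduction=2))
        with pytest.raises(ValueError):
            m.channel_attention(_rand((1, 4, 3, 3)))

    def test_reduction_below_one_channel_rejected(self):
        with pytest.raises(ValueError):
            MECSConfig(channels=8, reduction=16)


class TestApplyAndSpatial:
    def test_apply_channel_identity_zero_and_scalar(self):
        x = _rand((1, 4, 3, 3))
        ones = Tensor(np.ones((1, 4, 1, 1), np.float32))
        assert np.allclose(MECS.apply_channel(x, ones).data, x.data)
        zero = Tensor(np.zeros_like(x.data))
        assert np.allclose(MECS.apply_channel(zero, ones).data, 0.0)
        assert MECS.apply_channel(Tensor(np.full((1, 1, 1, 1), 2.0)),
                                  Tensor(np.full((1, 1, 1, 1), 0.5))).data == 1.0

    def test_spatial_zero_input_zero_bias_gives_zero(self):
        m = MECS(MECSConfig(channels=8, reduction=2))
        out = m.spatial_attention(Tensor(np.zeros((1, 8, 6, 6), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_identity_kernels_give_n_plus_one_times_square(self):
        cfg = MECSConfig(channels=4, reduction=2)
        m = MECS(cfg)
        # base 5x5 depthwise -> centered delta
        m.base.weight.data[:] = 0.0
        m.base.weight.data[:, 0, 2, 2] = 1.0
        m.base.bias.data[:] = 0.0
        for br in m.branches:
            for conv in br:
                kh, kw = conv.kernel_size
                conv.weight.data[:] = 0.0
                conv.weight.data[:, 0, kh // 2, kw // 2] = 1.0
                conv.bias.data[:] = 0.0
        m.proj.weight.data[:] = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
        m.proj.bias.data[:] = 0.0
        x = _rand((1, 4, 6, 6), seed=3)
        n = len(cfg.spatial_branches)
        expected = (n + 1) * x.data * x.data
        assert np.allclose(m.spatial_attention(x).data, expected, atol=1e-5)


class TestForward:
    def test_zero_in_zero_out_and_shape(self):
        m = MECS(MECSConfig(channels=16, reduction=4))
        out = m(Tensor(np.zeros((1, 16, 10, 10), np.float32)))
        assert out.shape == (1, 16, 10, 10)
        assert np.allclose(out.data, 0.0)

    @pytest.mark.parametrize("shape", [(1, 128, 40, 40), (2, 8, 9, 13)])
    def test_shape_preserving(self, shape):
        m = MECS(MECSConfig(channels=shape[1], reduction=4))
        assert m(_rand(shape)).shape == shape

    def test_degraded_config_is_a_channel_gate_in_zero_two(self):
        """Without the median branch and spatial stage, MECS reduces to a
        CBAM-style two-branch gate bounded in (0, 2) -- distinguishing the
        median wiring structurally."""
        cfg = MECSConfig(channels=16, reduction=4, use_median=False, use_spatial=False)
        m = MECS(cfg, rng=np.random.default_rng(5))
        x = _rand((2, 16, 6, 6), seed=9)
        gate = m.channel_attention(x).data
        assert np.all(gate > 0.0) and np.all(gate < 2.0)
        full_gate = MECS(MECSConfig(channels=16, reduction=4),
                         rng=np.random.default_rng(5)).channel_attention(x).data
        assert np.all(full_gate > gate)  # the extra sigmoid branch is wired in
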