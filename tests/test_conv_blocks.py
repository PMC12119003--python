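"""GSConv stack: shuffle permutation algebra, shapes, budgets, closed-form checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesiondet import nn
from lesiondet.conv_blocks import (
    ConvBnAct,
    ConvSpec,
    GSBottleneck,
    GSC2f,
    GSConv,
    channel_shuffle,
    complexity_bounds,
)
from lesiondet.nn import Tensor
from lesiondet.profiler import profile_model


def _planes(c):
    """(1, c, 2, 2) tensor whose channel i is constant i."""
    return Tensor(np.arange(c, dtype=np.float32)[None, :, None, None]
                  * np.ones((1, c, 2, 2), dtype=np.float32))


class TestChannelShuffle:
    def test_four_channels_two_groups_order(self):
        out = channel_shuffle(_planes(4), 2)
        assert list(out.data[0, :, 0, 0]) == [0, 2, 1, 3]

    def test_single_group_is_identity(self):
        x = _planes(6)
        assert np.array_equal(channel_shuffle(x, 1).data, x.data)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError):
            channel_shuffle(_planes(6), 4)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.sampled_from([2, 4, 6, 8, 12, 16, 24]), st.data())
    def test_shuffle_then_complement_is_identity(self, c, data):
        divisors = [g for g in range(1, c + 1) if c % g == 0]
        g = data.draw(st.sampled_from(divisors))
        x = _planes(c)
        back = channel_shuffle(channel_shuffle(x, g), c // g)
        assert np.array_equal(back.data, x.data)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.sampled_from([2, 4, 6, 8, 12, 16]), st.data())
    def test_output_planes_are_a_permutation_of_input_planes(self, c, data):
        g = data.draw(st.sampled_from([d for d in range(1, c + 1) if c % d == 0]))
        rng = np.random.default_rng(c * 7 + g)
        x = Tensor(rng.normal(size=(1, c, 3, 3)).astype(np.float32))
        out = channel_shuffle(x, g)
        in_planes = {x.data[0, i].tobytes() for i in range(c)}
        out_planes = {out.data[0, i].tobytes() for i in range(c)}
        assert in_planes == out_planes


class TestGSConv:
    def test_output_shape_follows_stride(self):
        out = GSConv(3, 16, 3, 2)(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert out.shape == (1, 16, 32, 32)

    def test_odd_output_channels_rejected(self):
        with pytest.raises(ValueError):
            GSConv(3, 15)

    def test_parameter_count_no_norm_with_bias(self):
        # dense branch 16*9*8+8 plus depthwise branch 9*8+8; shuffle is free
        gs = GSConv(16, 16, 3, norm=False)
        assert gs.num_params() == (16 * 9 * 8 + 8) + (9 * 8 + 8)

    @pytest.mark.parametrize("c2", [2, 4, 16, 30])
    def test_output_channel_count_matches_spec(self, c2):
        out = GSConv(8, c2, 3)(Tensor(np.zeros((1, 8, 8, 8), np.float32)))
        assert out.shape[1] == c2

    def test_flops_below_standard_conv_same_width(self):
        class Wrap(nn.Module):
            def __init__(self, inner):
                super().__init__()
                self.inner = inner

            def forward(self, x):
                return self.inner(x)

        gs = profile_model(Wrap(GSConv(64, 64, 3)), (32, 32), in_channels=64).total_flops
        sc = profile_model(Wrap(ConvBnAct(64, 64, 3)), (32, 32), in_channels=64).total_flops
        assert gs < sc


class TestGSBottleneck:
    def test_channel_preserving(self):
        out = GSBottleneck(32)(Tensor(np.zeros((2, 32, 20, 20), np.float32)))
        assert out.shape == (2, 32, 20, 20)

    def test_zero_input_maps_to_zero_at_init(self):
        out = GSBottleneck(16)(Tensor(np.zeros((1, 16, 8, 8), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_params_decompose_into_two_gsconvs(self):
        blk = GSBottleneck(32)
        assert blk.num_params() == blk.gs1.num_params() + blk.gs2.num_params()

    def test_residual_addition_when_shapes_match(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
        blk = GSBottleneck(16)
        blk.eval()
        with_short = blk(x).data
        blk.shortcut = False
        without = blk(x).data
        assert np.allclose(with_short, without + x.data, atol=1e-5)


class TestGSC2f:
    def test_output_shape_contract(self):
        out = GSC2f(48, 64, n=2)(Tensor(np.zeros((2, 48, 10, 10), np.float32)))
        assert out.shape == (2, 64, 10, 10)

    def test_depth_delta_decomposes_into_bottleneck_plus_wider_projection(self):
        # each extra stage adds one bottleneck and one more c-wide slab to
        # the final 1x1 projection's input
        p1 = GSC2f(64, 64, n=1).num_params()
        p2 = GSC2f(64, 64, n=2).num_params()
        cv2_growth = ConvBnAct(4 * 32, 64, 1).num_params() - ConvBnAct(3 * 32, 64, 1).num_params()
        assert p2 - p1 == GSBottleneck(32).num_params() + cv2_growth

    @pytest.mark.parametrize("c", [32, 64])
    def test_params_strictly_monotonic_in_depth(self, c):
        counts = [GSC2f(c, c, n=n).num_params() for n in (1, 2, 3)]
        assert counts[0] < counts[1] < counts[2]

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            GSC2f(32, 32, n=0)


class TestComplexityBounds:
    def test_printed_form_substitutions(self):
        spec = ConvSpec(in_channels=4, out_channels=8, kernel=(3, 3))
        t_sc, t_dsc, t_gs = complexity_bounds(spec, (10, 10))
        assert (t_sc, t_dsc, t_gs) == (9600, 1200, 3600)

    def test_rejects_degenerate_output(self):
        with pytest.raises(ValueError):
            complexity_bounds(ConvSpec(4, 8), (0, 10))
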