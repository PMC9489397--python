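"""Channel split/shuffle, depthwise-separable conv, SE, SK and the residual units."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervnet import nn
from cervnet.blocks import (AttentionConfig, BlockSpec, DepthwiseSeparableConv,
                            DownsampleUnit, InvertedResidualUnit, SEModule, SKModule,
                            channel_shuffle, channel_split, se_squeeze)
from cervnet.errors import (ConfigurationError, InvalidGroupsError,
                            InvalidShapeError)

from _oracles import naive_conv2d, shuffle_index_map


class TestChannelSplit:
    def test_even_split_takes_leading_channels(self, rng):
        x = rng.standard_normal((2, 4, 3, 3))
        x1, x2 = channel_split(x)
        np.testing.assert_array_equal(x1, x[:, :2])
        np.testing.assert_array_equal(x2, x[:, 2:])

    def test_concat_roundtrip_is_bit_exact(self, rng):
        x = rng.standard_normal((3, 7, 4, 5))
        x1, x2 = channel_split(x)
        np.testing.assert_array_equal(np.concatenate([x1, x2], axis=1), x)

    def test_odd_channels_floor_rule(self, rng):
        x1, x2 = channel_split(rng.standard_normal((1, 5, 2, 2)))
        assert x1.shape[1] == 2 and x2.shape[1] == 3

    def test_single_channel_rejected(self, rng):
        with pytest.raises(InvalidShapeError):
            channel_split(rng.standard_normal((1, 1, 2, 2)))


class TestChannelShuffle:
    def test_c4_g2_permutation(self):
        x = np.arange(4, dtype=float).reshape(1, 4, 1, 1)
        out = channel_shuffle(x, 2).ravel()
        np.testing.assert_array_equal(out, [0, 2, 1, 3])

    def test_single_group_is_identity(self, rng):
        x = rng.standard_normal((2, 6, 3, 3))
        np.testing.assert_array_equal(channel_shuffle(x, 1), x)

    def test_inverse_shuffle_restores_input(self, rng):
        for c, g in [(8, 2), (12, 3), (16, 4)]:
            x = rng.standard_normal((2, c, 3, 3))
            np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, g), c // g), x)

    def test_matches_reshape_transpose_oracle(self):
        for c in range(2, 65):
            for g in range(1, c + 1):
                if c % g:
                    continue
                x = np.arange(c, dtype=float).reshape(1, c, 1, 1)
                perm = channel_shuffle(x, g).ravel().astype(int)
                np.testing.assert_array_equal(perm, shuffle_index_map(c, g))
                assert sorted(perm) == list(range(c))  # bijection

    def test_indivisible_groups_rejected(self, rng):
        with pytest.raises(InvalidGroupsError):
            channel_shuffle(rng.standard_normal((1, 6, 2, 2)), 4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 8), st.integers(1, 6))
    def test_shuffle_is_pure_channel_permutation(self, g, n):
        c = g * n
        rng = np.random.default_rng(c)
        x = rng.standard_normal((1, c, 2, 2))
        out = channel_shuffle(x, g)
        # every output channel plane equals exactly one input channel plane
        matched = {int(np.flatnonzero([(out[0, i] == x[0, j]).all()
                                       for j in range(c)])[0]) for i in range(c)}
        assert matched == set(range(c))


class TestDepthwiseSeparableConv:
    def test_identity_kernels_preserve_input(self):
        m = DepthwiseSeparableConv(1, 1, kernel_size=1)
        m.depthwise.weight.data[...] = 1.0
        m.pointwise.weight.data[...] = 1.0
        x = np.array([[[[3.5]]]])
        np.testing.assert_allclose(m(x), x)

    def test_all_ones_3x3_on_constant_map_center_is_9c(self):
        c = 0.7
        m = DepthwiseSeparableConv(1, 1, kernel_size=3)
        m.depthwise.weight.data[...] = 1.0
        m.pointwise.weight.data[...] = 1.0
        x = np.full((1, 1, 3, 3), c)
        out = m(x)
        assert out[0, 0, 1, 1] == pytest.approx(9 * c)
        assert out[0, 0, 0, 0] == pytest.approx(4 * c)  # zero padding at the corner

    @pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
    def test_depthwise_stage_matches_naive_loop_conv(self, rng, stride, dilation):
        x = rng.standard_normal((1, 3, 5, 5))
        conv = nn.Conv2d(3, 3, 3, stride=stride, dilation=dilation, groups=3)
        expected, _ = naive_conv2d(x, conv.weight.data, stride, dilation, depthwise=True)
        np.testing.assert_allclose(conv(x), expected, atol=1e-12)

    def test_dense_conv_matches_naive_loop_conv(self, rng):
        x = rng.standard_normal((2, 3, 4, 4))
        conv = nn.Conv2d(3, 5, 3)
        expected, _ = naive_conv2d(x, conv.weight.data)
        np.testing.assert_allclose(conv(x), expected, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        m = DepthwiseSeparableConv(3, 4)
        with pytest.raises(InvalidShapeError):
            m(rng.standard_normal((1, 2, 4, 4)))


class TestSqueezeExcitation:
    def test_squeeze_of_constant_map_is_the_constant(self):
        u = np.full((2, 3, 4, 4), 2.25)
        np.testing.assert_allclose(se_squeeze(u), 2.25)

    def test_squeeze_single_channel_example(self):
        u = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        assert se_squeeze(u)[0, 0] == pytest.approx(2.5)

    def test_squeeze_matches_double_loop(self, rng):
        u = rng.standard_normal((2, 3, 5, 7))
        z = se_squeeze(u)
        for b in range(2):
            for c in range(3):
                acc = 0.0
                for i in range(5):
                    for j in range(7):
                        acc += u[b, c, i, j]
                assert z[b, c] == pytest.approx(acc / 35, abs=1e-12)

    def test_zero_excitation_weights_gate_at_half(self, rng):
        se = SEModule(6, reduction_ratio=2)
        for p in se.parameters():
            p.data[...] = 0.0
        s = se.excite(rng.standard_normal((4, 6)))
        np.testing.assert_allclose(s, 0.5)

    def test_gates_lie_in_open_unit_interval(self, rng):
        # moderate inputs: beyond |logit| ~ 37 float64 sigmoid saturates to
        # exactly 0/1 even though the gates are open-interval in exact arithmetic
        se = SEModule(8, reduction_ratio=4)
        s = se.excite(rng.standard_normal((10, 8)) * 3)
        assert ((s > 0) & (s < 1)).all()

    def test_excitation_is_trainable(self, rng):
        """Finite differences: gates respond to the squeezed descriptor."""
        se = SEModule(4, reduction_ratio=2)
        z = rng.standard_normal((1, 4))
        eps = 1e-6
        base = se.excite(z.copy())
        zp = z.copy()
        zp[0, 0] += eps
        grad = (se.excite(zp) - base) / eps
        assert np.abs(grad).max() > 1e-4

    def test_gate_one_is_identity_and_gate_zero_annihilates(self, rng):
        u = rng.standard_normal((2, 6, 4, 4))
        se = SEModule(6, reduction_ratio=2)
        se.gate_override = 1.0
        np.testing.assert_array_equal(se(u), u)
        se.gate_override = 0.0
        assert not se(u).any()

    def test_gating_contracts_each_channel(self, rng):
        u = rng.standard_normal((3, 8, 5, 5))
        se = SEModule(8, reduction_ratio=4)
        out = se(u)
        assert (np.abs(out) <= np.abs(u) + 1e-12).all()


class TestSelectiveKernel:
    def test_forced_weights_select_branch_one(self, rng):
        sk = SKModule(4, reduction_ratio=2).eval()
        u = rng.standard_normal((2, 4, 6, 6))
        sk.weight_override = (1.0, 0.0)
        out = sk(u)
        np.testing.assert_allclose(out, sk.branch1(u), atol=1e-12)

    def test_softmax_branch_weights_sum_to_one(self, rng):
        sk = SKModule(6, reduction_ratio=2, branch_norm="softmax").eval()
        w1, w2 = sk.branch_weights(rng.standard_normal((3, 6, 5, 5)))
        np.testing.assert_allclose(w1 + w2, 1.0, atol=1e-12)
        assert (w1 >= 0).all() and (w2 >= 0).all()

    def test_sigmoid_norm_keeps_weights_in_unit_interval(self, rng):
        sk = SKModule(6, reduction_ratio=2, branch_norm="sigmoid").eval()
        w1, w2 = sk.branch_weights(rng.standard_normal((3, 6, 5, 5)))
        assert ((w1 > 0) & (w1 < 1)).all() and ((w2 > 0) & (w2 < 1)).all()

    def test_output_shape_matches_input(self, rng):
        sk = SKModule(8).eval()
        u = rng.standard_normal((2, 8, 7, 9))
        assert sk(u).shape == u.shape

    def test_tiny_spatial_input_rejected(self, rng):
        sk = SKModule(4).eval()
        with pytest.raises(InvalidShapeError):
            sk(rng.standard_normal((1, 4, 1, 1)))


def _unit(attention="none", c=8, r=4):
    return InvertedResidualUnit(
        BlockSpec(c, c, stride=1, attention=AttentionConfig(attention, r)))


class TestInvertedResidualUnit:
    @pytest.mark.parametrize("attention", ["none", "se", "sk"])
    def test_stride1_preserves_shape(self, rng, attention):
        u = _unit(attention).eval()
        x = rng.standard_normal((2, 8, 6, 6))
        assert u(x).shape == x.shape

    def test_identity_branch_passes_through_with_zero_weights(self, rng):
        u = _unit("none").eval()
        for name, p in u.named_parameters():
            if "weight" in name and p.data.ndim == 4:
                p.data[...] = 0.0
        x = rng.standard_normal((2, 8, 5, 5))
        out = u(x)
        pre_shuffle = channel_shuffle(out, 4)  # invert the G=2 shuffle (n = C/G = 4)
        np.testing.assert_allclose(pre_shuffle[:, :4], x[:, :4], atol=1e-12)

    def test_se_parameter_excess_is_the_excitation_count(self):
        import math
        c, r = 16, 4
        plain = _unit("none", c, r)
        se = _unit("se", c, r)
        branch_w = c - c // 2
        width = max(1, math.ceil(branch_w / r))
        excitation = branch_w * width + width + width * branch_w + branch_w
        assert se.num_parameters() - plain.num_parameters() == excitation

    def test_attention_pinned_to_identity_reproduces_plain_unit(self, rng):
        plain = _unit("none").eval()
        se = _unit("se").eval()
        se_params = [p for n, p in se.named_parameters()
                     if ".fc1." not in n and ".fc2." not in n]
        for p_dst, (_, p_src) in zip(se_params, plain.named_parameters()):
            p_dst.data[...] = p_src.data
        for _, m in se.named_modules():
            if isinstance(m, SEModule):
                m.gate_override = 1.0
        x = rng.standard_normal((2, 8, 6, 6))
        np.testing.assert_allclose(se(x), plain(x), atol=1e-12)

    def test_stride2_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            InvertedResidualUnit(BlockSpec(8, 16, stride=2))

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(InvalidShapeError):
            _unit()(rng.standard_normal((1, 6, 4, 4)))


class TestDownsampleUnit:
    def test_224_input_halves_to_112(self, rng):
        u = DownsampleUnit(BlockSpec(4, 8, stride=2)).eval()
        out = u(rng.standard_normal((1, 4, 224, 224)))
        assert out.shape == (1, 8, 112, 112)

    @pytest.mark.parametrize("attention", ["none", "se", "sk"])
    def test_output_channels_match_spec(self, rng, attention):
        u = DownsampleUnit(BlockSpec(6, 20, stride=2,
                                     attention=AttentionConfig(attention, 4))).eval()
        out = u(rng.standard_normal((2, 6, 9, 9)))
        assert out.shape == (2, 20, 5, 5)  # ceil(9/2) = 5

    def test_parameter_count_matches_closed_form(self):
        cin, cout, k = 6, 20, 3
        half = cout // 2
        u = DownsampleUnit(BlockSpec(cin, cout, stride=2, kernel_size=k))
        expected = (
            cin * k * k + 2 * cin          # branch A depthwise + BN
            + cin * half + 2 * half        # branch A pointwise + BN
            + cin * half + 2 * half        # branch B 1x1 + BN
            + half * k * k + 2 * half      # branch B depthwise + BN
            + half * half + 2 * half       # branch B 1x1 + BN
        )
        assert u.num_parameters() == expected

    def test_stride1_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            DownsampleUnit(BlockSpec(8, 8, stride=1))


def test_blockspec_json_roundtrip():
    spec = BlockSpec(16, 32, stride=2, kernel_size=5,
                     attention=AttentionConfig("sk", 8, "sigmoid"))
    assert BlockSpec.from_json(spec.to_json()) == spec
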