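"""Core-block contracts: channel shuffle permutation, asymmetric depthwise
convolutions, DCA-A/DCA-B shape laws, the attention gate, and the analytic
cost formulas against enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcsanet import (
    AsymmetricDWConv,
    ChannelAttention,
    ConvCost,
    DCABlock,
    DCABlockConfig,
    FeatureMapSpec,
    channel_shuffle,
    conv_flops,
    count_params,
)
from dcsanet.autograd import Var
from dcsanet.blocks import shuffle_permutation


# ---------------------------------------------------------------------------
# channel shuffle


def brute_force_shuffle(channels, groups):
    """Independent oracle: literal reshape-(g,n), transpose, flatten on indices."""
    n = channels // groups
    return np.arange(channels).reshape(groups, n).transpose().reshape(-1)


@pytest.mark.parametrize("channels,groups,expected", [
    (6, 1, [0, 1, 2, 3, 4, 5]),
    (6, 6, [0, 1, 2, 3, 4, 5]),
    (6, 2, [0, 3, 1, 4, 2, 5]),
])
def test_channel_shuffle_known_orders(channels, groups, expected):
    x = np.arange(channels, dtype=float).reshape(1, channels, 1, 1)
    out = channel_shuffle(x, groups)
    assert out.ravel().tolist() == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(1, 8))
def test_channel_shuffle_matches_brute_force_and_is_permutation(groups, per_group):
    channels = groups * per_group
    perm = shuffle_permutation(channels, groups)
    assert perm.tolist() == brute_force_shuffle(channels, groups).tolist()
    assert sorted(perm.tolist()) == list(range(channels))
    # shuffling with g then with n restores the original order
    double = shuffle_permutation(channels, per_group)[perm]
    assert double.tolist() == list(range(channels))


def test_channel_shuffle_rejects_indivisible_groups():
    with pytest.raises(ValueError):
        channel_shuffle(np.zeros((1, 6, 2, 2)), 4)


def test_channel_shuffle_preserves_within_channel_values(rng):
    x = rng.standard_normal((2, 6, 4, 4))
    out = channel_shuffle(x, 2)
    perm = shuffle_permutation(6, 2)
    for dst, src in enumerate(perm):
        assert np.array_equal(out[:, dst], x[:, src])


# ---------------------------------------------------------------------------
# asymmetric depthwise convolution


@pytest.mark.parametrize("stride,expected_hw", [(1, (64, 64)), (2, (32, 32))])
def test_asymmetric_dw_conv_shape_contract(rng, stride, expected_hw):
    conv = AsymmetricDWConv(32, 7, stride=stride)
    x = Var(rng.standard_normal((1, 32, 64, 64)).astype(np.float32))
    out = conv(x)
    assert out.shape == (1, 32, *expected_hw)
    assert conv.out_shape((32, 64, 64)) == (32, *expected_hw)


def test_asymmetric_dw_conv_parameter_count_vs_square_depthwise():
    conv = AsymmetricDWConv(32, 7)
    assert count_params(conv) == 32 * (7 + 7)
    # square depthwise of the same receptive field would need 32 * 49
    assert 32 * 49 > count_params(conv)


def test_asymmetric_dw_conv_rejects_even_kernel():
    with pytest.raises(ValueError):
        AsymmetricDWConv(8, 4)


# ---------------------------------------------------------------------------
# DCA blocks


def _identity_bn(bn):
    bn.running_mean[:] = 0
    bn.running_var[:] = 1
    bn.gamma.data[:] = 1
    bn.beta.data[:] = 0


def test_dca_a_preserves_shape(rng):
    block = DCABlock(DCABlockConfig(48, "A"))
    x = Var(rng.standard_normal((2, 48, 32, 32)).astype(np.float32))
    assert block(x).shape == (2, 48, 32, 32)


def test_dca_a_with_zero_weights_is_pure_shuffle(rng):
    cfg = DCABlockConfig(8, "A")
    block = DCABlock(cfg).eval()
    for _, p in block.named_parameters():
        if p.data.ndim > 1 or "weight" in _:
            p.data[:] = 0
    for mod in block.modules():
        if hasattr(mod, "running_mean"):
            _identity_bn(mod)
    x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
    out = block(Var(x)).data
    assert np.allclose(out, channel_shuffle(x, cfg.shuffle_groups), atol=1e-6)


def test_dca_a_without_shuffle_keeps_channel_order(rng):
    cfg = DCABlockConfig(8, "A", use_shuffle=False)
    block = DCABlock(cfg).eval()
    for name, p in block.named_parameters():
        if p.data.ndim > 1:
            p.data[:] = 0
    for mod in block.modules():
        if hasattr(mod, "running_mean"):
            _identity_bn(mod)
    x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
    assert np.allclose(block(Var(x)).data, x, atol=1e-6)


@pytest.mark.parametrize("c,h,w", [(32, 64, 64), (16, 128, 128)])
def test_dca_b_halves_space_doubles_channels(rng, c, h, w):
    block = DCABlock(DCABlockConfig(c, "B"))
    x = Var(rng.standard_normal((1, c, h, w)).astype(np.float32))
    assert block(x).shape == (1, 2 * c, h // 2, w // 2)


def test_dca_b_rejects_odd_spatial_dims(rng):
    block = DCABlock(DCABlockConfig(8, "B"))
    with pytest.raises(ValueError):
        block(Var(rng.standard_normal((1, 8, 5, 6)).astype(np.float32)))


def test_dca_b_pooled_branch_of_constant_input_is_constant():
    block = DCABlock(DCABlockConfig(4, "B", use_shuffle=False)).eval()
    for _, p in block.named_parameters():
        if p.data.ndim > 1:
            p.data[:] = 0
    for mod in block.modules():
        if hasattr(mod, "running_mean"):
            _identity_bn(mod)
    x = np.full((1, 4, 8, 8), 3.5, dtype=np.float32)
    out = block(Var(x)).data
    # second half of the channels is the max-pooled input
    assert np.allclose(out[:, 4:], 3.5, atol=1e-6)
    assert out.shape == (1, 8, 4, 4)


def test_dca_block_mode_mismatch_errors():
    with pytest.raises(ValueError):
        DCABlockConfig(8, "C")
    from dcsanet.blocks import dca_a_block, dca_b_block

    with pytest.raises(ValueError):
        dca_a_block(Var(np.zeros((1, 8, 4, 4), np.float32)), DCABlockConfig(8, "B"))
    with pytest.raises(ValueError):
        dca_b_block(Var(np.zeros((1, 8, 4, 4), np.float32)), DCABlockConfig(8, "A"))


# ---------------------------------------------------------------------------
# channel attention


def test_channel_attention_identity_and_null_gates(rng):
    att = ChannelAttention(8, reduction=4)
    x = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
    # force gate to one: sigmoid(large positive) -> 1
    att.w1.data[:] = 0
    att.b1.data[:] = 0
    att.w2.data[:] = 0
    att.b2.data[:] = 50.0
    assert np.allclose(att(Var(x)).data, x, atol=1e-4)
    att.b2.data[:] = -50.0
    assert np.allclose(att(Var(x)).data, 0, atol=1e-4)


def test_channel_attention_pools_zero_channel_to_zero(rng):
    from dcsanet.autograd import global_avg_pool

    x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
    x[:, 0] = 0
    pooled = global_avg_pool(Var(x)).data
    assert pooled[0, 0] == 0


def test_channel_attention_rejects_bad_reduction():
    with pytest.raises(ValueError):
        ChannelAttention(4, reduction=8)


def test_channel_attention_gate_in_unit_interval(rng):
    att = ChannelAttention(8, reduction=4, rng=np.random.default_rng(3))
    x = Var(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
    gate = att.gate(x).data
    assert gate.min() >= 0.0 and gate.max() <= 1.0


# ---------------------------------------------------------------------------
# analytic cost formulas


def test_conv_flops_printed_formula_values():
    cost = ConvCost(kernel_length=3, in_channels=8, out_channels=16, out_height=16, out_width=16)
    assert conv_flops(cost, "standard") == 294_912
    ratio = conv_flops(cost, "depthwise_separable") / conv_flops(cost, "standard")
    assert ratio == pytest.approx(1 / 16 + 1 / 9, rel=1e-12)
    cost7 = ConvCost(kernel_length=7, in_channels=8, out_channels=16, out_height=16, out_width=16)
    assert conv_flops(cost7, "asymmetric") / conv_flops(cost7, "standard") == pytest.approx(2 / 7)


def test_conv_flops_unknown_kind():
    cost = ConvCost(3, 4, 4, 8, 8)
    with pytest.raises(ValueError):
        conv_flops(cost, "grouped")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.sampled_from([3, 5, 7, 9]),
    st.integers(1, 64),
    st.integers(1, 64),
    st.integers(1, 32),
    st.integers(1, 32),
)
def test_depthwise_ratio_identity(n, c1, c2, h, w):
    cost = ConvCost(n, c1, c2, h, w)
    ratio = conv_flops(cost, "standard") / conv_flops(cost, "depthwise_separable")
    assert ratio == pytest.approx(1 / (1 / c2 + 1 / n**2), rel=1e-9)


def test_conv_cost_validation():
    with pytest.raises(ValueError):
        ConvCost(4, 8, 8, 8, 8)  # even kernel
    with pytest.raises(ValueError):
        ConvCost(3, 0, 8, 8, 8)
    with pytest.raises(ValueError):
        FeatureMapSpec(0, 4, 4)


def _enumerate_params(module):
    """Oracle: exhaustively walk the weight arrays and sum their sizes."""
    return sum(int(np.prod(p.data.shape)) for _, p in module.named_parameters())


@pytest.mark.parametrize("make", [
    lambda: AsymmetricDWConv(16, 7),
    lambda: ChannelAttention(16, 4),
    lambda: DCABlock(DCABlockConfig(12, "A")),
    lambda: DCABlock(DCABlockConfig(12, "B")),
    lambda: DCABlock(DCABlockConfig(16, "A", use_attention=True)),
])
def test_count_params_matches_enumeration(make):
    module = make()
    assert count_params(module) == _enumerate_params(module)


def test_count_params_closed_forms():
    from dcsanet.layers import Conv2d, DepthwiseConv2d

    assert count_params(Conv2d(3, 16, 3, bias=True)) == 3 * 3 * 3 * 16 + 16
    assert count_params(DepthwiseConv2d(32, (7, 1))) == 32 * 7


def test_blocks_deterministic_at_inference(rng):
    block = DCABlock(DCABlockConfig(8, "A", use_attention=True)).eval()
    x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
    y1 = block(Var(x)).data
    y2 = block(Var(x)).data
    assert np.array_equal(y1, y2)
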