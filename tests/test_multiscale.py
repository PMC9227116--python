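"""SPP/ASPP branch and aggregation behaviour, with a brute-force atrous
oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wasppnet import nn
from wasppnet.multiscale import (ASPPBranch, MultiScaleBlock, SPPBranch,
                                 aggregate_direct, aggregate_waterfall,
                                 atrous_conv1d, atrous_conv2d,
                                 effective_span)
from wasppnet.nn import GeometryError


def brute_force_atrous2d(x, f, r):
    """Direct nested-loop tap sum: out[m, n] = sum x[m+r*i, n+r*j] f[i,j]."""
    kh, kw = f.shape
    oh = x.shape[0] - effective_span(kh, r) + 1
    ow = x.shape[1] - effective_span(kw, r) + 1
    out = np.zeros((oh, ow))
    for m in range(oh):
        for n in range(ow):
            for i in range(kh):
                for j in range(kw):
                    out[m, n] += x[m + r * i, n + r * j] * f[i, j]
    return out


def test_atrous_1d_worked_example():
    out = atrous_conv1d([1, 2, 3, 4, 5], [1, 1, 1], r=2)
    assert out.shape == (1,)
    assert out[0] == 1 + 3 + 5


def test_effective_span_enumerates_tap_positions():
    # taps for k=3, r=3 sit at offsets 0, 3, 6 -> span 7
    assert effective_span(3, 3) == 7
    assert effective_span(1, 5) == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 3), st.sampled_from([1, 3]),
       st.integers(0, 10_000))
def test_atrous_matches_brute_force(r, k, seed):
    rng = np.random.default_rng(seed)
    span = effective_span(k, r)
    h = rng.integers(span, 10)
    w = rng.integers(span, 10)
    x = rng.normal(size=(h, w))
    f = rng.normal(size=(k, k))
    out = atrous_conv2d(x, f, r)
    np.testing.assert_allclose(out, brute_force_atrous2d(x, f, r),
                               atol=1e-6)


def test_atrous_rate1_equals_standard_convolution():
    from scipy.signal import correlate2d
    rng = np.random.default_rng(0)
    x = rng.normal(size=(9, 9))
    f = rng.normal(size=(3, 3))
    np.testing.assert_allclose(atrous_conv2d(x, f, r=1),
                               correlate2d(x, f, mode="valid"), atol=1e-10)
    np.testing.assert_allclose(
        atrous_conv2d(x, f, r=1, padding_mode="same").shape, x.shape)


def test_atrous_geometry_error_when_span_exceeds_input():
    with pytest.raises(GeometryError):
        atrous_conv2d(np.zeros((4, 4)), np.ones((3, 3)), r=2)


def test_engine_dilated_conv_agrees_with_atrous_oracle():
    """The trainable Conv2d(dilation=r) path computes the same tap sum."""
    rng = np.random.default_rng(4)
    for r in (1, 2, 3):
        conv = nn.Conv2d(1, 1, 3, dilation=r, rng=rng)
        conv.params["b"][:] = 0
        x = rng.normal(size=(9, 9))
        out = conv.forward(x[None, None].astype(np.float32))
        ref = brute_force_atrous2d(x, conv.params["W"][0, 0].astype(
            np.float64), r)
        np.testing.assert_allclose(out[0, 0], ref, atol=1e-5)


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

def test_spp_branch_pool_preserves_constants_and_sizes():
    rng = np.random.default_rng(1)
    branch = SPPBranch(2, pool_side=10, out_channels=3, rng=rng)
    x = rng.normal(size=(1, 2, 65, 65)).astype(np.float32)
    conv_out = branch.layers[0][1].forward(x)
    pooled = branch.layers[1][1].forward(conv_out)
    assert pooled.shape[-2:] == (6, 6)  # floor(65 / 10)
    # average pooling of a constant map is the same constant
    const = np.full((1, 2, 20, 20), 3.5, dtype=np.float32)
    np.testing.assert_allclose(nn.AvgPool2d(4).forward(const), 3.5,
                               rtol=1e-6)
    assert branch.output_side(65) == 6


def test_aspp_branch_preserves_spatial_size():
    rng = np.random.default_rng(2)
    for rate in (1, 2, 5):
        branch = ASPPBranch(2, rate=rate, out_channels=3, rng=rng)
        x = rng.normal(size=(1, 2, 33, 33)).astype(np.float32)
        assert branch.forward(x).shape == (1, 3, 33, 33)
        assert branch.output_side(33) == 33


def test_aspp_rate1_branch_is_a_standard_conv_branch():
    rng = np.random.default_rng(3)
    aspp = ASPPBranch(2, rate=1, out_channels=3, rng=rng)
    conv = aspp.layers[0][1]
    assert conv.dilation == 1 and conv.padding == 1


# ---------------------------------------------------------------------------
# Aggregation flows
# ---------------------------------------------------------------------------

def test_direct_aggregation_channel_arithmetic_and_skip():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 8, 20, 20)).astype(np.float32)
    out = aggregate_direct(x, "spp", [2, 3, 4, 5], branch_channels=4, seed=0)
    assert out.shape == (2, 8 + 4 * 4, 20, 20)
    np.testing.assert_array_equal(out[:, :8], x)  # skip copy leads


def test_empty_aggregation_is_identity():
    x = np.ones((1, 2, 9, 9), dtype=np.float32)
    np.testing.assert_array_equal(aggregate_direct(x, "spp", []), x)


def test_direct_block_channel_slots_equal_individual_branches():
    """Concatenated channel block i reproduces branch i run alone."""
    rng = np.random.default_rng(6)
    block = MultiScaleBlock("aspp", "direct", [1, 2], in_channels=3,
                            input_side=12, branch_channels=4, rng=rng)
    x = rng.normal(size=(1, 3, 12, 12)).astype(np.float32)
    out = block.forward(x)
    for i, branch in enumerate(block.branches):
        alone = branch.forward(x)
        np.testing.assert_array_equal(out[:, 3 + 4 * i: 3 + 4 * (i + 1)],
                                      alone)


def test_waterfall_single_branch_equals_direct():
    rng_a = np.random.default_rng(7)
    rng_b = np.random.default_rng(7)
    direct = MultiScaleBlock("aspp", "direct", [2], 3, 12,
                             branch_channels=4, rng=rng_a)
    water = MultiScaleBlock("aspp", "waterfall", [2], 3, 12,
                            branch_channels=4, rng=rng_b)
    x = np.random.default_rng(8).normal(size=(2, 3, 12, 12)).astype(
        np.float32)
    np.testing.assert_array_equal(direct.forward(x), water.forward(x))


def test_waterfall_spp_raw_chaining_rejected_when_pooling_exhausts_map():
    # 65 -> floor(65/4)=16 -> floor(16/6)=2 -> pool 8 impossible
    with pytest.raises(GeometryError, match="stage 3"):
        MultiScaleBlock("spp", "waterfall", [4, 6, 8, 10], in_channels=4,
                        input_side=65, branch_channels=2)
    # chaining from resized outputs keeps every stage feasible
    block = MultiScaleBlock("spp", "waterfall", [4, 6, 8, 10], 4, 65,
                            branch_channels=2, chain_resized=True,
                            rng=np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 4, 65, 65)).astype(
        np.float32)
    assert block.forward(x).shape == (1, 4 + 4 * 2, 65, 65)


def test_waterfall_aspp_preserves_spatial_size_at_flow_rates():
    rng = np.random.default_rng(9)
    block = MultiScaleBlock("aspp", "waterfall", [2, 3, 4, 5], 4, 65,
                            branch_channels=2, rng=rng)
    x = rng.normal(size=(1, 4, 65, 65)).astype(np.float32)
    assert block.forward(x).shape == (1, 4 + 4 * 2, 65, 65)


def test_aggregation_eval_deterministic_for_fixed_weights():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(1, 3, 16, 16)).astype(np.float32)
    a = aggregate_waterfall(x, "aspp", [1, 2], branch_channels=2, seed=42)
    b = aggregate_waterfall(x, "aspp", [1, 2], branch_channels=2, seed=42)
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("flow,chain_resized", [
    ("direct", False), ("waterfall", False), ("waterfall", True)])
def test_block_backward_matches_numerical(flow, chain_resized):
    """End-to-end gradient of the aggregation block (branch chaining,
    skip, resize-concat) agrees with central differences."""
    import test_nn
    params = [2, 3] if not chain_resized else [2, 4]
    block = MultiScaleBlock("spp" if chain_resized else "aspp", flow,
                            params, in_channels=2, input_side=10,
                            branch_channels=2, chain_resized=chain_resized,
                            rng=np.random.default_rng(11))
    # bias every batch norm so ReLUs stay in their linear region: the
    # finite-difference check is ill-posed across the ReLU kink
    for _, layer in block.all_layers_nested(""):
        if isinstance(layer, nn.BatchNorm2d):
            layer.params["beta"][:] = 2.0
    rng = np.random.default_rng(12)
    x = rng.normal(size=(2, 2, 10, 10)).astype(np.float32)
    weight = rng.normal(size=block.forward(x, train=True).shape).astype(
        np.float32)

    def loss():
        return float((block.forward(x, train=True) * weight).sum())

    block.forward(x, train=True)
    dx = block.backward(weight)
    num = test_nn.numerical_grad(loss, x)
    np.testing.assert_allclose(dx, num, atol=3e-3, rtol=3e-2)
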