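"""Base CNN shape chain, variant assembly, presets, parameter counts,
checkpoints."""

import numpy as np
import pytest

from wasppnet import nn
from wasppnet.architectures import (ArchitectureSpec, EXPECTED_SIDES,
                                    PRESET_NAMES, build_base_cnn,
                                    build_variant, count_parameters,
                                    get_preset, infer_output_side,
                                    load_checkpoint, save_checkpoint,
                                    summarize)
from wasppnet.nn import GeometryError

TINY = 1 / 32  # width multiplier for anything that runs a forward pass


@pytest.mark.parametrize("args,expected", [
    ((75, 7, 1, 0), 69),
    ((65, 3, 2, 0), 32),
    ((5, 1, 1, 0), 5),
    ((1, 1, 1, 0), 1),
    ((32, 3, 2, 1), 16),
    ((16, 3, 2, 1), 8),
])
def test_infer_output_side(args, expected):
    assert infer_output_side(*args) == expected


def test_infer_output_side_rejects_invalid_geometry():
    with pytest.raises(GeometryError, match="Pool9"):
        infer_output_side(2, 7, 1, 0, layer_name="Pool9")
    with pytest.raises(ValueError):
        infer_output_side(10, 3, 0, 0)


def test_base_summary_matches_printed_architecture():
    """Channel counts 96/256/512 and the 69-65-65-32-32-16-16-8 spatial
    chain, dense sizes 128/128/3, 11 named rows."""
    model = build_base_cnn()
    s = summarize(model)
    assert s.layer_names == ["Conv1", "Conv2", "Conv3", "Pool3", "Conv4",
                             "Pool4", "Conv5", "Pool5", "FC1", "FC2", "FC3"]
    assert s.shape_of("Conv1") == (96, 69, 69)
    assert s.shape_of("Conv2") == (256, 65, 65)
    assert s.shape_of("Conv3") == (512, 65, 65)
    assert s.shape_of("Pool3") == (512, 32, 32)
    assert s.shape_of("Conv4") == (512, 32, 32)
    assert s.shape_of("Pool4") == (512, 16, 16)
    assert s.shape_of("Conv5") == (512, 16, 16)
    assert s.shape_of("Pool5") == (512, 8, 8)
    assert s.shape_of("FC1") == (128,)
    assert s.shape_of("FC2") == (128,)
    assert s.shape_of("FC3") == (3,)
    assert s.total_parameters == count_parameters(model)


def test_width_scaling_preserves_spatial_chain():
    s = summarize(build_base_cnn(width=TINY))
    for name, side in EXPECTED_SIDES.items():
        assert s.shape_of(name)[1:] == (side, side)


@pytest.mark.parametrize("preset", ["base", "WASPP", "SPP-I"])
def test_forward_probabilities_normalized(preset):
    model = build_variant(get_preset(preset, width=TINY), seed=0)
    x = np.random.default_rng(0).normal(size=(4, 3, 75, 75)).astype(
        np.float32)
    p = model.forward(x)
    assert p.shape == (4, 3)
    assert np.all(p >= 0)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_eval_outputs_batch_size_invariant():
    model = build_variant(get_preset("WASPP", width=TINY), seed=1)
    x = np.random.default_rng(1).normal(size=(3, 3, 75, 75)).astype(
        np.float32)
    lone = np.concatenate([model.forward(x[i:i + 1]) for i in range(3)])
    # eval mode has no cross-sample coupling; BLAS accumulation order in
    # the dense layers may differ across batch shapes at float32 epsilon
    np.testing.assert_allclose(model.forward(x), lone, atol=1e-5)
    assert np.array_equal(model.forward(x).argmax(1), lone.argmax(1))


def test_single_conv_parameter_count_closed_form():
    conv = nn.Conv2d(2, 4, 3)
    assert conv.n_params() == 3 * 3 * 2 * 4 + 4


def test_parameter_counts_seed_invariant():
    spec = get_preset("DASPP", width=TINY)
    assert (count_parameters(build_variant(spec, seed=0))
            == count_parameters(build_variant(spec, seed=99)))


def test_dspp_and_daspp_parameter_counts_equal():
    """SPP branch conv + pool and ASPP atrous conv have identical weight
    tensors, so the two direct-flow presets count identically."""
    assert (count_parameters(build_variant(get_preset("DSPP")))
            == count_parameters(build_variant(get_preset("DASPP"))))


def test_every_variant_has_more_parameters_than_base():
    base = count_parameters(build_base_cnn(width=TINY))
    for name in PRESET_NAMES:
        if name == "base":
            continue
        variant = count_parameters(build_variant(get_preset(name,
                                                            width=TINY)))
        assert variant > base, name


def test_preset_definitions():
    spp8 = get_preset("SPP-VIII")
    assert (spp8.module_kind, spp8.flow, spp8.n_branches,
            spp8.branch_params, spp8.placement) == (
        "spp", "direct", 5, (2, 4, 6, 8, 10), "after_conv2")
    daspp = get_preset("DASPP")
    assert (daspp.module_kind, daspp.flow, daspp.branch_params,
            daspp.placement) == ("aspp", "direct", (2, 3, 4, 5),
                                 "after_conv2")
    aspp3 = get_preset("ASPP-III")
    assert aspp3.branch_params == (1, 2, 3, 4)
    assert aspp3.placement == "after_conv1"
    with pytest.raises(KeyError):
        get_preset("SPP-IX")


def test_placement_inserts_block_between_conv_layers():
    s1 = summarize(build_variant(ArchitectureSpec(
        "aspp", "direct", 2, (1, 2), "after_conv1", branch_channels=2,
        width=TINY)))
    names = s1.layer_names
    assert names.index("Conv1") < names.index("ASPP") < names.index("Conv2")
    s2 = summarize(build_variant(get_preset("WASPP", width=TINY)))
    assert s2.layer_names.index("Conv2") < s2.layer_names.index("ASPP")


def test_single_branch_direct_and_waterfall_identical_networks():
    kwargs = dict(module_kind="aspp", n_branches=1, branch_params=(2,),
                  branch_channels=2, width=TINY)
    d = build_variant(ArchitectureSpec(flow="direct", **kwargs), seed=3)
    w = build_variant(ArchitectureSpec(flow="waterfall", **kwargs), seed=3)
    x = np.random.default_rng(4).normal(size=(2, 3, 75, 75)).astype(
        np.float32)
    np.testing.assert_array_equal(d.forward(x), w.forward(x))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ArchitectureSpec("spp", "direct", 3, (2, 4), "after_conv1")
    with pytest.raises(ValueError):
        ArchitectureSpec("spp", "direct", 2, (4, 2), "after_conv1")
    with pytest.raises(ValueError):
        ArchitectureSpec(module_kind="pyramid")
    with pytest.raises(ValueError):
        ArchitectureSpec(n_classes=1)


def test_checkpoint_roundtrip(tmp_path):
    model = build_variant(get_preset("WASPP", width=TINY), seed=5)
    x = np.random.default_rng(5).normal(size=(2, 3, 75, 75)).astype(
        np.float32)
    before = model.forward(x)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    assert restored.spec == model.spec
    np.testing.assert_array_equal(restored.forward(x), before)


def test_summary_text_serializes():
    text = summarize(build_base_cnn(width=TINY)).to_text()
    assert "Conv1" in text and "Total parameters" in text
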