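"""Architecture family: block shapes, bottleneck fusion, forward contracts."""

from __future__ import annotations

import numpy as np
import pytest

import imau_seg as I
from imau_seg.errors import ConfigurationError, PretrainedWeightsUnavailable
from imau_seg.nn import ops
from imau_seg.nn.tensor import Tensor


def feature_map(rng, h=8, w=8, c=64):
    return Tensor(rng.normal(size=(1, h, w, c)).astype(np.float32))


# -- MCP block -----------------------------------------------------------

def test_mcp_concatenation_channels_at_reduced_width(rng):
    spec = I.ArchitectureSpec(width_multiplier=0.25)  # branch filters 64
    block = I.build_mcp_block(32, spec)
    out = block(feature_map(rng, c=32))
    assert out.shape == (1, 8, 8, 192)  # 3 branches x 64


def test_mcp_preserves_spatial_size_with_even_and_odd_kernels(rng):
    spec = I.ArchitectureSpec(width_multiplier=0.0625)
    block = I.build_mcp_block(16, spec)
    for h, w in ((8, 8), (7, 9)):
        assert block(feature_map(rng, h, w, 16)).shape[1:3] == (h, w)


def test_mcp_pool_branches_pass_constants_through():
    x = Tensor(np.full((1, 6, 6, 4), 3.25, np.float32))
    for k in (2, 3, 5):
        pooled = ops.maxpool2d(x, k, 1, "same")
        assert np.allclose(pooled.data, 3.25)


def test_mcp_pooling_is_monotone_under_pixel_increase(rng):
    x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
    base = ops.maxpool2d(Tensor(x), 3, 1).data
    bumped = x.copy()
    bumped[0, 4, 4, 2] += 1.0
    after = ops.maxpool2d(Tensor(bumped), 3, 1).data
    assert (after >= base - 1e-7).all()


def test_mcp_kernel_larger_than_input_raises(rng):
    spec = I.ArchitectureSpec(width_multiplier=0.0625)
    block = I.build_mcp_block(8, spec)
    with pytest.raises(ValueError, match="kernel"):
        block(feature_map(rng, 2, 2, 8))


# -- ASPP block ----------------------------------------------------------

def test_aspp_concat_and_reduction_channels_at_reduced_width(rng):
    spec = I.ArchitectureSpec(width_multiplier=0.25)  # 64 per branch, reduce 128
    block = I.build_aspp_block(32, spec)
    cat, red = block.forward_detail(feature_map(rng, c=32))
    assert cat.shape[-1] == 5 * 64 == 320
    assert red.shape[-1] == 128
    assert cat.shape[1:3] == red.shape[1:3] == (8, 8)


def test_aspp_gap_branch_averages_constants():
    x = Tensor(np.full((1, 8, 8, 4), -1.5, np.float32))
    gap = ops.global_avg_pool(x)
    assert np.allclose(gap.data, -1.5)
    up = ops.broadcast_hw(gap, (8, 8))
    assert up.shape == (1, 8, 8, 4) and np.allclose(up.data, -1.5)


@pytest.mark.parametrize("rate", [2, 4, 6, 8])
def test_dilated_conv_receptive_field_extent_is_2r_plus_1(rate):
    # impulse response support of a 3x3 convolution at dilation r
    size = 2 * 8 + 3
    x = np.zeros((1, size, size, 1), np.float32)
    x[0, size // 2, size // 2, 0] = 1.0
    w = Tensor(np.ones((3, 3, 1, 1), np.float32))
    resp = ops.conv2d(Tensor(x), w, dilation=rate).data[0, :, :, 0]
    rows = np.where(resp.any(axis=1))[0]
    assert rows.max() - rows.min() + 1 == 2 * rate + 1


# -- encoder taps --------------------------------------------------------

def test_encoder_taps_shapes_order_and_channels():
    enc, shapes = I.build_encoder_taps(width=0.125, input_size=(64, 64))
    sizes = [shapes[n][0] for n in ("mixed0", "mixed3", "mixed6", "mixed10")]
    assert sizes == sorted(sizes, reverse=True)  # non-increasing spatial order
    # channel widths follow the canonical backbone, scaled by 1/8
    assert shapes["mixed0"][2] == enc.tap_channels["mixed0"] == 32
    assert shapes["mixed10"][2] == enc.tap_channels["mixed10"] == 256


def test_full_width_backbone_final_tap_has_2048_channels():
    enc = I.InceptionV3Encoder(width=1.0, rng=np.random.default_rng(0))
    assert enc.tap_channels["mixed10"] == 2048
    assert enc.tap_channels["mixed0"] == 256
    assert enc.tap_channels["mixed3"] == enc.tap_channels["mixed6"] == 768


def test_seeded_backbone_init_is_reproducible():
    a = I.InceptionV3Encoder(width=0.0625, rng=np.random.default_rng(5))
    b = I.InceptionV3Encoder(width=0.0625, rng=np.random.default_rng(5))
    for pa, pb in zip(a.parameters(), b.parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_pretrained_weights_request_raises_offline_error():
    with pytest.raises(PretrainedWeightsUnavailable, match="offline"):
        I.InceptionV3Encoder(pretrained=True)


# -- full models ---------------------------------------------------------

@pytest.mark.parametrize("variant", I.architectures.VARIANTS)
def test_all_variants_forward_contract(variant, rng):
    spec = I.ArchitectureSpec(
        variant=variant, width_multiplier=0.0625, input_size=(160, 160, 3)
    )
    model = I.build_model(spec, seed=0)
    prob = model.predict(rng.uniform(size=(160, 160, 3)).astype(np.float32))
    assert prob.shape == (160, 160)
    assert (prob > 0).all() and (prob < 1).all()  # sigmoid range, strict
    assert model.parameter_count > 0
    assert "bottleneck" in model.endpoints and "output" in model.endpoints


def test_imau_bottleneck_fuses_mcp_and_aspp_channels():
    spec = I.ArchitectureSpec(
        variant="imau_net", width_multiplier=0.125, input_size=(160, 160, 3)
    )
    model = I.build_model(spec, seed=0)
    model.predict(np.zeros((160, 160, 3), np.float32))
    bf = spec.scaled(spec.branch_filters)
    reduced = spec.scaled(spec.aspp_reduced_filters)
    assert model.endpoints["bottleneck"][-1] == 3 * bf + reduced
    assert model.bottleneck_channels == 3 * bf + reduced


def test_forward_deterministic_for_fixed_seed(rng):
    spec = I.ArchitectureSpec(
        variant="mcp_unet", width_multiplier=0.0625, input_size=(160, 160, 3)
    )
    x = rng.uniform(size=(160, 160, 3)).astype(np.float32)
    p1 = I.build_model(spec, seed=3).predict(x)
    p2 = I.build_model(spec, seed=3).predict(x)
    assert np.array_equal(p1, p2)


def test_zeroing_a_skip_connection_changes_the_output(rng):
    spec = I.ArchitectureSpec(
        variant="imau_net", width_multiplier=0.0625, input_size=(160, 160, 3)
    )
    model = I.build_model(spec, seed=1)
    x = rng.uniform(size=(160, 160, 3)).astype(np.float32)
    base = model.predict(x)
    ablated = model.predict(x, disable_skips=("mixed0",))
    assert np.abs(base - ablated).max() > 0


def test_shape_soundness_for_other_divisible_by_32_sizes(rng):
    spec = I.ArchitectureSpec(variant="imau_net", width_multiplier=0.0625)
    model = I.build_model(spec, seed=0)
    prob = model.predict(rng.uniform(size=(160, 192, 3)).astype(np.float32))
    assert prob.shape == (160, 192)


def test_checkpoint_round_trip(tmp_path, rng):
    spec = I.ArchitectureSpec(
        variant="aspp_unet", width_multiplier=0.0625, input_size=(64, 64, 3)
    )
    model = I.build_model(spec, seed=4)
    x = rng.uniform(size=(64, 64, 3)).astype(np.float32)
    before = model.predict(x)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = I.Model.load(path)
    assert loaded.spec == spec
    assert np.allclose(loaded.predict(x), before)


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        ({"variant": "resnet_unet"}, "variant"),
        ({"aspp_dilations": (2, 2, 6, 8)}, "increasing"),
        ({"width_multiplier": 0.0}, "width_multiplier"),
        ({"mcp_kernels": (0, 3, 5)}, "positive"),
    ],
)
def test_invalid_architecture_spec_rejected(kwargs, msg):
    with pytest.raises(ConfigurationError, match=msg):
        I.ArchitectureSpec(**kwargs)
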