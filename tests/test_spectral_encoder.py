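"""Spectral encoder: frozen backbone, reduction, CBAM, joint gating."""

import numpy as np
import pytest

from nmrmatch.autodiff import Tensor, no_grad
from nmrmatch.nn import Adam
from nmrmatch.spectral_encoder import (CBAM, ChannelAttention, ImageSizeError,
                                       JointGate, SpectralEncoder,
                                       SpectralEncoderConfig, TinyBackbone,
                                       resnet101_trunk)
from oracles import cbam_reference, joint_gate_reference, sigmoid


@pytest.fixture(scope="module")
def encoder():
    return SpectralEncoder(SpectralEncoderConfig(), np.random.default_rng(3))


def fake_images(rng, n=2):
    return rng.random((n, 3, 256, 256)).astype(np.float32)


# ------------------------------------------------------------------ backbone

def test_backbone_reduction_2048_to_16_preserves_spatial_size(encoder, rng):
    feats = encoder.backbone_features(fake_images(rng))
    assert feats.shape[1] == 2048
    h, w = feats.shape[2:]
    reduced = encoder.reduce_h(Tensor(feats))
    assert reduced.shape == (feats.shape[0], 16, h, w)


def test_wrong_image_size_raises_with_resize_instruction(encoder, rng):
    with pytest.raises(ImageSizeError, match="resize"):
        encoder.backbone_features(rng.random((1, 3, 128, 128)))


def test_backbone_is_frozen_and_immutable_under_training(encoder, rng):
    """An optimizer step over all trainable params leaves the trunk intact."""
    before = {n: p.data.copy()
              for n, p in encoder.backbone.named_parameters()}
    imgs = fake_images(rng)
    feats0 = encoder.backbone_features(imgs)
    opt = Adam(encoder.trainable_parameters(), lr=1e-2)
    out = encoder.forward_from_features(Tensor(feats0), Tensor(feats0))
    (out ** 2).sum().backward()
    opt.step()
    for n, p in encoder.backbone.named_parameters():
        np.testing.assert_array_equal(before[n], p.data)
    np.testing.assert_array_equal(feats0, encoder.backbone_features(imgs))


def test_trainable_backbone_flag_is_rejected(rng):
    enc = SpectralEncoder(SpectralEncoderConfig(), rng)
    for p in enc.backbone.parameters():
        p.frozen = False
    from nmrmatch.spectral_encoder import BackboneNotFrozenError

    with pytest.raises(BackboneNotFrozenError):
        enc.check_frozen()


def test_resnet101_trunk_parameter_count_is_42_50_million():
    trunk = resnet101_trunk(np.random.default_rng(0))
    counts = trunk.count_parameters()
    assert counts["total"] == 42_500_160
    assert counts["trainable"] == 0


# ---------------------------------------------------------------------- CBAM

def test_zero_mlp_gives_channel_weights_half(rng):
    ca = ChannelAttention(16, 4, rng)
    for p in ca.parameters():
        p.data[:] = 0.0
    mc = ca(Tensor(rng.random((2, 16, 4, 4)).astype(np.float32)))
    np.testing.assert_allclose(mc.data, 0.5, atol=1e-7)


def test_spatially_constant_map_makes_gap_equal_gmp(rng):
    """Mc = sigmoid(2 * MLP(g)) when average and max descriptors coincide."""
    ca = ChannelAttention(16, 4, rng)
    g = rng.normal(size=16).astype(np.float32)
    fmap = np.broadcast_to(g[:, None, None], (16, 5, 5)).copy()
    mc = ca(Tensor(fmap[None]))
    hidden = np.maximum(g @ ca.fc1.weight.data + ca.fc1.bias.data, 0)
    expected = sigmoid(2 * (hidden @ ca.fc2.weight.data + ca.fc2.bias.data))
    np.testing.assert_allclose(mc.data[0], expected, atol=1e-5)


def test_cbam_matches_straight_line_reference(rng):
    """Random 16x8x8 map: full CBAM equals the dense reference computation."""
    cbam = CBAM(16, 4, rng)
    fmap = rng.normal(size=(16, 8, 8)).astype(np.float32)
    out, mc, ms = cbam(Tensor(fmap[None]), return_masks=True)
    exp_out, exp_mc, exp_ms = cbam_reference(
        fmap.astype(np.float64),
        cbam.channel.fc1.weight.data, cbam.channel.fc1.bias.data,
        cbam.channel.fc2.weight.data, cbam.channel.fc2.bias.data,
        cbam.spatial.conv.weight.data, cbam.spatial.conv.bias.data)
    np.testing.assert_allclose(mc.data[0], exp_mc, atol=1e-5)
    np.testing.assert_allclose(ms.data[0, 0], exp_ms, atol=1e-5)
    np.testing.assert_allclose(out.data[0], exp_out, atol=1e-5)


def test_masks_lie_in_unit_interval_and_attenuate(rng):
    cbam = CBAM(16, 4, rng)
    fmap = rng.normal(size=(3, 16, 6, 6)).astype(np.float32)
    out, mc, ms = cbam(Tensor(fmap), return_masks=True)
    assert np.all(mc.data > 0) and np.all(mc.data < 1)
    assert np.all(ms.data > 0) and np.all(ms.data < 1)
    assert np.all(np.abs(out.data) <= np.abs(fmap) + 1e-7)


# ---------------------------------------------------------------- joint gate

def test_zero_gate_mlp_halves_every_channel(rng):
    gate = JointGate(16, 8, rng)
    for p in gate.parameters():
        p.data[:] = 0.0
    mh = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
    mc_ = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
    out_h, out_c, g = gate(Tensor(mh), Tensor(mc_))
    np.testing.assert_allclose(g.data, 0.5)
    np.testing.assert_allclose(out_h.data, mh * 0.5, atol=1e-7)
    np.testing.assert_allclose(out_c.data, mc_ * 0.5, atol=1e-7)


def test_saturated_gate_passes_maps_through(rng):
    gate = JointGate(16, 8, rng)
    for p in gate.parameters():
        p.data[:] = 0.0
    gate.fc2.bias.data[:] = 30.0       # sigmoid saturates to ~1
    mh = rng.normal(size=(1, 16, 4, 4)).astype(np.float32)
    mc_ = rng.normal(size=(1, 16, 4, 4)).astype(np.float32)
    out_h, out_c, _ = gate(Tensor(mh), Tensor(mc_))
    np.testing.assert_allclose(out_h.data, mh, atol=1e-3)
    np.testing.assert_allclose(out_c.data, mc_, atol=1e-3)


def test_joint_gate_matches_concat_split_reference(rng):
    gate = JointGate(16, 8, rng)
    mh = rng.normal(size=(16, 5, 5))
    mc_ = rng.normal(size=(16, 5, 5))
    out_h, out_c, g = gate(Tensor(mh[None].astype(np.float32)),
                           Tensor(mc_[None].astype(np.float32)))
    exp_h, exp_c, exp_g = joint_gate_reference(
        mh, mc_, gate.fc1.weight.data, gate.fc1.bias.data,
        gate.fc2.weight.data, gate.fc2.bias.data)
    np.testing.assert_allclose(g.data[0], exp_g, atol=1e-5)
    np.testing.assert_allclose(out_h.data[0], exp_h, atol=1e-5)
    np.testing.assert_allclose(out_c.data[0], exp_c, atol=1e-5)


def test_channel_count_mismatch_raises(rng):
    gate = JointGate(16, 8, rng)
    with pytest.raises(ValueError, match="channel"):
        gate(Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32)),
             Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))


# ------------------------------------------------------------ full pipeline

def test_f_spec_has_length_32(encoder, rng):
    out = encoder(fake_images(rng), fake_images(rng))
    assert out.shape == (2, 32)


def test_swapping_nuclei_changes_the_embedding(encoder, rng):
    """Branch parameters are distinct, so the encoder is branch-asymmetric."""
    h, c = fake_images(rng, 1), fake_images(rng, 1)
    a = encoder.eval()(h, c).data
    b = encoder.eval()(c, h).data
    assert np.abs(a - b).max() > 1e-4


def test_forward_is_deterministic_in_eval_mode(encoder, rng):
    h, c = fake_images(rng, 1), fake_images(rng, 1)
    encoder.eval()
    np.testing.assert_array_equal(encoder(h, c).data, encoder(h, c).data)


def test_full_pipeline_matches_composed_reference(rng):
    """Plain-CBAM encoder on fixed inputs equals the composed oracles."""
    cfg = SpectralEncoderConfig(multiscale=False)
    enc = SpectralEncoder(cfg, np.random.default_rng(11)).eval()
    feats_h = rng.normal(size=(1, 2048, 4, 4)).astype(np.float32)
    feats_c = rng.normal(size=(1, 2048, 4, 4)).astype(np.float32)
    out = enc.forward_from_features(Tensor(feats_h), Tensor(feats_c)).data

    def reduce(feats, conv):
        w = conv.weight.data[:, :, 0, 0]
        return np.einsum("chw,oc->ohw", feats[0].astype(np.float64), w) + \
            conv.bias.data[:, None, None]

    ref_h, _, _ = cbam_reference(
        reduce(feats_h, enc.reduce_h),
        enc.cbam_h.channel.fc1.weight.data, enc.cbam_h.channel.fc1.bias.data,
        enc.cbam_h.channel.fc2.weight.data, enc.cbam_h.channel.fc2.bias.data,
        enc.cbam_h.spatial.conv.weight.data, enc.cbam_h.spatial.conv.bias.data)
    ref_c, _, _ = cbam_reference(
        reduce(feats_c, enc.reduce_c),
        enc.cbam_c.channel.fc1.weight.data, enc.cbam_c.channel.fc1.bias.data,
        enc.cbam_c.channel.fc2.weight.data, enc.cbam_c.channel.fc2.bias.data,
        enc.cbam_c.spatial.conv.weight.data, enc.cbam_c.spatial.conv.bias.data)
    cal_h, cal_c, _ = joint_gate_reference(
        ref_h, ref_c, enc.gate.fc1.weight.data, enc.gate.fc1.bias.data,
        enc.gate.fc2.weight.data, enc.gate.fc2.bias.data)
    f_spec = np.concatenate([cal_h.mean(axis=(1, 2)), cal_c.mean(axis=(1, 2))])
    # eval-mode output calibration with fresh running stats is the identity
    np.testing.assert_allclose(out[0], f_spec, atol=2e-4)


def test_tiny_backbone_ends_in_2048_channels(rng):
    bb = TinyBackbone(rng)
    with no_grad():
        out = bb(Tensor(rng.random((1, 3, 256, 256)).astype(np.float32)))
    assert out.shape[1] == 2048
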