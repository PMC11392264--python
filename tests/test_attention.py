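"""SSIA, DSFF and EFE block contracts: shapes, limits, and attention bounds."""

import numpy as np
import pytest

from polypseg.attention import DSFF, EFE, SSIA, SSIAMask, channel_attention
from polypseg.exceptions import ConfigError
from polypseg.grad import engine as E


def rand(shape, seed=0):
    return np.random.default_rng(seed).standard_normal(shape).astype(np.float32)


class TestSSIA:
    def test_mask_shape_follows_stem_resolution(self):
        ssia = SSIA(32, 512, rng=np.random.default_rng(0))
        mask = ssia(rand((1, 32, 128, 128)), rand((1, 512, 8, 8), 1))
        assert mask.logits.shape == (1, 1, 128, 128)
        assert mask.probability.shape == (1, 1, 128, 128)
        assert (mask.probability.data >= 0).all() and (mask.probability.data <= 1).all()

    def test_zero_head_weights_give_constant_probability(self):
        ssia = SSIA(8, 16, mid_channels=8, rng=np.random.default_rng(0))
        ssia.head.weight.data = np.zeros_like(ssia.head.weight.data)
        ssia.head.bias.data = np.full_like(ssia.head.bias.data, 0.3)
        mask = ssia(rand((2, 8, 16, 16)), rand((2, 16, 2, 2), 1))
        np.testing.assert_allclose(mask.logits.data, 0.3, atol=1e-6)
        assert np.ptp(mask.probability.data) < 1e-6

    def test_interpolation_preserves_constant_deep_branch(self):
        """τ on a constant field stays constant at any target size."""
        const = E.Tensor(np.full((1, 4, 3, 3), 2.5, dtype=np.float32))
        up = E.interpolate_bilinear(const, (24, 24))
        np.testing.assert_allclose(up.data, 2.5, atol=1e-6)

    def test_batch_mismatch_rejected(self):
        ssia = SSIA(8, 16, mid_channels=8)
        with pytest.raises(ConfigError):
            ssia(rand((1, 8, 16, 16)), rand((2, 16, 2, 2)))

    def test_no_cross_sample_leakage_in_eval_mode(self):
        ssia = SSIA(8, 16, mid_channels=8, rng=np.random.default_rng(3))
        ssia.eval()
        low = rand((3, 8, 16, 16), 4)
        high = rand((3, 16, 2, 2), 5)
        batched = ssia(low, high).probability.data
        for i in range(3):
            single = ssia(low[i:i + 1], high[i:i + 1]).probability.data
            np.testing.assert_allclose(batched[i:i + 1], single, atol=1e-6)


def make_mask(prob_value, shape=(1, 1, 8, 8)):
    prob = np.full(shape, prob_value, dtype=np.float32)
    logits = np.log(prob / (1 - prob)) if 0 < prob_value < 1 else np.zeros(shape)
    return SSIAMask(logits=E.Tensor(logits.astype(np.float32)), probability=E.Tensor(prob))


class TestDSFF:
    def test_output_shape_preserved(self):
        dsff = DSFF(256, rng=np.random.default_rng(0))
        out = dsff(rand((1, 256, 16, 16)), make_mask(0.7))
        assert out.shape == (1, 256, 16, 16)

    def test_saturated_mask_adds_unit_residual(self):
        """mask ≡ 1 ⇒ refinement convolution sees E + 1."""
        dsff = DSFF(4, rng=np.random.default_rng(1))
        e = rand((1, 4, 8, 8), 2)
        out = dsff(e, make_mask(1.0)).data
        expected = channel_attention(dsff.refine(E.Tensor(e + 1.0))).data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_null_mask_leaves_bias_response(self):
        """mask ≡ 0 ⇒ the convolution input is identically zero."""
        dsff = DSFF(4, rng=np.random.default_rng(1))
        out_a = dsff(rand((1, 4, 8, 8), 2), make_mask(0.0)).data
        out_b = dsff(rand((1, 4, 8, 8), 7), make_mask(0.0)).data
        np.testing.assert_allclose(out_a, out_b, atol=1e-6)  # input-independent

    def test_channel_attention_oracle(self):
        """A single constant nonzero channel is scaled by σ(c)."""
        c = 1.3
        x = np.zeros((1, 3, 4, 4), dtype=np.float64)
        x[0, 1] = c
        out = channel_attention(E.Tensor(x)).data
        sig = 1.0 / (1.0 + np.exp(-c))
        np.testing.assert_allclose(out[0, 1], c * sig, atol=1e-12)
        assert not out[0, 0].any() and not out[0, 2].any()

    def test_multichannel_mask_rejected(self):
        dsff = DSFF(4)
        bad = SSIAMask(logits=E.Tensor(np.zeros((1, 2, 4, 4))),
                       probability=E.Tensor(np.zeros((1, 2, 4, 4))))
        with pytest.raises(ConfigError):
            dsff(rand((1, 4, 8, 8)), bad)

    def test_degenerate_mode_without_mask(self):
        dsff = DSFF(4, rng=np.random.default_rng(5))
        e = rand((1, 4, 8, 8), 6)
        out = dsff(e, None).data
        expected = channel_attention(dsff.refine(E.Tensor(e))).data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_feature_residual_variant(self):
        dsff = DSFF(4, rng=np.random.default_rng(8), residual="feature")
        e = rand((1, 4, 8, 8), 9)
        out = dsff(e, make_mask(1.0)).data
        expected = channel_attention(dsff.refine(E.Tensor(e + e))).data
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestEFE:
    def test_branch_and_output_shapes(self):
        efe = EFE(512, 256, rng=np.random.default_rng(0))
        x = rand((1, 512, 8, 8))
        parts = [branch(E.Tensor(x)) for branch in efe.branches]
        assert all(p.shape == (1, 64, 8, 8) for p in parts)
        assert efe(x).shape == (1, 256, 8, 8)

    def test_identity_limit_reduces_to_trunk(self, monkeypatch):
        """Channel weights 1 and spatial map 0 leave the multi-kernel trunk."""
        efe = EFE(8, 8, reduction=2, rng=np.random.default_rng(1))
        x = rand((1, 8, 8, 8), 2)
        trunk = E.concat([b(E.Tensor(x)) for b in efe.branches], axis=1).data
        for gate in efe.channel_fcs:
            monkeypatch.setattr(
                gate, "forward",
                lambda t, _n=gate.fc2.weight.shape[0]:
                E.Tensor(np.ones((t.shape[0], _n, 1, 1), dtype=np.float32)))
        monkeypatch.setattr(
            efe, "spatial_attention",
            lambda t: E.Tensor(np.zeros((t.shape[0], 1, t.shape[2], t.shape[3]),
                                        dtype=np.float32)))
        np.testing.assert_allclose(efe(x).data, trunk, atol=1e-6)

    def test_spatial_submodule_constant_input(self):
        """Mean- and max-planes coincide on a constant field ⇒ the map is
        constant wherever the 7×7 window sees no zero padding."""
        efe = EFE(8, 8, reduction=2, rng=np.random.default_rng(3))
        const = np.full((1, 8, 12, 12), 0.4, dtype=np.float32)
        mean_plane = E.tmean(E.Tensor(const), axis=1, keepdims=True).data
        max_plane = E.tmax(E.Tensor(const), axis=1, keepdims=True).data
        np.testing.assert_allclose(mean_plane, max_plane, atol=1e-7)
        plane = efe.spatial_attention(const).data
        assert plane.shape == (1, 1, 12, 12)
        interior = plane[:, :, 3:-3, 3:-3]
        assert np.ptp(interior) < 1e-6

    def test_attention_term_bounded_between_zero_and_two(self):
        efe = EFE(16, 16, reduction=2, rng=np.random.default_rng(4))
        x = rand((2, 16, 8, 8), 5)
        channel_w = E.concat(
            [gate(branch(E.Tensor(x))) for gate, branch in
             zip(efe.channel_fcs, efe.branches)], axis=1).data
        spatial_w = efe.spatial_attention(x).data
        att = channel_w + spatial_w
        assert (att > 0).all() and (att < 2).all()

    def test_width_not_divisible_rejected(self):
        with pytest.raises(ConfigError):
            EFE(16, 18)

    def test_reduction_too_aggressive_rejected(self):
        with pytest.raises(ConfigError):
            EFE(16, 8, reduction=4)  # branch width 2 → hidden 0


@pytest.mark.parametrize("block_factory", [
    lambda: SSIA(8, 16, mid_channels=8, rng=np.random.default_rng(0)),
    lambda: DSFF(8, rng=np.random.default_rng(0)),
    lambda: EFE(8, 8, reduction=1, rng=np.random.default_rng(0)),
], ids=["ssia", "dsff", "efe"])
def test_gradients_reach_every_block_parameter(block_factory):
    block = block_factory()
    if isinstance(block, SSIA):
        out = block(E.Tensor(rand((2, 8, 16, 16), 1), requires_grad=True),
                    E.Tensor(rand((2, 16, 2, 2), 2), requires_grad=True)).logits
    elif isinstance(block, DSFF):
        prob = E.sigmoid(E.Tensor(rand((2, 1, 8, 8), 3)))
        out = block(E.Tensor(rand((2, 8, 16, 16), 4), requires_grad=True),
                    SSIAMask(logits=prob, probability=prob))
    else:
        out = block(E.Tensor(rand((8, 8, 8, 8), 5), requires_grad=True))
    E.tsum(E.mul(out, out)).backward()
    for name, p in block.named_parameters():
        assert p.grad is not None and np.any(p.grad), name
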