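"""Network building blocks and architecture contracts."""

import numpy as np
import pytest

from mdfnet import (
    ConfigurationError, FeatureShapes, MDFNet, ModelConfig, attention_pool,
    causal_dilated_conv, classification_loss, cmix_forward, load_checkpoint,
    save_checkpoint, temporal_attention_pool, ttcn_block,
)
from mdfnet.autodiff import Tensor
from oracles import attention_pool_direct, cmix_stage_direct, gelu_direct

TINY = ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4), dropout=0.2)
TINY_SHAPES = FeatureShapes(n_channels=3, n_time=8, n_freq=5, n_wavelet=7)


def _tiny_features(rng, batch=4):
    return {
        "time": rng.normal(size=(batch, 3, 8)),
        "freq": np.abs(rng.normal(size=(batch, 3, 5))),
        "wavelet": rng.normal(size=(batch, 3, 7)),
    }


class TestCausalConv:
    def test_current_tap_identity_kernel(self, rng):
        x = rng.normal(size=(3, 10))
        w = np.zeros((3, 3, 3))
        for c in range(3):
            w[c, c, -1] = 1.0  # last tap = current time step
        np.testing.assert_allclose(causal_dilated_conv(x, w, dilation=2), x)

    @pytest.mark.parametrize("dilation", [1, 2, 4])
    def test_causality_probe(self, rng, dilation):
        x = rng.normal(size=(2, 16))
        w = rng.normal(size=(2, 2, 3))
        y0 = causal_dilated_conv(x, w, dilation)
        t0 = 9
        x2 = x.copy()
        x2[:, t0:] += rng.normal(size=(2, 16 - t0))
        y1 = causal_dilated_conv(x2, w, dilation)
        assert np.array_equal(y0[:, :t0], y1[:, :t0])  # bit-exact before t0
        assert not np.allclose(y0[:, t0:], y1[:, t0:])

    def test_output_length_preserved(self, rng):
        y = causal_dilated_conv(rng.normal(size=(2, 11)), rng.normal(size=(5, 2, 3)), 4)
        assert y.shape == (5, 11)

    def test_default_dilations_double_per_block(self):
        assert ModelConfig().dilations() == (1, 2, 4)


class TestTTCNBlock:
    def test_zero_conv_identity_residual_is_gelu(self, rng):
        x = rng.normal(size=(4, 9))
        conv_w = np.zeros((4, 4, 3))
        y = ttcn_block(x, conv_w, np.zeros(4), None, None, dilation=1)
        np.testing.assert_allclose(y, np.vectorize(gelu_direct)(x), atol=1e-12)

    def test_channel_projection_residual(self, rng):
        x = rng.normal(size=(3, 6))
        y = ttcn_block(x, rng.normal(size=(5, 3, 3)), rng.normal(size=5),
                       rng.normal(size=(5, 3)), rng.normal(size=5), dilation=2)
        assert y.shape == (5, 6)

    def test_eval_determinism_and_seeded_dropout(self, rng):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=0)
        feats = _tiny_features(rng)
        a, _ = model.forward(feats)
        b, _ = model.forward(feats)
        assert np.array_equal(a.data, b.data)
        d1, _ = model.forward(feats, training=True, rng=np.random.default_rng(5))
        d2, _ = model.forward(feats, training=True, rng=np.random.default_rng(5))
        d3, _ = model.forward(feats, training=True, rng=np.random.default_rng(6))
        assert np.array_equal(d1.data, d2.data)
        assert not np.array_equal(d1.data, d3.data)


class TestAttentionPooling:
    def test_uniform_weights_for_constant_columns(self):
        y = np.tile(np.array([[1.0], [2.0], [-0.5]]), (1, 6))
        _, alpha = temporal_attention_pool(y, np.array([0.3, -1.2, 0.7]))
        np.testing.assert_allclose(alpha, np.full(6, 1 / 6), atol=1e-12)

    def test_single_column(self, rng):
        y = rng.normal(size=(4, 1))
        pooled, alpha = temporal_attention_pool(y, rng.normal(size=4))
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(pooled, y[:, 0])

    @pytest.mark.parametrize("shape", [(4, 5), (3, 3), (5, 2)])
    def test_matches_brute_force(self, rng, shape):
        y = rng.normal(size=shape)
        w = rng.normal(size=shape[0])
        pooled, alpha = temporal_attention_pool(y, w)
        pooled_o, alpha_o = attention_pool_direct(y, w)
        np.testing.assert_allclose(pooled, pooled_o, atol=1e-9)
        np.testing.assert_allclose(alpha, alpha_o, atol=1e-9)

    def test_coefficient_axis_variant_same_math(self, rng):
        m = rng.normal(size=(3, 4))
        u = rng.normal(size=3)
        np.testing.assert_array_equal(attention_pool(m, u)[1],
                                      temporal_attention_pool(m, u)[1])

    def test_nonfinite_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            temporal_attention_pool(np.full((2, 3), np.inf), rng.normal(size=2))


class TestCmix:
    def test_zero_weights_identity(self, rng):
        x = rng.normal(size=(3, 5))
        out = cmix_forward(x, np.zeros((5, 5)), np.zeros(5), np.zeros((3, 3)), np.zeros(3))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(3, 5))
        tw, tb = rng.normal(size=(5, 5)), rng.normal(size=5)
        cw, cb = rng.normal(size=(3, 3)), rng.normal(size=3)
        np.testing.assert_allclose(cmix_forward(x, tw, tb, cw, cb),
                                   cmix_stage_direct(x, tw, tb, cw, cb), atol=1e-9)

    def test_shape_preserved(self, rng):
        x = rng.normal(size=(4, 6))
        out = cmix_forward(x, rng.normal(size=(6, 6)), rng.normal(size=6),
                           rng.normal(size=(4, 4)), rng.normal(size=4))
        assert out.shape == x.shape


class TestForward:
    def test_branch_toggle_isolation(self, rng):
        model = MDFNet(ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4),
                                   branches_enabled=("T",)), TINY_SHAPES, rng_seed=1)
        feats = _tiny_features(rng)
        base, _ = model.forward(feats)
        perturbed = dict(feats)
        perturbed["freq"] = feats["freq"] + 100.0
        perturbed["wavelet"] = feats["wavelet"] * -3.0
        out, _ = model.forward(perturbed)
        assert np.array_equal(base.data, out.data)

    @pytest.mark.parametrize("branches", [("T",), ("T", "F"), ("T", "W"), ("T", "F", "W")])
    def test_ablation_configs_build_and_run(self, rng, branches):
        model = MDFNet(ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4),
                                   branches_enabled=branches), TINY_SHAPES, rng_seed=1)
        logits, attn = model.forward(_tiny_features(rng))
        assert logits.shape == (4, 2)
        assert ("freq" in attn) == ("F" in branches)
        assert ("wavelet" in attn) == ("W" in branches)

    def test_fusion_input_is_three_times_last_channel_dim(self):
        model = MDFNet(ModelConfig(), FeatureShapes(), rng_seed=0)
        assert model.params["fusion_w"].shape == (2, 192)

    def test_missing_feature_for_enabled_branch_rejected(self, rng):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=0)
        feats = _tiny_features(rng)
        del feats["wavelet"]
        with pytest.raises(ConfigurationError):
            model.forward(feats)

    def test_attention_weights_on_simplex(self, rng):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=2)
        _, attn = model.forward(_tiny_features(rng))
        for key, val in attn.items():
            assert (val >= 0).all(), key
            np.testing.assert_allclose(val.sum(axis=-1), 1.0, atol=1e-6)

    def test_gradient_flows_to_every_parameter(self, rng):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=3)
        logits, _ = model.forward(_tiny_features(rng))
        loss = classification_loss(logits, np.array([0, 1, 0, 1]))
        loss.backward()
        for name, p in model.params.items():
            assert p.grad is not None and np.abs(p.grad).sum() > 0, name

    def test_time_shuffle_changes_temporal_branch_only_structurally(self, rng):
        # TTCN is order-sensitive; the spectrum-fed branch sees the same bins
        model = MDFNet(ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4),
                                   branches_enabled=("T",)), TINY_SHAPES, rng_seed=4)
        feats = _tiny_features(rng)
        shuffled = dict(feats)
        shuffled["time"] = feats["time"][:, :, ::-1].copy()
        a, _ = model.forward(feats)
        b, _ = model.forward(shuffled)
        assert not np.allclose(a.data, b.data)


class TestLoss:
    def test_uniform_logits_equal_weights_ln2(self):
        logits = Tensor(np.zeros((6, 2)))
        loss = classification_loss(logits, np.array([0, 1, 0, 1, 1, 0]),
                                   class_weights=(1.0, 1.0), smoothing=0.0)
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_prediction_loss_vanishes(self):
        logits = Tensor(np.array([[30.0, -30.0], [-30.0, 30.0]]))
        loss = classification_loss(logits, np.array([0, 1]),
                                   class_weights=(1.0, 1.0), smoothing=0.0)
        assert float(loss.data) < 1e-8

    def test_smoothing_does_not_change_uniform_prediction_loss(self):
        logits = Tensor(np.zeros((4, 2)))
        loss = classification_loss(logits, np.array([0, 1, 1, 0]),
                                   class_weights=(1.0, 1.0), smoothing=0.1)
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-12)

    def test_class_weighting_reweights_samples(self):
        # one confident-wrong PD sample weighs more under w1 = 1.2
        logits = Tensor(np.array([[2.0, -2.0]]))
        lw = classification_loss(logits, np.array([1]), class_weights=(0.8, 1.2),
                                 smoothing=0.0)
        lu = classification_loss(logits, np.array([1]), class_weights=(1.0, 1.0),
                                 smoothing=0.0)
        # weighted mean over a single sample normalizes the weight away
        assert float(lw.data) == pytest.approx(float(lu.data))

    def test_invalid_smoothing_rejected(self):
        with pytest.raises(ConfigurationError):
            classification_loss(Tensor(np.zeros((1, 2))), np.array([0]), smoothing=1.0)


class TestCheckpoint:
    def test_reload_is_bit_stable(self, tmp_path, rng):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=9)
        feats = _tiny_features(rng)
        ref, _ = model.forward(feats)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        out, _ = loaded.forward(feats)
        assert np.array_equal(ref.data, out.data)
        assert loaded.config == model.config

    def test_mismatched_state_rejected(self, tmp_path):
        model = MDFNet(TINY, TINY_SHAPES, rng_seed=9)
        other = MDFNet(TINY, FeatureShapes(n_channels=3, n_time=9, n_freq=5,
                                           n_wavelet=7), rng_seed=9)
        with pytest.raises(ConfigurationError):
            model.load_state_dict(other.state_dict())
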