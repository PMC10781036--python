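import dataclasses

import numpy as np
import pytest

from ppg_bioauth import nn
from ppg_bioauth.model import (CVTBranch, ChannelAttention, ConvMixerBranch,
                               Fuse, Head, MixerBlock, ModelConfig,
                               ResidualUnit, build_model, channel_attention,
                               classify, convmixer_block, convmixer_features,
                               convmixer_stem, cvt_features, desk_config,
                               fuse, paper_full_config, residual_unit)
from ppg_bioauth.nn import Tensor


def _image(side, seed=0):
    return np.random.default_rng(seed).random((side, side)).astype(np.float32)


class TestConfig:
    def test_invalid_configs_name_the_field(self):
        with pytest.raises(ValueError, match="n_classes"):
            ModelConfig(n_classes=1)
        with pytest.raises(ValueError, match="cvt_channel_plan"):
            ModelConfig(cvt_conv_layers=3)
        with pytest.raises(ValueError, match="n_heads"):
            ModelConfig(token_dim=30, n_heads=4)

    def test_paper_full_profile_dimensions(self):
        cfg = paper_full_config()
        assert cfg.cvt_conv_layers == 17 and cfg.n_pool == 5
        assert cfg.n_heads == 8 and cfg.n_tokens == 7
        assert cfg.patch_size == 5 and cfg.hidden_dim == 32 and cfg.mixer_depth == 7


class TestConvMixerStem:
    def test_paper_shape(self):
        """128x128 image with 5x5 stride-5 patch embedding -> 25x25 map."""
        cfg = dataclasses.replace(
            paper_full_config(), cvt_conv_layers=1, cvt_channel_plan=(4,),
            n_pool=1, n_tokens=1, token_dim=16, n_heads=2, mlp_hidden=8)
        z0 = convmixer_stem(_image(128), cfg)
        assert z0.values.shape == (1, 32, 25, 25)

    def test_divisible_shape(self, tiny_model_cfg):
        z0 = convmixer_stem(_image(16), tiny_model_cfg)
        assert z0.values.shape == (1, 8, 4, 4)

    def test_single_patch_boundary(self):
        cfg = ModelConfig(image_side=16, patch_size=16, hidden_dim=8,
                          mixer_depth=1, cvt_conv_layers=1, cvt_channel_plan=(4,),
                          n_pool=1, n_tokens=1, token_dim=16, n_heads=2,
                          mlp_hidden=8, n_classes=2)
        z0 = convmixer_stem(_image(16), cfg)
        assert z0.values.shape == (1, 8, 1, 1)


class TestMixerBlock:
    def test_residual_identity_when_depthwise_zeroed(self, tiny_model_cfg):
        """With the depthwise path forced to zero the block reduces to
        BN(GELU(0)) + input = input (eval mode, zero-initialized BN shift)."""
        rng = np.random.default_rng(0)
        block = MixerBlock(8, 3, rng)
        block.eval()
        block.dw.w.data[:] = 0
        block.dw.b.data[:] = 0
        z = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        out = block.spatial(Tensor(z)).data
        np.testing.assert_allclose(out, z, atol=1e-6)

    def test_shape_preserved(self, tiny_model_cfg):
        z = np.random.default_rng(1).normal(size=(2, 8, 5, 5)).astype(np.float32)
        out = convmixer_block(z, tiny_model_cfg)
        assert out.values.shape == (2, 8, 5, 5)

    def test_channel_mismatch_rejected(self, tiny_model_cfg):
        z = np.zeros((1, 5, 4, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="channels"):
            convmixer_block(z, tiny_model_cfg)

    def test_deep_stack_stays_finite(self, tiny_model_cfg):
        rng = np.random.default_rng(2)
        block = MixerBlock(8, 3, rng)
        block.eval()
        z = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        for _ in range(7):
            z = block(z)
        assert np.all(np.isfinite(z.data))


class TestConvMixerFeatures:
    def test_output_is_2h(self, tiny_model_cfg):
        out = convmixer_features(_image(16), tiny_model_cfg)
        assert out.values.shape == (1, 16)  # 2h for h=8

    def test_zero_fused_map_pools_to_zero(self):
        assert float(Tensor(np.zeros((1, 4, 2, 2))).gelu().mean().data) == 0.0

    def test_uniform_attention_is_token_mean(self, tiny_model_cfg):
        """With forced-uniform attention weights the pooled vector equals
        plain averaging and is invariant to token permutation."""
        rng = np.random.default_rng(3)
        att = nn.MultiHeadSelfAttention(8, 2, rng)
        att.eval()
        att.force_uniform = True
        x = rng.normal(size=(1, 6, 8)).astype(np.float32)
        pooled = att(Tensor(x)).data.mean(axis=1)
        perm = rng.permutation(6)
        pooled_p = att(Tensor(x[:, perm])).data.mean(axis=1)
        np.testing.assert_allclose(pooled, pooled_p, atol=1e-6)


class TestCVTBranch:
    def test_desk_output_dimension(self):
        cfg = desk_config(n_classes=8)
        out = cvt_features(_image(64), cfg)
        assert out.values.shape == (1, 64)

    def test_deterministic_across_builds(self, tiny_model_cfg):
        img = _image(16, seed=5)
        a = cvt_features(img, tiny_model_cfg).values
        b = cvt_features(img, tiny_model_cfg).values
        np.testing.assert_array_equal(a, b)

    def test_zero_image_finite(self, tiny_model_cfg):
        out = cvt_features(np.zeros((16, 16), np.float32), tiny_model_cfg)
        assert np.all(np.isfinite(out.values))


class TestFuse:
    def test_alpha_zero_gives_cvt_path(self, tiny_model_cfg):
        cfg = dataclasses.replace(tiny_model_cfg, alpha=0.0,
                                  alpha_learnable=False)
        a = np.random.default_rng(0).normal(size=(2, 8)).astype(np.float32)
        b = np.random.default_rng(1).normal(size=(2, 8)).astype(np.float32)
        out = fuse(a, b, cfg)
        np.testing.assert_array_equal(out.values, a)

    def test_zero_convmixer_passthrough(self, tiny_model_cfg):
        cfg = dataclasses.replace(tiny_model_cfg, alpha=1.0)
        a = np.random.default_rng(2).normal(size=(1, 8)).astype(np.float32)
        out = fuse(a, np.zeros_like(a), cfg)
        np.testing.assert_array_equal(out.values, a)

    def test_arithmetic(self, tiny_model_cfg):
        cfg = dataclasses.replace(tiny_model_cfg, alpha=2.0)
        ones = np.ones((1, 8), dtype=np.float32)
        out = fuse(ones, ones, cfg)
        np.testing.assert_array_equal(out.values, 3 * ones)

    def test_dimension_mismatch_projected(self, tiny_model_cfg):
        a = np.ones((1, 8), np.float32)
        b = np.ones((1, 12), np.float32)
        out = fuse(a, b, tiny_model_cfg)
        assert out.values.shape == (1, 12)


class TestResidualUnit:
    def test_zeroed_transform_is_relu(self, tiny_model_cfg):
        unit = ResidualUnit(8, tiny_model_cfg)
        unit.lin.w.data[:] = 0
        unit.lin.b.data[:] = 0
        x = np.random.default_rng(0).normal(size=(2, 8)).astype(np.float32)
        out = unit(Tensor(x)).data
        np.testing.assert_allclose(out, np.maximum(x, 0), atol=1e-7)

    def test_zero_input_zero_output(self, tiny_model_cfg):
        unit = ResidualUnit(8, tiny_model_cfg)
        unit.lin.b.data[:] = 0
        out = residual_unit(np.zeros((1, 8), np.float32), tiny_model_cfg,
                            module=unit)
        np.testing.assert_array_equal(out.values, 0)

    def test_nonnegative_output(self, tiny_model_cfg):
        x = np.random.default_rng(1).normal(size=(4, 8)).astype(np.float32)
        assert np.all(residual_unit(x, tiny_model_cfg).values >= 0)


class TestChannelAttention:
    def test_attenuation_bound(self, tiny_model_cfg):
        x = np.random.default_rng(0).normal(size=(3, 8)).astype(np.float32)
        out = channel_attention(x, tiny_model_cfg)
        assert np.all(np.abs(out.values) <= np.abs(x))

    def test_forced_half_weights(self, tiny_model_cfg):
        mod = ChannelAttention(8, tiny_model_cfg)
        mod.fc1.w.data[:] = 0
        mod.fc1.b.data[:] = 0
        mod.fc2.w.data[:] = 0
        mod.fc2.b.data[:] = 0  # sigmoid(0) = 0.5
        x = np.random.default_rng(1).normal(size=(2, 8)).astype(np.float32)
        out = mod(Tensor(x)).data
        np.testing.assert_allclose(out, 0.5 * x, atol=1e-7)

    def test_zero_input_zero_output(self, tiny_model_cfg):
        out = channel_attention(np.zeros((1, 8), np.float32), tiny_model_cfg)
        np.testing.assert_array_equal(out.values, 0)


class TestClassify:
    def test_probabilities_normalized(self, tiny_model_cfg):
        x = np.random.default_rng(0).normal(size=(5, 16)).astype(np.float32)
        p = classify(x, tiny_model_cfg)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p > 0) & (p < 1))

    def test_softmax_symmetry_and_argmax(self):
        p = nn.softmax(Tensor(np.array([[0.0, 0.0]])), axis=-1).data
        np.testing.assert_allclose(p, [[0.5, 0.5]], atol=1e-7)
        p = nn.softmax(Tensor(np.array([[10.0, 0.0, 0.0]])), axis=-1).data
        assert p.argmax() == 0


class TestBuildModel:
    def test_deterministic_parameters(self, tiny_model_cfg):
        a = build_model(tiny_model_cfg).state_vector()
        b = build_model(tiny_model_cfg).state_vector()
        np.testing.assert_array_equal(a, b)

    def test_forward_shape(self, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        batch = np.random.default_rng(0).random((4, 16, 16)).astype(np.float32)
        probs = model.predict_proba(batch)
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_desk_parameter_budget(self):
        model = build_model(desk_config(n_classes=8))
        assert model.n_parameters() < 2_000_000

    def test_paper_full_profile_builds_and_runs(self):
        model = build_model(paper_full_config(n_classes=35))
        assert 30e6 < model.n_parameters() < 50e6
        img = np.random.default_rng(0).random((1, 128, 128)).astype(np.float32)
        p = model.predict_proba(img)
        assert p.shape == (1, 35)
        np.testing.assert_allclose(p.sum(), 1.0, atol=1e-6)

    def test_alpha_zero_equals_cvt_only_ablation(self, tiny_model_cfg):
        cfg = dataclasses.replace(tiny_model_cfg, alpha=0.0,
                                  alpha_learnable=False)
        img = _image(16, seed=9)
        full = build_model(cfg)
        ablated = build_model(cfg, use_convmixer=False)
        np.testing.assert_allclose(full.predict_proba(img),
                                   ablated.predict_proba(img), atol=1e-7)

    def test_forward_finite_across_seeds(self, tiny_model_cfg):
        rng = np.random.default_rng(0)
        for seed in range(20):
            cfg = dataclasses.replace(tiny_model_cfg, seed=seed)
            model = build_model(cfg)
            img = rng.random((2, 16, 16)).astype(np.float32)
            assert np.all(np.isfinite(model.predict_proba(img)))

    def test_feature_map_roles_present(self, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        maps = model.feature_maps(_image(16))
        for role in ("Z0", "CVT_map", "ConvMixer_map", "Dense_Features_map",
                     "Output", "W", "Features"):
            assert maps[role].role == role
        w = maps["W"].values
        assert np.all((w > 0) & (w < 1))

    def test_gradient_step_reduces_loss(self, tiny_model_cfg):
        """One optimizer step on one batch must not increase its loss by
        more than 10%."""
        from ppg_bioauth.nn.autograd import log_softmax

        rng = np.random.default_rng(0)
        x = rng.random((8, 1, 16, 16)).astype(np.float32)
        y = np.zeros((8, 3), np.float32)
        y[np.arange(8), rng.integers(0, 3, 8)] = 1

        for seed in range(5):
            cfg = dataclasses.replace(tiny_model_cfg, seed=seed)
            model = build_model(cfg)
            model.train()
            opt = nn.Adam(model.parameters(), lr=1e-3)

            def batch_loss():
                return -(Tensor(y) * log_softmax(model.logits(Tensor(x)), -1)
                         ).sum() * (1 / 8)

            l0 = batch_loss()
            model.zero_grad()
            l0.backward()
            opt.step()
            l1 = batch_loss()
            assert float(l1.data) <= float(l0.data) * 1.10
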