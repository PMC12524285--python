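"""Network structure: token counts, closed-form limits, equivariances,
parameter counting, and training determinism."""

import numpy as np
import pytest

from satsn._autograd import Tensor
from satsn.net import (TINY, SatsnArchConfig, SatsnModel, count_parameters,
                       load_checkpoint, save_checkpoint, train_satsn)
from satsn.nn import MultiHeadSelfAttention


SMALL = SatsnArchConfig(T=4, alpha=2, slow_res=32, fast_res=32,
                        tubelet=(2, 16, 16), embed_dim=64, vit_depth=2,
                        n_heads=4, fast_channels=(8, 16), lateral_after=(1, 2))


class TestTubeletEmbed:
    def test_token_count(self):
        m = SatsnModel(SMALL, seed=0)
        frames = np.zeros((1, 4, 32, 32, 3), dtype=np.float32)
        tokens = m.tubelet_embed(frames)
        # (4/2) * (32/16) * (32/16) = 8 tokens of dim 64
        assert tokens.shape == (1, 8, 64)

    def test_zero_frames_give_positional_embeddings(self):
        m = SatsnModel(SMALL, seed=0)
        tokens = m.tubelet_embed(np.zeros((2, 4, 32, 32, 3), dtype=np.float32))
        assert np.allclose(tokens.data[0], m.pos_emb.data, atol=1e-7)
        assert np.allclose(tokens.data[1], m.pos_emb.data, atol=1e-7)

    def test_batch_permutation_equivariance(self, rng):
        m = SatsnModel(SMALL, seed=0)
        x = rng.normal(size=(3, 4, 32, 32, 3)).astype(np.float32)
        out = m.tubelet_embed(x).data
        out_perm = m.tubelet_embed(x[[2, 0, 1]]).data
        assert np.allclose(out[[2, 0, 1]], out_perm)

    def test_indivisible_input_reports_padding(self):
        m = SatsnModel(SMALL, seed=0)
        with pytest.raises(ValueError, match="pad"):
            m.tubelet_embed(np.zeros((1, 3, 32, 32, 3), dtype=np.float32))


class TestVitEncode:
    def test_attention_rows_sum_to_one(self, rng):
        attn = MultiHeadSelfAttention(32, 4, rng)
        x = Tensor(rng.normal(size=(2, 7, 32)))
        w = attn.attention_weights(x).data
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_depth_zero_is_identity(self, rng):
        m = SatsnModel(SMALL, seed=0)
        tokens = Tensor(rng.normal(size=(1, 8, 64)))
        out = m.vit_encode(tokens, depth=0)
        assert np.array_equal(out.data, tokens.data)

    def test_single_token_closed_form(self, rng):
        """With one token the softmax is a 1x1 matrix equal to 1, so the
        attention output is the projected value vector."""
        attn = MultiHeadSelfAttention(16, 2, rng)
        x = rng.normal(size=(1, 1, 16))
        out = attn(Tensor(x)).data
        qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
        v = qkv[:, :, 32:]
        expected = v @ attn.proj.weight.data + attn.proj.bias.data
        assert np.allclose(out, expected, atol=1e-10)


class TestFastPathway:
    def test_stage_shapes(self, rng):
        cfg = SatsnArchConfig(T=2, alpha=4, slow_res=32, fast_res=64,
                              tubelet=(2, 8, 8), embed_dim=64, vit_depth=2,
                              n_heads=4, fast_channels=(8, 16), lateral_after=(1, 2))
        m = SatsnModel(cfg, seed=0)
        x = rng.normal(size=(1, 8, 64, 64, 3)).astype(np.float32)
        feats = m.fast_pathway(x)
        assert feats[0].shape == (1, 8, 8, 32, 32)
        assert feats[1].shape == (1, 8, 16, 16, 16)

    def test_zero_ta_weights_halve_stages(self, rng):
        m = SatsnModel(SMALL, seed=0)
        for ta in m.ta_blocks:
            ta.W_n.data[:] = 0.0
            ta.W_m.data[:] = 0.0
        x = rng.normal(size=(1, 8, 32, 32, 3)).astype(np.float32)
        with_ta = m.fast_pathway(x, apply_ta=True)
        without = m.fast_pathway(x, apply_ta=False)
        # TA is applied per stage, so stage s carries a (1/2)^(s+1) factor
        assert np.allclose(with_ta[0].data, 0.5 * without[0].data, atol=1e-6)
        assert np.allclose(with_ta[1].data, 0.25 * without[1].data, atol=1e-6)

    def test_positive_homogeneity_without_biases(self, rng):
        """Bias-free conv stages with ReLU scale linearly on positive scaling."""
        m = SatsnModel(SMALL, seed=0)
        for conv in m.fast_convs:
            conv.bias.data[:] = 0.0
        for ta in m.ta_blocks:
            ta.W_n.data[:] = 0.0
            ta.W_m.data[:] = 0.0
        x = rng.normal(size=(1, 8, 32, 32, 3)).astype(np.float32)
        f1 = m.fast_pathway(x)[-1].data
        f2 = m.fast_pathway(2.0 * x)[-1].data
        assert np.allclose(f2, 2.0 * f1, rtol=1e-5, atol=1e-6)

    def test_too_small_input_rejected(self):
        m = SatsnModel(SMALL, seed=0)
        with pytest.raises(ValueError, match="downsampling"):
            m.fast_pathway(np.zeros((1, 8, 2, 2, 3), dtype=np.float32))


class TestLateralFusion:
    def test_zero_projection_leaves_tokens(self, rng):
        m = SatsnModel(SMALL, seed=0)
        m.laterals[0].weight.data[:] = 0.0
        tokens = Tensor(rng.normal(size=(1, 8, 64)))
        fast = Tensor(rng.normal(size=(1, 8, 8, 16, 16)))
        fused = m.lateral_fuse(fast, tokens, 0)
        assert np.allclose(fused.data, tokens.data)
        assert fused.shape == tokens.shape

    def test_projection_linearity(self, rng):
        m = SatsnModel(SMALL, seed=0)
        tokens = Tensor(rng.normal(size=(1, 8, 64)))
        a = rng.normal(size=(1, 8, 8, 16, 16))
        b = rng.normal(size=(1, 8, 8, 16, 16))
        f_ab = m.lateral_fuse(Tensor(a + b), tokens, 0).data
        f_a = m.lateral_fuse(Tensor(a), tokens, 0).data
        f_b = m.lateral_fuse(Tensor(b), tokens, 0).data
        assert np.allclose(f_ab, f_a + f_b - tokens.data, atol=1e-8)


class TestForward:
    def test_probability_simplex(self, rng):
        m = SatsnModel(SMALL, seed=1)
        slow = rng.normal(size=(3, 4, 32, 32, 3)).astype(np.float32)
        fast = rng.normal(size=(3, 8, 32, 32, 3)).astype(np.float32)
        p = m.predict_proba(slow, fast)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_determinism(self, rng):
        m = SatsnModel(SMALL, seed=1)
        slow = rng.normal(size=(2, 4, 32, 32, 3)).astype(np.float32)
        fast = rng.normal(size=(2, 8, 32, 32, 3)).astype(np.float32)
        assert np.array_equal(m.predict_proba(slow, fast), m.predict_proba(slow, fast))

    def test_head_permutation_equivariance(self, rng):
        m = SatsnModel(SMALL, seed=1)
        # make the head non-degenerate before permuting
        m.head.weight.data[:] = rng.normal(size=m.head.weight.shape)
        m.head.bias.data[:] = rng.normal(size=m.head.bias.shape)
        slow = rng.normal(size=(2, 4, 32, 32, 3)).astype(np.float32)
        fast = rng.normal(size=(2, 8, 32, 32, 3)).astype(np.float32)
        p = m.predict_proba(slow, fast)
        perm = [2, 0, 3, 1]
        m.head.weight.data = m.head.weight.data[:, perm]
        m.head.bias.data = m.head.bias.data[perm]
        p_perm = m.predict_proba(slow, fast)
        assert np.allclose(p_perm, p[:, perm], atol=1e-6)


class TestParameterCount:
    @pytest.mark.parametrize("cfg", [SMALL, TINY])
    def test_matches_hand_formula(self, cfg):
        tt, th, tw = cfg.tubelet
        D, H = cfg.embed_dim, int(cfg.embed_dim * cfg.mlp_ratio)
        n_tok = (cfg.T // tt) * (cfg.slow_res // th) * (cfg.slow_res // tw)
        patch = (tt * th * tw * 3) * D + D
        pos = n_tok * D
        block = (2 * D) + (D * 3 * D + 3 * D) + (D * D + D) \
            + (2 * D) + (D * H + H) + (H * D + D)
        vit = cfg.vit_depth * block
        Tf = cfg.T * cfg.alpha
        kt, kh, kw = cfg.fast_kernel
        fast = 0
        c_in = 3
        for c in cfg.fast_channels:
            fast += c * c_in * kt * kh * kw + c           # conv + bias
            fast += 2 * (Tf // cfg.ta_r) * Tf             # TA bottleneck
            fast += c * D                                  # lateral projection
            c_in = c
        head_in = D + cfg.fast_channels[-1]
        head = 2 * head_in + head_in * cfg.num_classes + cfg.num_classes
        assert count_parameters(cfg) == patch + pos + vit + fast + head


class TestTraining:
    def _toy_dataset(self, rng, n=6):
        return [(rng.normal(size=(4, 32, 32, 3)).astype(np.float32),
                 rng.normal(size=(8, 32, 32, 3)).astype(np.float32),
                 int(i % 4)) for i, _ in enumerate(range(n))]

    def test_same_seed_same_loss_curve(self, rng):
        data = self._toy_dataset(rng)
        _m1, log1 = train_satsn(data, arch=SMALL, seed=3, epochs=2, batch_size=3,
                                augment=False)
        _m2, log2 = train_satsn(data, arch=SMALL, seed=3, epochs=2, batch_size=3,
                                augment=False)
        assert log1 == log2

    def test_single_sample_overfit(self, rng):
        data = self._toy_dataset(rng, n=1)
        _m, log = train_satsn(data, arch=SMALL, seed=0, epochs=30, batch_size=1,
                              learning_rate=0.05, augment=False, warmup_epochs=0,
                              cosine_decay=False)
        assert log[-1]["loss"] < log[0]["loss"]
        assert log[-1]["loss"] < 0.1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_satsn([], arch=SMALL, seed=0, epochs=1)

    def test_augmentation_keeps_range(self, rng):
        from satsn.net import augment_sample
        slow = rng.uniform(-0.5, 0.5, size=(4, 32, 32, 3)).astype(np.float32)
        fast = rng.uniform(-0.5, 0.5, size=(8, 32, 32, 3)).astype(np.float32)
        s, f = augment_sample(slow, fast, np.random.default_rng(0))
        assert s.shape == slow.shape and f.shape == fast.shape
        assert s.min() >= -0.5 and s.max() <= 0.5


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        m = SatsnModel(SMALL, seed=2)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        slow = rng.normal(size=(1, 4, 32, 32, 3)).astype(np.float32)
        fast = rng.normal(size=(1, 8, 32, 32, 3)).astype(np.float32)
        assert np.array_equal(m.predict_proba(slow, fast),
                              m2.predict_proba(slow, fast))

    def test_config_mismatch_rejected(self, tmp_path):
        m = SatsnModel(SMALL, seed=2)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        with pytest.raises(ValueError, match="does not match"):
            load_checkpoint(path, expect_config=TINY)
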