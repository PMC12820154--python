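"""Backbone: parameter accounting, patch embedding, attention, gradients."""

import numpy as np
import pytest

from fedlora import ViTConfig, build_model, count_parameters, embed_patches, encoder_block, forward_logits
from fedlora import autodiff
from fedlora.errors import ConfigurationError, ShapeError
from fedlora.vit import base_parameter_count, load_checkpoint, patchify, save_checkpoint


class TestParameterAccounting:
    def test_deit_tiny_total_is_5_524_802(self, deit_tiny):
        # closed-form sum: patch proj 147,648 + cls 192 + pos 37,824
        # + 12 x 444,864 + final LN 384 + head 386
        assert count_parameters(deit_tiny) == 5_524_802
        assert base_parameter_count(deit_tiny.config) == 5_524_802

    def test_closed_form_matches_enumeration_for_odd_config(self):
        cfg = ViTConfig(image_size=48, patch_size=16, embed_dim=24, depth=3, num_heads=2)
        model = build_model(cfg, seed=0)
        assert count_parameters(model) == base_parameter_count(cfg)

    def test_head_parameter_count(self, deit_tiny):
        assert deit_tiny.params["head.weight"].size + deit_tiny.params["head.bias"].size == 386

    def test_single_patch_config_has_two_tokens(self):
        cfg = ViTConfig(image_size=16, patch_size=16)
        assert cfg.num_patches == 1
        assert cfg.seq_len == 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ViTConfig(image_size=224, patch_size=15)
        with pytest.raises(ConfigurationError):
            ViTConfig(embed_dim=190, num_heads=3)


class TestPatchEmbedding:
    def test_token_count_and_dim(self, deit_tiny, rng):
        img = rng.random((224, 224, 3), dtype=np.float32)
        z = embed_patches(img, deit_tiny)
        assert z.shape == (1, 197, 192)

    def test_zero_weights_give_positional_embedding(self, tiny_cfg, tiny_model):
        m = tiny_model.copy()
        m.params["patch_embed.weight"][:] = 0
        m.params["patch_embed.bias"][:] = 0
        m.params["cls_token"][:] = 0
        z = embed_patches(np.zeros((16, 16, 3), dtype=np.float32), m)
        np.testing.assert_array_equal(z[0], m.params["pos_embed"])

    def test_patchify_matches_naive_double_loop(self, rng):
        cfg = ViTConfig(image_size=32, patch_size=16, embed_dim=8, depth=1, num_heads=2)
        img = rng.random((32, 32, 3))
        got = patchify(img, cfg)[0]
        P = cfg.patch_size
        expected = []
        for by in range(2):
            for bx in range(2):
                patch = img[by * P : (by + 1) * P, bx * P : (bx + 1) * P, :]
                expected.append(patch.reshape(-1))  # row-major pixel, then channel
        np.testing.assert_allclose(got, np.array(expected))

    def test_size_mismatch_raises(self, deit_tiny, rng):
        with pytest.raises(ShapeError):
            embed_patches(rng.random((64, 64, 3)), deit_tiny)


class TestEncoderBlock:
    def test_identity_limit_with_zero_projections(self, tiny_model, rng):
        m = tiny_model.copy()
        for k in m.params:
            if k.startswith("blocks.0.") and ("weight" in k or "bias" in k):
                if ".ln" in k:
                    continue
                m.params[k][:] = 0
        tokens = rng.normal(size=(5, 8))
        out = encoder_block(tokens, m, 0)
        np.testing.assert_allclose(out, tokens, atol=1e-6)

    def test_single_token_attention_is_one(self, rng):
        cfg = ViTConfig(image_size=16, patch_size=16, embed_dim=8, depth=1, num_heads=1)
        m = build_model(cfg, seed=0)
        tokens = rng.normal(size=(1, 2, 8))
        _, attn = encoder_block(tokens, m, 0, return_attention=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        # 2 tokens: each row is a softmax over 2 entries summing to 1
        assert attn.shape == (1, 1, 2, 2)

    def test_attention_matches_per_head_loop(self, tiny_model, rng):
        """Block output must equal an explicit per-head loop computation."""
        m = tiny_model.copy()
        tokens = rng.normal(size=(1, 4, 8)).astype(np.float64)
        out, cache = autodiff.block_forward(tokens, m.params, 0, m.config, None)

        # brute force: per-head q/k/v loops
        p = m.params
        d, H, dh = 8, 2, 4
        h, _ = autodiff.layernorm_forward(
            tokens, p["blocks.0.ln1.weight"], p["blocks.0.ln1.bias"]
        )
        qkv = h[0] @ p["blocks.0.attn.qkv.weight"] + p["blocks.0.attn.qkv.bias"]
        q, k, v = qkv[:, :d], qkv[:, d : 2 * d], qkv[:, 2 * d :]
        merged = np.zeros((4, d))
        for head in range(H):
            sl = slice(head * dh, (head + 1) * dh)
            qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
            for t in range(4):
                scores = np.array([qh[t] @ kh[s] / np.sqrt(dh) for s in range(4)])
                w = np.exp(scores - scores.max())
                w /= w.sum()
                merged[t, sl] = sum(w[s] * vh[s] for s in range(4))
        attn_out = merged @ p["blocks.0.attn.proj.weight"] + p["blocks.0.attn.proj.bias"]
        x1 = tokens[0] + attn_out
        h2, _ = autodiff.layernorm_forward(x1, p["blocks.0.ln2.weight"], p["blocks.0.ln2.bias"])
        u = h2 @ p["blocks.0.mlp.fc1.weight"] + p["blocks.0.mlp.fc1.bias"]
        expected = x1 + autodiff.gelu(u) @ p["blocks.0.mlp.fc2.weight"] + p["blocks.0.mlp.fc2.bias"]
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_block_preserves_sequence_shape(self, tiny_model, rng):
        tokens = rng.normal(size=(3, 5, 8))
        assert encoder_block(tokens, tiny_model, 1).shape == (3, 5, 8)

    def test_attention_rows_sum_to_one(self, tiny_model, rng):
        tokens = rng.normal(size=(2, 5, 8))
        _, attn = encoder_block(tokens, tiny_model, 0, return_attention=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


class TestForwardLogits:
    def test_output_shape(self, tiny_model, rng):
        imgs = rng.random((2, 16, 16, 3), dtype=np.float32)
        assert forward_logits(imgs, tiny_model).shape == (2, 2)

    def test_batch_permutation_equivariance(self, tiny_model, rng):
        imgs = rng.random((4, 16, 16, 3), dtype=np.float32)
        logits = forward_logits(imgs, tiny_model)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(forward_logits(imgs[perm], tiny_model), logits[perm], rtol=1e-6)

    def test_zero_head_gives_zero_logits(self, tiny_model, rng):
        m = tiny_model.copy()
        m.params["head.weight"][:] = 0
        m.params["head.bias"][:] = 0
        imgs = rng.random((3, 16, 16, 3), dtype=np.float32)
        np.testing.assert_array_equal(forward_logits(imgs, m), 0)

    def test_eval_forward_deterministic(self, tiny_model, rng):
        imgs = rng.random((2, 16, 16, 3), dtype=np.float32)
        np.testing.assert_array_equal(
            forward_logits(imgs, tiny_model), forward_logits(imgs, tiny_model)
        )

    def test_build_deterministic_per_seed(self, tiny_cfg):
        a, b = build_model(tiny_cfg, seed=7), build_model(tiny_cfg, seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_cfg, rng):
        """Analytic gradients agree with central differences for every tensor."""
        from fedlora import LoRAConfig, inject_lora

        m = build_model(tiny_cfg, seed=0)
        m = inject_lora(m, LoRAConfig(rank=2, alpha=4, dropout=0.0, train_head=True), seed=1)
        for k in m.params:
            m.params[k] = m.params[k].astype(np.float64)
            if k.endswith("lora_B"):
                m.params[k] = rng.normal(0, 0.1, m.params[k].shape)
        m.trainable = {k: True for k in m.params}
        x = rng.normal(0.4, 0.2, (2, 16, 16, 3))
        y = np.array([0, 1])
        _, _, grads = autodiff.loss_and_grads(m, x, y, train=False)

        def loss():
            logits, _ = autodiff.model_forward(m, x, train=False)
            return autodiff.softmax_cross_entropy(logits, y)[0]

        eps = 1e-6
        for k in m.params:
            flat = m.params[k].reshape(-1)
            g = grads[k].reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[i]) <= 1e-4 * max(1.0, abs(fd)), k


class TestCheckpoint:
    def test_round_trip(self, tiny_model, tmp_path, rng):
        path = str(tmp_path / "model.h5")
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_model.config
        for k in tiny_model.params:
            np.testing.assert_array_equal(loaded.params[k], tiny_model.params[k])
        imgs = rng.random((2, 16, 16, 3), dtype=np.float32)
        np.testing.assert_array_equal(
            forward_logits(imgs, loaded), forward_logits(imgs, tiny_model)
        )
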