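"""Architecture contracts: parameter arithmetic, shapes, determinism, I/O."""

import dataclasses

import numpy as np
import pytest

from lusseg.model import (ModelConfig, build_model, count_trainable_parameters,
                          load_checkpoint, save_checkpoint)


def vit_small_parameter_count(cfg: ModelConfig) -> int:
    """Independent closed-form count for the ViT encoder (oracle)."""
    d = cfg.embed_dim
    n_patches = (cfg.image_size // cfg.patch_size) ** 2
    patch_embed = cfg.in_channels * cfg.patch_size ** 2 * d + d
    cls_token = d
    pos_embed = (n_patches + 1) * d
    hidden = int(d * cfg.mlp_ratio)
    per_block = (2 * (2 * d)                      # two layer norms
                 + d * 3 * d + 3 * d              # qkv projection
                 + d * d + d                      # attention output
                 + d * hidden + hidden            # mlp fc1
                 + hidden * d + d)                # mlp fc2
    final_norm = 2 * d
    return patch_embed + cls_token + pos_embed + cfg.depth * per_block + final_norm


def decoder_parameter_count(cfg: ModelConfig) -> int:
    """Conv3x3 + BatchNorm per stage, then a 1x1 head (oracle)."""
    total, cin = 0, cfg.embed_dim
    for cout in cfg.decoder_channels:
        total += cin * cout * 9 + cout        # conv3x3 with bias
        total += 2 * cout                     # batch-norm gamma/beta
        cin = cout
    total += cin * cfg.out_channels + cfg.out_channels   # 1x1 head
    return total


class TestParameterCount:
    def test_default_config_against_closed_form(self):
        cfg = ModelConfig()
        want = vit_small_parameter_count(cfg) + decoder_parameter_count(cfg)
        assert count_trainable_parameters(cfg) == want

    def test_default_rounds_to_23_million(self):
        n = count_trainable_parameters(ModelConfig())
        assert round(n / 1e6) == 23

    def test_tiny_config_against_closed_form(self, tiny_model_cfg):
        want = (vit_small_parameter_count(tiny_model_cfg)
                + decoder_parameter_count(tiny_model_cfg))
        assert count_trainable_parameters(tiny_model_cfg) == want

    def test_encoder_block_count_matches_depth(self, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        assert len(model.encoder.blocks) == tiny_model_cfg.depth


class TestConfigValidation:
    def test_image_size_must_be_divisible_by_patch(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size=100, patch_size=16)

    def test_decoder_stages_must_recover_resolution(self):
        # 224/16 = 14-token grid; 3 stages give 112, not 224
        with pytest.raises(ValueError):
            ModelConfig(decoder_channels=[256, 128, 64])

    def test_heads_must_divide_embed_dim(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=384, num_heads=5)


class TestForward:
    def test_output_shape(self, tiny_model_cfg, rng):
        model = build_model(tiny_model_cfg)
        s = tiny_model_cfg.image_size
        img = rng.random((2, s, s))
        out = model.forward(img)
        assert out.data.shape == (2, 1, s, s)

    def test_predict_proba_range_and_shape(self, tiny_model_cfg, rng):
        model = build_model(tiny_model_cfg)
        s = tiny_model_cfg.image_size
        probs = model.predict_proba(rng.random((3, s, s)))
        assert probs.shape == (3, s, s)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_single_image_accepted(self, tiny_model_cfg, rng):
        model = build_model(tiny_model_cfg)
        s = tiny_model_cfg.image_size
        assert model.predict_proba(rng.random((s, s))).shape == (1, s, s)

    def test_same_seed_same_init_and_output(self, tiny_model_cfg, rng):
        s = tiny_model_cfg.image_size
        img = rng.random((1, s, s))
        a = build_model(tiny_model_cfg).predict_proba(img)
        b = build_model(tiny_model_cfg).predict_proba(img)
        np.testing.assert_array_equal(a, b)

    def test_different_seed_different_init(self, tiny_model_cfg):
        a = build_model(tiny_model_cfg)
        other = dataclasses.replace(tiny_model_cfg, seed=tiny_model_cfg.seed + 1)
        b = build_model(other)
        pa = dict(a.named_parameters())
        pb = dict(b.named_parameters())
        assert pa.keys() == pb.keys()
        assert any(not np.array_equal(pa[k].data, pb[k].data) for k in pa)


class TestCheckpoint:
    def test_roundtrip_bitwise(self, tiny_model_cfg, rng, tmp_path):
        model = build_model(tiny_model_cfg)
        # perturb away from the seeded init so the test is non-trivial
        for p in model.parameters():
            p.data += rng.standard_normal(p.data.shape).astype(p.data.dtype) * 0.01
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path, tiny_model_cfg)
        for (ka, pa), (kb, pb) in zip(sorted(model.named_parameters()),
                                      sorted(clone.named_parameters())):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)
        s = tiny_model_cfg.image_size
        img = rng.random((1, s, s))
        np.testing.assert_array_equal(model.predict_proba(img),
                                      clone.predict_proba(img))

    def test_pretrained_requires_local_path(self):
        with pytest.raises(FileNotFoundError):
            build_model(ModelConfig(pretrained=True))
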