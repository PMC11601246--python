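"""Network contracts: shared-weight encoding, channel-set invariance,
attention symmetry, positivity scores, gradient reversal, shapes,
determinism, and checkpoint round-trips."""

import numpy as np
import pytest

from phenoclip import nn
from phenoclip.autodiff import Tensor
from phenoclip.model import (ModelConfig, PhenotypeModel, load_checkpoint,
                             save_checkpoint, tiny_config)


def rand_batch(rng, b, c, d_raw=256):
    x = rng.random((b, c, 3, 64, 64)).astype(np.float32)
    raw = rng.normal(size=(b, c, d_raw)).astype(np.float32)
    mask = np.ones((b, c), dtype=np.float32)
    return x, raw, mask


@pytest.fixture(scope="module")
def model():
    m = PhenotypeModel(tiny_config(seed=3))
    m.eval()
    return m


class TestEncodeImages:
    def test_identical_channel_content_gives_identical_rows(self, model):
        rng = np.random.default_rng(0)
        x, _, _ = rand_batch(rng, 1, 1)
        dup = np.repeat(x, 4, axis=1)             # same content in 4 slots
        emb = model.encode_images(dup).data
        for j in range(1, 4):
            np.testing.assert_allclose(emb[0, j], emb[0, 0], atol=1e-6)

    def test_all_zero_padded_slots_share_one_embedding(self, model):
        x = np.zeros((2, 3, 3, 64, 64), dtype=np.float32)
        emb = model.encode_images(x).data
        np.testing.assert_allclose(emb, np.broadcast_to(emb[0, 0], emb.shape),
                                   atol=1e-6)

    def test_wrong_spatial_size_rejected(self, model):
        with pytest.raises(ValueError):
            model.encode_images(np.zeros((1, 2, 3, 32, 32), np.float32))

    def test_feature_map_size_matches_conv_arithmetic_oracle(self):
        cfg = ModelConfig()
        model_full = PhenotypeModel(cfg)
        # independent oracle: repeated integer conv arithmetic
        size = 64
        for stride in cfg.cnn_strides:
            size = (size + 2 * cfg.cnn_padding - cfg.cnn_kernel) // stride + 1
        assert model_full.cnn.feature_map_size(64, cfg.cnn_kernel,
                                               cfg.cnn_padding) == size
        assert size == 2  # interleaved strides 1/2 on 64x64 end at 2x2


class TestChannelSetInvariance:
    @pytest.mark.parametrize("c_max,b", [(4, 1), (16, 7), (75, 2)])
    def test_output_shapes_across_config_grid(self, c_max, b):
        m = PhenotypeModel(tiny_config(seed=1, c_max=c_max))
        m.eval()
        rng = np.random.default_rng(c_max)
        x, raw, mask = rand_batch(rng, b, c_max)
        out = m.forward(x, raw, mask)
        cfg = m.config
        assert out.cls_embedding.shape == (b, cfg.d_model)
        assert out.channel_embeddings.shape == (b, c_max, cfg.d_model)
        assert out.positivity_scores.shape == (b, c_max)
        assert out.modality_logits.shape == (b, cfg.n_modalities)
        assert float(out.temperature.data) > 0

    def test_permuting_channels_permutes_outputs_and_fixes_cls(self, model):
        rng = np.random.default_rng(5)
        x, raw, mask = rand_batch(rng, 2, 6)
        out = model.forward(x, raw, mask)
        perm = rng.permutation(6)
        out_p = model.forward(x[:, perm], raw[:, perm], mask[:, perm])
        np.testing.assert_allclose(out_p.cls_embedding.data,
                                   out.cls_embedding.data, atol=1e-4)
        np.testing.assert_allclose(out_p.channel_embeddings.data,
                                   out.channel_embeddings.data[:, perm], atol=1e-4)
        np.testing.assert_allclose(out_p.positivity_scores.data,
                                   out.positivity_scores.data[:, perm], atol=1e-4)

    def test_appending_padded_slots_leaves_real_outputs_unchanged(self, model):
        rng = np.random.default_rng(6)
        x, raw, mask = rand_batch(rng, 2, 5)
        out = model.forward(x, raw, mask)
        pad = 4
        x2 = np.concatenate([x, np.zeros((2, pad, 3, 64, 64), np.float32)], axis=1)
        raw2 = np.concatenate([raw, rng.normal(size=(2, pad, 256)).astype(np.float32)],
                              axis=1)
        mask2 = np.concatenate([mask, np.zeros((2, pad), np.float32)], axis=1)
        out2 = model.forward(x2, raw2, mask2)
        np.testing.assert_allclose(out2.cls_embedding.data,
                                   out.cls_embedding.data, atol=1e-4)
        np.testing.assert_allclose(out2.positivity_scores.data[:, :5],
                                   out.positivity_scores.data, atol=1e-4)
        assert np.all(out2.positivity_scores.data[:, 5:] == 0)

    def test_duplicated_channel_tokens_receive_identical_cls_attention(self, model):
        rng = np.random.default_rng(7)
        x, raw, mask = rand_batch(rng, 1, 4)
        x[0, 3] = x[0, 1]
        raw[0, 3] = raw[0, 1]
        out = model.forward(x, raw, mask)
        attn = out.attention.data.mean(axis=1)[0, 0, 1:]   # [CLS] -> channels
        assert abs(attn[3] - attn[1]) < 1e-5


class TestPositivity:
    def test_scores_bounded_and_top_marker_scores_one(self, model):
        rng = np.random.default_rng(8)
        x, raw, mask = rand_batch(rng, 3, 6)
        scores = model.forward(x, raw, mask).positivity_scores.data
        assert scores.min() >= 0.0 and scores.max() <= 1.0 + 1e-6
        np.testing.assert_allclose(scores.max(axis=1), 1.0, atol=1e-5)

    def test_empty_channel_set_rejected(self, model):
        rng = np.random.default_rng(9)
        x, raw, mask = rand_batch(rng, 1, 3)
        mask[0] = 0
        with pytest.raises(ValueError):
            model.forward(x, raw, mask)


class TestGradientReversal:
    def test_forward_identical_with_and_without_reversal(self, model):
        cls = Tensor(np.random.default_rng(1).normal(size=(3, 64)).astype(np.float32))
        np.testing.assert_array_equal(model.modality_logits(cls, reverse=True).data,
                                      model.modality_logits(cls, reverse=False).data)

    def test_trunk_gradient_is_minus_lambda_times_unreversed(self):
        # numerical-gradient oracle on a small trunk input
        for lam in (0.5, 1.0, 2.0):
            m = PhenotypeModel(tiny_config(seed=2, grl_lambda=lam))
            rng = np.random.default_rng(0)
            cls_data = rng.normal(size=(2, 64)).astype(np.float64)

            def loss_of(reverse):
                cls = Tensor(cls_data.copy(), requires_grad=True)
                (m.modality_logits(cls, reverse=reverse) ** 2).sum().backward()
                return cls.grad

            np.testing.assert_allclose(loss_of(True), -lam * loss_of(False),
                                       rtol=1e-6)

    def test_lambda_zero_blocks_trunk_gradient(self):
        m = PhenotypeModel(tiny_config(seed=2, grl_lambda=0.0))
        cls = Tensor(np.ones((1, 64), np.float32), requires_grad=True)
        (m.modality_logits(cls) ** 2).sum().backward()
        np.testing.assert_array_equal(cls.grad, np.zeros_like(cls.grad))

    def test_too_few_modalities_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(n_modalities=1)


class TestDeterminismAndCheckpoint:
    def test_same_seed_and_config_give_bit_identical_init(self):
        a = PhenotypeModel(tiny_config(seed=11))
        b = PhenotypeModel(tiny_config(seed=11))
        for (na, pa), (nb, pb) in zip(sorted(a.named_parameters()),
                                      sorted(b.named_parameters())):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_eval_forward_is_deterministic(self, model):
        rng = np.random.default_rng(12)
        x, raw, mask = rand_batch(rng, 2, 4)
        a = model.forward(x, raw, mask).cls_embedding.data
        b = model.forward(x, raw, mask).cls_embedding.data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip_reproduces_outputs(self, model, tmp_path):
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path, provider_id="offline-hash-v1")
        back, meta = load_checkpoint(path, expected_provider_id="offline-hash-v1")
        back.eval()
        rng = np.random.default_rng(13)
        x, raw, mask = rand_batch(rng, 2, 4)
        np.testing.assert_array_equal(back.forward(x, raw, mask).cls_embedding.data,
                                      model.forward(x, raw, mask).cls_embedding.data)

    def test_checkpoint_provider_mismatch_rejected(self, model, tmp_path):
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path, provider_id="offline-hash-v1")
        with pytest.raises(ValueError):
            load_checkpoint(path, expected_provider_id="http:somewhere")
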