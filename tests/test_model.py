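"""Network components: autoencoder equations, positional encoding,
attention, residual blocks, fusion, cross-modal decoding and the loss."""

import math

import numpy as np
import pytest

from aetrans.autograd import Tensor
from aetrans.model import (
    AETransModel,
    ArchitectureConfig,
    apply_feature_mask,
    positional_encoding,
)
from aetrans.nn import MultiHeadAttention, FeedForward
from tests.conftest import TINY_ARCH


class TestAutoencoder:
    def test_zero_weights_encode_to_zero(self, tiny_model):
        for p in tiny_model.rna_ae.named_parameters().values():
            p.data[...] = 0.0
        z = tiny_model.ae_encode(np.ones((1, 30)), "expression")
        np.testing.assert_array_equal(z.data, np.zeros((1, TINY_ARCH.latent_dim)))

    def test_identity_weights_pass_nonnegative_input_through(self):
        cfg = ArchitectureConfig(
            rna_input_dim=4, meth_input_dim=4, ae_hidden_dim=4, n_tokens=1,
            d_model=4, n_encoder_layers=1, n_heads=2, ffn_hidden_dim=4,
            mask_rate=0.0,
        )
        m = AETransModel(cfg, seed=0)
        m.rna_ae.enc1.W.data = np.eye(4)
        m.rna_ae.enc1.b.data[...] = 0.0
        m.rna_ae.enc2.W.data = np.eye(4)
        m.rna_ae.enc2.b.data[...] = 0.0
        x = np.array([[0.5, 1.0, 0.0, 2.0]])
        np.testing.assert_array_equal(m.ae_encode(x, "expression").data, x)

    def test_relu_zeroes_negative_preactivations(self, tiny_model):
        tiny_model.rna_ae.enc1.W.data[...] = 0.0
        tiny_model.rna_ae.enc1.b.data[...] = -1.0  # all hidden pre-activations -1
        h = tiny_model.rna_ae.enc1(Tensor(np.ones((1, 30)))).relu()
        np.testing.assert_array_equal(h.data, np.zeros_like(h.data))

    def test_zero_weights_decode_to_half(self, tiny_model):
        for p in tiny_model.meth_ae.named_parameters().values():
            p.data[...] = 0.0
        x_hat = tiny_model.ae_decode(np.ones((1, TINY_ARCH.latent_dim)), "methylation")
        np.testing.assert_allclose(x_hat.data, 0.5)

    def test_decoder_output_in_unit_interval(self, tiny_model):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(100, TINY_ARCH.latent_dim)) * 5
        out = tiny_model.ae_decode(z, "expression").data
        assert out.min() > 0.0 and out.max() < 1.0

    def test_large_decoder_bias_saturates_towards_one(self, tiny_model):
        tiny_model.rna_ae.dec2.b.data[...] = 50.0
        out = tiny_model.ae_decode(np.zeros((1, TINY_ARCH.latent_dim)), "expression")
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_wrong_input_dim_raises(self, tiny_model):
        with pytest.raises(ValueError, match="dim"):
            tiny_model.ae_encode(np.zeros((1, 7)), "expression")


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(3, 6)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)

    def test_first_position_first_channel_is_sin_one(self):
        for d in (4, 8, 16):
            assert positional_encoding(2, d)[1, 0] == pytest.approx(math.sin(1.0))

    def test_entries_bounded_by_one(self):
        pe = positional_encoding(50, 32)
        assert np.abs(pe).max() <= 1.0

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 5)


def naive_single_head_attention(q, k, v):
    """Brute-force softmax(QK^T/sqrt(d_k))V, row by row."""
    dk = q.shape[-1]
    scores = q @ k.T / math.sqrt(dk)
    out = np.zeros_like(q @ v.T @ v) if False else np.zeros((q.shape[0], v.shape[1]))
    for i in range(scores.shape[0]):
        e = np.exp(scores[i] - scores[i].max())
        w = e / e.sum()
        out[i] = w @ v
    return out


class TestAttention:
    def mha_identity(self, d_model, n_heads=1):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(d_model, n_heads, rng)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.W.data = np.eye(d_model)
            lin.b.data[...] = 0.0
        return mha

    def test_single_key_token_returns_value_regardless_of_query(self):
        mha = self.mha_identity(4)
        rng = np.random.default_rng(1)
        q = Tensor(rng.normal(size=(1, 3, 4)))
        kv = Tensor(rng.normal(size=(1, 1, 4)))
        out = mha(q, kv, kv).data
        np.testing.assert_allclose(out, np.broadcast_to(kv.data, (1, 3, 4)), atol=1e-12)

    def test_identical_scores_give_uniform_attention(self):
        mha = self.mha_identity(4)
        q = Tensor(np.zeros((1, 1, 4)))
        k = Tensor(np.ones((1, 2, 4)))
        v = Tensor(np.array([[[1.0, 0, 0, 0], [0, 1.0, 0, 0]]]))
        out = mha(q, k, v).data
        np.testing.assert_allclose(out[0, 0], [0.5, 0.5, 0, 0], atol=1e-12)
        np.testing.assert_allclose(mha.last_attention[0, 0, 0], [0.5, 0.5])

    def test_matches_naive_reference_on_hand_set_inputs(self):
        mha = self.mha_identity(2)
        rng = np.random.default_rng(7)
        q = rng.normal(size=(2, 2))
        k = rng.normal(size=(2, 2))
        v = rng.normal(size=(2, 2))
        out = mha(Tensor(q[None]), Tensor(k[None]), Tensor(v[None])).data[0]
        np.testing.assert_allclose(out, naive_single_head_attention(q, k, v), atol=1e-12)

    def test_attention_rows_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(3)
        tokens = Tensor(rng.normal(size=(5, TINY_ARCH.n_tokens, TINY_ARCH.d_model)))
        tiny_model.transformer_encode(tokens, "expression")
        attn = tiny_model.rna_encoder.layers[0].mha.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(6, 4, np.random.default_rng(0))


class TestFeedForward:
    def test_zero_weights_broadcast_second_bias(self):
        ffn = FeedForward(4, 8, np.random.default_rng(0))
        ffn.lin1.W.data[...] = 0.0
        ffn.lin1.b.data[...] = 0.0
        ffn.lin2.W.data[...] = 0.0
        ffn.lin2.b.data[...] = 3.0
        out = ffn(Tensor(np.random.default_rng(1).normal(size=(2, 3, 4))))
        np.testing.assert_array_equal(out.data, np.full((2, 3, 4), 3.0))

    def test_identity_composition_on_nonnegative_input(self):
        ffn = FeedForward(3, 3, np.random.default_rng(0))
        ffn.lin1.W.data = np.eye(3)
        ffn.lin1.b.data[...] = 0.0
        ffn.lin2.W.data = np.eye(3)
        ffn.lin2.b.data[...] = 0.0
        x = np.array([[[0.0, 1.0, 2.0]]])
        np.testing.assert_array_equal(ffn(Tensor(x)).data, x)


class TestEncoderStack:
    def test_shape_preserved_for_any_token_count(self, tiny_model):
        rng = np.random.default_rng(0)
        for b in (1, 4):
            tokens = Tensor(rng.normal(size=(b, TINY_ARCH.n_tokens, TINY_ARCH.d_model)))
            out = tiny_model.transformer_encode(tokens, "methylation")
            assert out.shape == tokens.shape

    def test_permutation_equivariance_without_positional_encoding(self, tiny_model):
        """Self-attention blocks commute with token permutation, so permuting
        input tokens permutes the output identically."""
        rng = np.random.default_rng(5)
        tokens = rng.normal(size=(1, TINY_ARCH.n_tokens, TINY_ARCH.d_model))
        perm = [1, 0]
        out = tiny_model.transformer_encode(Tensor(tokens), "expression").data
        out_perm = tiny_model.transformer_encode(
            Tensor(tokens[:, perm]), "expression"
        ).data
        np.testing.assert_allclose(out[:, perm], out_perm, atol=1e-10)


class TestFusionAndClassifier:
    def test_zero_classifier_weights_give_half_probability(self, tiny_model):
        for p in tiny_model.classifier.named_parameters().values():
            p.data[...] = 0.0
        rng = np.random.default_rng(0)
        out = tiny_model.forward(rng.normal(size=(3, 30)), rng.normal(size=(3, 30)))
        np.testing.assert_allclose(out["probability"].data, 0.5)

    def test_probability_in_open_unit_interval(self, tiny_model):
        rng = np.random.default_rng(1)
        out = tiny_model.forward(rng.normal(size=(8, 30)) * 10, rng.normal(size=(8, 30)) * 10)
        p = out["probability"].data
        assert p.min() > 0.0 and p.max() < 1.0

    def test_fused_vector_has_configured_dimension(self, tiny_model):
        rng = np.random.default_rng(2)
        out = tiny_model.forward(rng.normal(size=(2, 30)), rng.normal(size=(2, 30)))
        assert out["fused"].shape == (2, TINY_ARCH.effective_fusion_dim)


class TestCrossReconstruction:
    def test_output_dims_match_target_modality(self, tiny_model):
        rng = np.random.default_rng(0)
        out = tiny_model.forward(rng.normal(size=(2, 30)), rng.normal(size=(2, 30)))
        assert out["cycle_rna"].shape == (2, 30)
        assert out["cycle_meth"].shape == (2, 30)
        for key in ("cycle_rna", "cycle_meth", "recon_rna", "recon_meth"):
            vals = out[key].data
            assert vals.min() > 0.0 and vals.max() < 1.0

    def test_unknown_modality_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="modality"):
            tiny_model.cross_reconstruct(Tensor(np.zeros((1, TINY_ARCH.latent_dim))), "protein")

    def test_cycle_loss_couples_both_encoders(self, tiny_model):
        """The methylation cycle reconstruction must backpropagate a nonzero
        gradient into the expression encoder: cross-modal coupling."""
        rng = np.random.default_rng(4)
        x_rna = Tensor(rng.normal(size=(2, 30)))
        x_meth = Tensor(rng.normal(size=(2, 30)))
        out = tiny_model.forward(x_rna, x_meth)
        cyc_meth = ((out["cycle_meth"] - x_meth) ** 2).mean()
        tiny_model.zero_grad()
        cyc_meth.backward()
        g = tiny_model.rna_ae.enc1.W.grad
        assert g is not None and np.abs(g).max() > 0.0


class TestFeatureMask:
    def test_zero_rate_is_identity(self):
        x = np.ones((4, 10))
        out = apply_feature_mask(x, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_surviving_fraction_within_binomial_tolerance(self):
        x = np.ones((1, 10_000))
        out = apply_feature_mask(x, 0.3, np.random.default_rng(1))
        frac = out.mean()
        assert 0.67 <= frac <= 0.73

    def test_near_one_rate_kills_almost_everything(self):
        x = np.ones((1, 1000))
        out = apply_feature_mask(x, 0.999, np.random.default_rng(2))
        assert out.sum() <= 5

    def test_mask_inactive_in_evaluation_mode(self, tiny_cohort):
        import dataclasses

        cfg = dataclasses.replace(TINY_ARCH, mask_rate=0.5)
        m = AETransModel(cfg, seed=0)
        m.eval()
        rng = np.random.default_rng(0)
        x_rna, x_meth = rng.normal(size=(2, 30)), rng.normal(size=(2, 30))
        a = m.forward(x_rna, x_meth)["probability"].data
        b = m.forward(x_rna, x_meth)["probability"].data
        np.testing.assert_array_equal(a, b)


class TestLoss:
    def test_perfect_prediction_and_reconstruction_give_near_zero_loss(self, tiny_model):
        x = np.full((2, 30), 0.5)
        outputs = {
            "probability": Tensor(np.array([1 - 1e-9, 1e-9])),
            "recon_rna": Tensor(x.copy()),
            "recon_meth": Tensor(x.copy()),
            "cycle_rna": Tensor(x.copy()),
            "cycle_meth": Tensor(x.copy()),
        }
        _, bd = tiny_model.compute_loss(outputs, np.array([1.0, 0.0]), x, x)
        assert bd.total < 1e-5

    def test_half_probability_gives_ln_two_bce(self, tiny_model):
        x = np.zeros((1, 30))
        outputs = {
            "probability": Tensor(np.array([0.5])),
            "recon_rna": Tensor(x.copy()),
            "recon_meth": Tensor(x.copy()),
            "cycle_rna": Tensor(x.copy()),
            "cycle_meth": Tensor(x.copy()),
        }
        _, bd = tiny_model.compute_loss(outputs, np.array([1.0]), x, x)
        assert bd.classification == pytest.approx(math.log(2.0), rel=1e-12)

    def test_constant_offset_reconstruction_gives_squared_constant_mse(self, tiny_model):
        c = 0.3
        x = np.zeros((1, 30))
        outputs = {
            "probability": Tensor(np.array([0.5])),
            "recon_rna": Tensor(x + c),
            "recon_meth": Tensor(x.copy()),
            "cycle_rna": Tensor(x.copy()),
            "cycle_meth": Tensor(x.copy()),
        }
        _, bd = tiny_model.compute_loss(outputs, np.array([1.0]), x, x)
        assert bd.reconstruction_rna == pytest.approx(c**2, rel=1e-12)

    def test_total_is_weighted_sum_of_terms(self, tiny_cohort):
        import dataclasses

        cfg = dataclasses.replace(TINY_ARCH, loss_weights=(2.0, 0.5, 1.0, 0.0, 3.0))
        m = AETransModel(cfg, seed=0)
        rng = np.random.default_rng(0)
        x_rna, x_meth = rng.normal(size=(3, 30)), rng.normal(size=(3, 30))
        out = m.forward(x_rna, x_meth)
        _, bd = m.compute_loss(out, np.array([1.0, 0.0, 1.0]), x_rna, x_meth)
        expected = (
            2.0 * bd.classification + 0.5 * bd.reconstruction_rna
            + 1.0 * bd.reconstruction_meth + 0.0 * bd.cycle_rna + 3.0 * bd.cycle_meth
        )
        assert bd.total == pytest.approx(expected, rel=1e-12)


class TestModelContracts:
    def test_forward_deterministic_in_eval_mode(self, tiny_model):
        tiny_model.eval()
        rng = np.random.default_rng(0)
        x_rna, x_meth = rng.normal(size=(3, 30)), rng.normal(size=(3, 30))
        a = tiny_model.forward(x_rna, x_meth)["probability"].data
        b = tiny_model.forward(x_rna, x_meth)["probability"].data
        np.testing.assert_array_equal(a, b)

    def test_loss_gradient_reaches_every_parameter_group(self, tiny_model):
        rng = np.random.default_rng(0)
        x_rna, x_meth = rng.normal(size=(4, 30)), rng.normal(size=(4, 30))
        out = tiny_model.forward(x_rna, x_meth)
        loss, _ = tiny_model.compute_loss(out, np.array([1.0, 0, 1, 0]), x_rna, x_meth)
        tiny_model.zero_grad()
        loss.backward()
        for name, p in tiny_model.named_parameters().items():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0.0, f"zero gradient for {name}"

    def test_loss_gradient_matches_finite_difference_on_a_weight(self, tiny_model):
        rng = np.random.default_rng(1)
        x_rna, x_meth = rng.normal(size=(2, 30)), rng.normal(size=(2, 30))
        y = np.array([1.0, 0.0])

        def loss_value():
            out = tiny_model.forward(x_rna, x_meth)
            _, bd = tiny_model.compute_loss(out, y, x_rna, x_meth)
            return bd.total

        out = tiny_model.forward(x_rna, x_meth)
        loss, _ = tiny_model.compute_loss(out, y, x_rna, x_meth)
        tiny_model.zero_grad()
        loss.backward()
        w = tiny_model.fusion.W
        i, j = 3, 2
        eps = 1e-6
        orig = w.data[i, j]
        w.data[i, j] = orig + eps
        hi = loss_value()
        w.data[i, j] = orig - eps
        lo = loss_value()
        w.data[i, j] = orig
        fd = (hi - lo) / (2 * eps)
        assert w.grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        rng = np.random.default_rng(0)
        x_rna, x_meth = rng.normal(size=(3, 30)), rng.normal(size=(3, 30))
        before = tiny_model.predict_proba(x_rna, x_meth)
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = AETransModel.load(path)
        after = loaded.predict_proba(x_rna, x_meth)
        np.testing.assert_array_equal(before, after)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(
                rna_input_dim=10, meth_input_dim=10, n_tokens=2, d_model=6,
                n_heads=4,
            ).validate()
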