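"""Architecture and forward-pass contracts: reference per-component parameter
counts, dense-attention oracle, autoencoder decoder identities, edge-mask
semantics, monotone sparsification, determinism and permutation invariance."""

import numpy as np
import pytest

from sfegat.model import (
    EvolutionBlock,
    ModelConfig,
    SFEGAT,
    apply_mask,
    count_parameters,
    load_checkpoint,
    sample_edge_mask_train,
    save_checkpoint,
    threshold_edge_mask_eval,
)
from sfegat.nn.autodiff import Tensor
from sfegat.nn.layers import DenseGATv2, add_self_loops
from tests.conftest import random_graph_batch

TINY = ModelConfig(
    in_dim=5, hidden_per_head=4, heads=2, gae_latent=3, n_blocks=3, n_classes=4
)


def warmed_model(config, h, a, seed=0):
    """A model whose batch-norm running statistics have seen one batch."""
    model = SFEGAT(config, seed=seed)
    model.train()
    model.logits(h, a, rng=np.random.default_rng(99))
    model.eval()
    return model


class TestParameterCounts:
    """The reference component table: input attention layer 2560, block
    attention layers 33,280, batch norms 256, autoencoders 4192, final
    linear 516, total 149,796 (~0.15M)."""

    def test_reference_component_counts(self):
        counts = count_parameters(ModelConfig())
        assert counts["input_gatv2"] == 2560
        for k in (1, 2, 3):
            assert counts[f"block{k}_gatv2"] == 33_280
            assert counts[f"block{k}_batchnorm"] == 256
            assert counts[f"block{k}_gae"] == 4_192
        assert counts["classifier_gatv2"] == 33_280
        assert counts["classifier_batchnorm"] == 256
        assert counts["classifier_linear"] == 516
        assert counts["total"] == 149_796

    def test_total_rounds_to_015_million(self):
        assert round(count_parameters(ModelConfig())["total"] / 1e6, 2) == 0.15

    def test_counts_match_instantiated_model(self):
        model = SFEGAT(ModelConfig(), seed=0)
        assert model.n_parameters() == count_parameters(ModelConfig())["total"]

    def test_counting_convention_formula(self):
        """Each attention layer = two in->out projections with biases +
        per-head attention vectors + output bias; GAE = GCN(128->32) with
        bias + 32-feature batch norm."""
        cfg = ModelConfig()
        out = cfg.block_dim
        gat_in = 2 * (cfg.in_dim * out) + 2 * out + cfg.heads * cfg.hidden_per_head + out
        gat_block = 2 * (out * out) + 2 * out + cfg.heads * cfg.hidden_per_head + out
        gae = out * cfg.gae_latent + cfg.gae_latent + 2 * cfg.gae_latent
        counts = count_parameters(cfg)
        assert counts["input_gatv2"] == gat_in == 2560
        assert counts["block1_gatv2"] == gat_block == 33_280
        assert counts["block1_gae"] == gae == 4192


class TestAttentionLayer:
    def test_dense_oracle_small_graph(self, rng):
        """A 3-node path graph against a hand-rolled dense computation."""
        layer = DenseGATv2(2, 1, 3, rng)
        x = rng.normal(size=(1, 3, 2))
        support = np.zeros((1, 3, 3), dtype=bool)
        support[0, [0, 1, 1, 2], [1, 0, 2, 1]] = True
        support = add_self_loops(support)
        out = layer(Tensor(x), support).data

        wl, bl = layer.weight_src.data, layer.bias_src.data
        wr, br = layer.weight_dst.data, layer.bias_dst.data
        att = layer.att.data.reshape(-1)
        src = x[0] @ wl + bl
        dst = x[0] @ wr + br
        expected = np.zeros((3, 3))
        for i in range(3):
            neigh = [j for j in range(3) if support[0, i, j]]
            e = []
            for j in neigh:
                pre = dst[i] + src[j]
                act = np.where(pre > 0, pre, 0.2 * pre)
                e.append(att @ act)
            alpha = np.exp(e - max(e))
            alpha /= alpha.sum()
            expected[i] = sum(a * src[j] for a, j in zip(alpha, neigh))
        np.testing.assert_allclose(out[0], expected + layer.bias.data, atol=1e-10)

    def test_attention_rows_normalize(self, rng):
        layer = DenseGATv2(4, 3, 5, rng)
        h, a = random_graph_batch(rng, n=2, c=6, b=4)
        support = add_self_loops(a != 0)
        alpha = layer.attention(Tensor(h), support).data
        np.testing.assert_allclose(alpha.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(alpha[~np.broadcast_to(support[..., None], alpha.shape)] == 0)

    def test_singleton_neighbourhood_gets_unit_attention(self, rng):
        layer = DenseGATv2(3, 2, 4, rng)
        support = np.zeros((1, 3, 3), dtype=bool)
        support[0, 0, 1] = True  # node 0 attends only to node 1
        support[0, 1, 1] = support[0, 2, 2] = True
        alpha = layer.attention(Tensor(rng.normal(size=(1, 3, 3))), support).data
        np.testing.assert_allclose(alpha[0, 0, 1], 1.0)

    def test_identical_features_uniform_attention(self, rng):
        layer = DenseGATv2(3, 2, 4, rng)
        x = np.tile(rng.normal(size=(1, 1, 3)), (1, 5, 1))
        support = add_self_loops(np.ones((1, 5, 5), dtype=bool))
        alpha = layer.attention(Tensor(x), support).data
        np.testing.assert_allclose(alpha, 0.2, atol=1e-12)

    def test_empty_neighbourhood_raises(self, rng):
        layer = DenseGATv2(3, 2, 4, rng)
        support = np.zeros((1, 3, 3), dtype=bool)  # no self-loops
        with pytest.raises(ValueError, match="neighbourhood"):
            layer(Tensor(rng.normal(size=(1, 3, 3))), support)


class TestEdgeDecoder:
    def test_inner_product_sigmoid_oracle(self, rng):
        """P equals elementwise sigmoid of Z Z^T for hand-set latents."""
        cfg = ModelConfig(in_dim=4, hidden_per_head=3, heads=2, gae_latent=4,
                          n_blocks=1)
        block = EvolutionBlock(cfg, rng)
        z = rng.normal(size=(2, 5, 4))
        logits = z @ z.swapaxes(1, 2)
        np.testing.assert_allclose(
            1 / (1 + np.exp(-logits)),
            (Tensor(z) @ Tensor(z).swapaxes(1, 2)).sigmoid().data,
            atol=1e-12,
        )
        del block

    def test_probabilities_symmetric_in_unit_interval(self, rng):
        cfg = ModelConfig(in_dim=4, hidden_per_head=3, heads=2, gae_latent=4,
                          n_blocks=1)
        block = EvolutionBlock(cfg, rng)
        h, a = random_graph_batch(rng, n=3, c=6, b=4)
        p = block.gae.edge_probabilities(Tensor(rng.normal(size=(3, 6, 6))), Tensor(a))
        assert p.data.min() >= 0.0 and p.data.max() <= 1.0
        np.testing.assert_allclose(p.data, p.data.swapaxes(1, 2), atol=1e-12)

    def test_orthogonal_latents_give_half(self):
        z = np.zeros((1, 2, 2))
        z[0, 0, 0] = 1.0
        z[0, 1, 1] = 1.0  # z0 . z1 = 0
        p = (Tensor(z) @ Tensor(z).swapaxes(1, 2)).sigmoid().data
        assert p[0, 0, 1] == 0.5


class TestEdgeMasks:
    def test_certain_probabilities(self, rng):
        assert np.all(sample_edge_mask_train(np.ones((4, 4)), rng) == 1)
        assert np.all(sample_edge_mask_train(np.zeros((4, 4)), rng) == 0)

    def test_sampled_mask_symmetric(self, rng):
        p = rng.random((6, 6))
        p = (p + p.T) / 2
        m = sample_edge_mask_train(p, rng)
        np.testing.assert_array_equal(m, m.T)

    def test_invalid_probabilities_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_edge_mask_train(np.full((3, 3), 1.5), rng)

    def test_threshold_enumeration(self):
        p = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.9], [0.5, 0.9, 0.0]])
        m = threshold_edge_mask_eval(p, 0.5)
        expected = np.zeros((3, 3))
        expected[1, 2] = expected[2, 1] = 1.0
        np.testing.assert_array_equal(m, expected)

    def test_threshold_extremes(self, rng):
        p = rng.random((5, 5))
        assert np.all(threshold_edge_mask_eval(p, 1.0) == 0)
        np.testing.assert_array_equal(threshold_edge_mask_eval(p, 0.0), p > 0)

    def test_threshold_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="tau"):
            threshold_edge_mask_eval(rng.random((3, 3)), 1.5)

    def test_apply_mask_elementwise(self, rng):
        a = rng.normal(size=(4, 4))
        m = (rng.random((4, 4)) > 0.5).astype(float)
        out = apply_mask(a, m)
        np.testing.assert_array_equal(out[m == 1], a[m == 1])
        assert np.all(out[m == 0] == 0)

    def test_apply_mask_identity_and_annihilator(self, rng):
        a = rng.normal(size=(3, 3))
        np.testing.assert_array_equal(apply_mask(a, np.ones((3, 3))), a)
        assert np.all(apply_mask(a, np.zeros((3, 3))) == 0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            apply_mask(np.ones((3, 3)), np.ones((4, 4)))


class TestForwardPass:
    def test_probabilities_sum_to_one(self, rng):
        h, a = random_graph_batch(rng, n=6, c=7, b=5)
        model = warmed_model(TINY, h, a)
        probs = model.forward(h, a).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_bit_determinism(self, rng):
        h, a = random_graph_batch(rng, n=4, c=7, b=5)
        model = warmed_model(TINY, h, a)
        out1, state1 = model.logits(h, a, return_state=True)
        out2, state2 = model.logits(h, a, return_state=True)
        np.testing.assert_array_equal(out1.data, out2.data)
        for s1, s2 in zip(state1.supports, state2.supports):
            np.testing.assert_array_equal(s1, s2)

    def test_monotone_sparsification_both_modes(self, rng):
        h, a = random_graph_batch(rng, n=4, c=8, b=5, density=0.7)
        model = warmed_model(TINY, h, a)
        _, state = model.logits(h, a, return_state=True)
        counts = state.edge_counts()
        assert all(b <= a_ for a_, b in zip(counts, counts[1:]))
        model.train()
        _, state = model.logits(h, a, rng=np.random.default_rng(3), return_state=True)
        counts = state.edge_counts()
        assert all(b <= a_ for a_, b in zip(counts, counts[1:]))

    def test_fully_masked_graph_still_runs(self, rng):
        """With every edge pruned the model must survive on self-loops."""
        h, a = random_graph_batch(rng, n=2, c=5, b=5)
        model = warmed_model(TINY, h, a, seed=1)
        probs = model.forward(h, np.zeros_like(a)).data
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_invariance_of_graph_outputs(self, rng):
        h, a = random_graph_batch(rng, n=3, c=8, b=5)
        model = warmed_model(TINY, h, a)
        perm = rng.permutation(8)
        h_p = h[:, perm, :]
        a_p = a[:, perm][:, :, perm]
        p1 = model.forward(h, a).data
        p2 = model.forward(h_p, a_p).data
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_zeroed_head_gives_uniform_probabilities(self, rng):
        h, a = random_graph_batch(rng, n=3, c=6, b=5)
        model = warmed_model(TINY, h, a)
        model.cls_linear.weight.data[:] = 0.0
        model.cls_linear.bias.data[:] = 0.0
        probs = model.forward(h, a).data
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_train_mode_without_rng_raises(self, rng):
        h, a = random_graph_batch(rng, n=2, c=5, b=5)
        model = SFEGAT(TINY, seed=0)
        model.train()
        with pytest.raises(ValueError, match="rng"):
            model.logits(h, a)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        h, a = random_graph_batch(rng, n=3, c=6, b=5)
        model = warmed_model(TINY, h, a)
        ref = model.forward(h, a).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        restored.eval()
        np.testing.assert_array_equal(restored.forward(h, a).data, ref)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_eval": 1.5},
            {"n_blocks": 0},
            {"edge_gradient": "gumbel"},
            {"attention": "transformer"},
            {"conv": "sage"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)
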