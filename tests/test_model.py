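import numpy as np
import pytest

import gednn as G
from gednn.model import ModelConfig, forward, init_model, loss, train_step


def all_equal_states(s1, s2):
    return all(np.array_equal(a, b) for a, b in zip(s1.weights, s2.weights)) and all(
        np.array_equal(a, b) for a, b in zip(s1.biases, s2.biases)
    )


class TestInit:
    def test_masked_entries_zero_at_birth(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0], seed=3)
        assert (state.weights[0][a.matrix == 0] == 0).all()
        assert (state.weights[1][ap.matrix == 0] == 0).all()

    def test_gene_graph_identity_mask_makes_w1_diagonal(self):
        p, q = 6, 4
        a = G.SnpGeneMask(np.ones((p, q)), [f"rs{i}" for i in range(p)],
                          [f"g{j}" for j in range(q)])
        ap = G.GeneGraphMask(np.eye(q), [f"g{j}" for j in range(q)])
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=p, seed=0)
        off_diag = state.weights[1][~np.eye(q, dtype=bool)]
        assert (off_diag == 0).all()
        assert (np.diag(state.weights[1]) != 0).all()

    def test_same_seed_bit_identical(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        s1 = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0], seed=5)
        s2 = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0], seed=5)
        assert all_equal_states(s1, s2)

    def test_dnn_with_masks_is_contract_error(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        with pytest.raises(ValueError, match="dnn"):
            init_model(ModelConfig(mode="dnn"), (a, ap), p=a.matrix.shape[0])

    @pytest.mark.parametrize("mode,needs", [("e_dnn", "SNP-gene"), ("gedfn", "gene-gene"),
                                            ("gednn", "SNP-gene")])
    def test_missing_required_mask_is_error(self, mode, needs):
        with pytest.raises(ValueError, match=needs):
            init_model(ModelConfig(mode=mode), None, p=5, q=3)

    def test_layer_shape_chain(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        p, q = a.matrix.shape
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=p)
        assert state.dims == [p, q, q, 128, 16, 2]
        state = init_model(ModelConfig(mode="dnn"), None, p=p)
        assert state.dims == [p, 256, 64, 16, 2]


class TestForward:
    def test_probability_rows_sum_to_one(self, tiny_dataset, rng):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0], seed=1)
        x = rng.normal(size=(9, a.matrix.shape[0]))
        probs = forward(state, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_probabilities(self):
        state = init_model(ModelConfig(mode="dnn", hidden_widths=(4,), bias_init=0.0),
                           None, p=3, seed=0)
        for w in state.weights:
            w[:] = 0.0
        probs = forward(state, np.ones((2, 3)))
        np.testing.assert_allclose(probs, 0.5)

    def test_shape_mismatch_rejected(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0])
        with pytest.raises(ValueError, match="features"):
            forward(state, np.zeros((2, 3)))


class TestLoss:
    @pytest.fixture
    def dense_state(self):
        return init_model(ModelConfig(mode="dnn", hidden_widths=(4,), alpha=0.0),
                          None, p=3, seed=0)

    def test_uniform_probabilities_give_ln2(self, dense_state):
        probs = np.full((5, 2), 0.5)
        assert loss(probs, np.array([0, 1, 1, 0, 1]), dense_state) == pytest.approx(np.log(2))

    def test_perfect_predictions_bounded_by_clamp(self, dense_state):
        y = np.array([0, 1])
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss(probs, y, dense_state) <= -np.log(1 - 1e-7) + 1e-12

    def test_zero_weights_contribute_no_penalty(self):
        state = init_model(ModelConfig(mode="dnn", hidden_widths=(4,), alpha=1.0),
                           None, p=3, seed=0)
        for w in state.weights:
            w[:] = 0.0
        probs = np.full((4, 2), 0.5)
        assert loss(probs, np.array([0, 1, 0, 1]), state) == pytest.approx(np.log(2))


class TestTrainStep:
    def make_training_pair(self, tiny_dataset, seed=2):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        state = init_model(ModelConfig(mode="gednn"), (a, ap), p=a.matrix.shape[0], seed=seed)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, a.matrix.shape[0]))
        y = rng.integers(0, 2, 8)
        return state, x, y, a, ap

    def test_masked_entries_stay_exactly_zero(self, tiny_dataset):
        state, x, y, a, ap = self.make_training_pair(tiny_dataset)
        for _ in range(5):
            train_step(state, x, y)
        assert (state.weights[0][a.matrix == 0] == 0).all()
        assert (state.weights[1][ap.matrix == 0] == 0).all()

    def test_same_seed_and_order_identical(self, tiny_dataset):
        s1, x, y, *_ = self.make_training_pair(tiny_dataset, seed=4)
        s2, _, _, *_ = self.make_training_pair(tiny_dataset, seed=4)
        for _ in range(3):
            train_step(s1, x, y)
            train_step(s2, x, y)
        assert all_equal_states(s1, s2)

    def test_zero_learning_rate_leaves_weights(self, tiny_dataset):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        cfg = ModelConfig(mode="gednn", learning_rate=0.0, dropout_keep=1.0)
        state = init_model(cfg, (a, ap), p=a.matrix.shape[0], seed=1)
        before = [w.copy() for w in state.weights]
        rng = np.random.default_rng(0)
        train_step(state, rng.normal(size=(4, a.matrix.shape[0])), np.array([0, 1, 0, 1]))
        for w_before, w_after in zip(before, state.weights):
            np.testing.assert_array_equal(w_before, w_after)
        assert state.adam_t == 1  # optimizer bookkeeping still advanced

    def test_gradient_masking_equivalent_to_post_hoc_zeroing(self):
        """Plain-SGD oracle on a one-hidden-layer network: masking gradients
        before the update equals re-zeroing weights after the update."""
        rng = np.random.default_rng(9)
        mask = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        w = rng.normal(size=(3, 2)) * mask
        v = rng.normal(size=(2, 2))
        x = rng.normal(size=(6, 3))
        y = rng.integers(0, 2, 6)
        onehot = np.column_stack([1 - y, y]).astype(float)

        def grads(w_, v_):
            h = np.maximum(x @ w_, 0)
            z = h @ v_
            e = np.exp(z - z.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            d2 = (p - onehot) / len(y)
            gv = h.T @ d2
            d1 = (d2 @ v_.T) * (x @ w_ > 0)
            return x.T @ d1, gv

        lr = 0.05
        gw, gv = grads(w, v)
        w_masked_grad = w - lr * (gw * mask)
        w_post_zeroed = (w - lr * gw) * mask
        np.testing.assert_allclose(w_masked_grad, w_post_zeroed, atol=1e-15)

    def test_overfits_linearly_separable_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 10))
        y = (x[:, 0] > 0).astype(int)
        cfg = ModelConfig(mode="dnn", hidden_widths=(8,), max_epochs=200, patience=0, seed=0)
        state = init_model(cfg, None, p=10, seed=0)
        for _ in range(cfg.max_epochs):
            order = state.rng.permutation(60)
            for s0 in range(0, 60, cfg.batch_size):
                sel = order[s0: s0 + cfg.batch_size]
                train_step(state, x[sel], y[sel])
        auc, _ = G.roc_auc(forward(state, x)[:, 1], y)
        assert auc >= 0.99


class TestCheckpoint:
    def test_round_trip_preserves_weights_masks_config(self, tiny_dataset, tmp_path):
        a, ap = tiny_dataset["snp_gene"], tiny_dataset["gene_graph"]
        cfg = ModelConfig(mode="gednn", hidden_widths=(8, 4), alpha=0.01)
        state = init_model(cfg, (a, ap), p=a.matrix.shape[0], seed=6)
        path = tmp_path / "model.npz"
        G.save_checkpoint(state, path)
        back = G.load_checkpoint(path)
        assert all_equal_states(state, back)
        assert back.config == cfg
        assert back.snp_ids == state.snp_ids and back.gene_ids == state.gene_ids
        np.testing.assert_array_equal(back.layer_masks[0], state.layer_masks[0])
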