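import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinpred.dbn import (
    DBNModel,
    RBM,
    cd_gradient_estimate,
    cd_train_rbm,
    dbn_finetune,
    dbn_pretrain,
    dbn_transform,
    finetune_loss,
    head_gradient,
    hidden_given_visible,
    sigmoid,
    visible_given_hidden,
)


def enumerate_boltzmann(rbm):
    """Exact joint distribution over all binary (v, h) states."""
    nv, nh = rbm.visible_dim, rbm.hidden_dim
    states, weights = [], []
    for v in itertools.product((0.0, 1.0), repeat=nv):
        for h in itertools.product((0.0, 1.0), repeat=nh):
            v_ = np.array(v)
            h_ = np.array(h)
            energy = -(v_ @ rbm.W @ h_ + rbm.a @ h_ + rbm.b @ v_)
            states.append((v_, h_))
            weights.append(np.exp(-energy))
    weights = np.array(weights)
    return states, weights / weights.sum()


def exact_loglik_gradient_W(rbm, data):
    """d/dW of the mean log-likelihood, by enumeration of the model term."""
    data = np.atleast_2d(data)
    ph = hidden_given_visible(rbm, data)
    positive = data.T @ ph / data.shape[0]
    states, probs = enumerate_boltzmann(rbm)
    negative = np.zeros_like(rbm.W)
    for (v, h), p in zip(states, probs):
        negative += p * np.outer(v, h)
    return positive - negative


class TestSigmoid:
    def test_zero(self):
        assert sigmoid(0.0) == 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-700, 700, allow_nan=False))
    def test_antisymmetry(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_values_stable(self):
        assert sigmoid(500.0) == pytest.approx(1.0)
        assert sigmoid(-500.0) == pytest.approx(0.0, abs=1e-200)
        assert sigmoid(-500.0) > 0.0

    def test_against_high_precision_oracle(self):
        import sympy

        for x in (-30.0, -2.5, 0.1, 17.0):
            oracle = float(1 / (1 + sympy.exp(-sympy.Float(x, 50))))
            assert sigmoid(x) == pytest.approx(oracle, rel=1e-14)


class TestConditionals:
    def test_zero_parameters_give_half(self):
        rbm = RBM(W=np.zeros((3, 2)), a=np.zeros(2), b=np.zeros(3))
        np.testing.assert_allclose(hidden_given_visible(rbm, np.ones(3)), 0.5)
        np.testing.assert_allclose(visible_given_hidden(rbm, np.ones(2)), 0.5)

    def test_hand_computed_hidden(self):
        rbm = RBM(W=np.array([[1.0], [1.0]]), a=np.zeros(1), b=np.zeros(2))
        p = hidden_given_visible(rbm, np.array([1.0, 1.0]))
        assert p[0] == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_hand_computed_round_trip(self):
        rbm = RBM(W=np.array([[0.5], [-0.5]]), a=np.array([0.1]), b=np.array([0.2, -0.2]))
        h = hidden_given_visible(rbm, np.array([1.0, 0.0]))
        assert h[0] == pytest.approx(sigmoid(0.6))
        v = visible_given_hidden(rbm, h)
        assert v[0] == pytest.approx(sigmoid(0.5 * h[0] + 0.2))
        assert v[1] == pytest.approx(sigmoid(-0.5 * h[0] - 0.2))

    def test_outputs_in_open_interval(self, rng):
        rbm = RBM(W=rng.normal(size=(4, 3)), a=rng.normal(size=3), b=rng.normal(size=4))
        p = hidden_given_visible(rbm, rng.uniform(size=(6, 4)))
        assert np.all(p > 0) and np.all(p < 1)

    def test_dimension_mismatch(self):
        rbm = RBM(W=np.zeros((3, 2)), a=np.zeros(2), b=np.zeros(3))
        with pytest.raises(ValueError):
            hidden_given_visible(rbm, np.ones(4))
        with pytest.raises(ValueError):
            visible_given_hidden(rbm, np.ones(3))


class TestCDTraining:
    def test_reconstruction_error_decreases(self, rng):
        pattern = np.tile([1.0, 0.0, 1.0], (20, 1))
        rbm = RBM.initialize(3, 2, rng)
        trained, log = cd_train_rbm(rbm, pattern, epochs=200, seed=0)
        assert log[-1] < log[0]

    def test_zero_learning_rate_is_noop(self, rng):
        rbm = RBM.initialize(3, 2, rng)
        data = rng.uniform(size=(10, 3))
        trained, _ = cd_train_rbm(rbm, data, epochs=5, learning_rate=0.0, seed=0)
        np.testing.assert_array_equal(trained.W, rbm.W)
        np.testing.assert_array_equal(trained.a, rbm.a)
        np.testing.assert_array_equal(trained.b, rbm.b)

    def test_empty_data_rejected(self, rng):
        rbm = RBM.initialize(3, 2, rng)
        with pytest.raises(ValueError):
            cd_train_rbm(rbm, np.empty((0, 3)), epochs=1)

    def test_determinism(self, rng):
        rbm = RBM.initialize(4, 3, rng)
        data = rng.uniform(size=(12, 4))
        t1, l1 = cd_train_rbm(rbm, data, epochs=10, seed=9)
        t2, l2 = cd_train_rbm(rbm, data, epochs=10, seed=9)
        assert np.array_equal(t1.W, t2.W) and l1 == l2

    def test_row_order_invariance_matched_order(self, rng):
        rbm = RBM.initialize(3, 2, rng)
        data = rng.uniform(size=(9, 3))
        perm = rng.permutation(9)
        order = rng.permutation(9)
        # visiting data[order] must equal visiting data[perm][perm^-1[order]]
        inv = np.empty(9, dtype=int)
        inv[perm] = np.arange(9)
        t1, _ = cd_train_rbm(rbm, data, epochs=8, seed=4, row_order=order)
        t2, _ = cd_train_rbm(rbm, data[perm], epochs=8, seed=4, row_order=inv[order])
        np.testing.assert_array_equal(t1.W, t2.W)

    def test_cd1_gradient_matches_enumeration(self, rng):
        # exact-enumeration oracle on a 2-visible x 2-hidden RBM
        # small weights keep the CD-1 bias below the Monte-Carlo resolution
        rbm = RBM(
            W=rng.normal(0, 0.05, size=(2, 2)),
            a=rng.normal(0, 0.05, size=2),
            b=rng.normal(0, 0.05, size=2),
        )
        data = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        exact = exact_loglik_gradient_W(rbm, data)
        reps = 10_000
        samples = np.empty((reps, 2, 2))
        g = np.random.default_rng(77)
        for r in range(reps):
            row = data[g.integers(len(data))][None, :]
            gw, _, _, _ = cd_gradient_estimate(rbm, row, g)
            samples[r] = gw
        mean = samples.mean(axis=0)
        se = samples.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - exact) <= 3 * se + 1e-4)


class TestGibbsStationary:
    def test_chain_matches_boltzmann(self, rng):
        rbm = RBM(
            W=rng.normal(0, 0.5, size=(2, 2)),
            a=rng.normal(0, 0.3, size=2),
            b=rng.normal(0, 0.3, size=2),
        )
        states, probs = enumerate_boltzmann(rbm)
        keys = {tuple(np.concatenate([v, h])): p for (v, h), p in zip(states, probs)}
        g = np.random.default_rng(5)
        v = (g.uniform(size=2) < 0.5).astype(float)
        counts: dict[tuple, int] = {}
        burn, steps = 500, 40_000
        for step in range(burn + steps):
            ph = hidden_given_visible(rbm, v)
            h = (g.uniform(size=2) < ph).astype(float)
            pv = visible_given_hidden(rbm, h)
            v = (g.uniform(size=2) < pv).astype(float)
            if step >= burn:
                key = tuple(np.concatenate([v, h]))
                counts[key] = counts.get(key, 0) + 1
        tvd = 0.5 * sum(
            abs(counts.get(k, 0) / steps - p) for k, p in keys.items()
        )
        assert tvd < 0.05


class TestDBN:
    def test_pretrain_shapes(self, rng):
        X = rng.uniform(size=(30, 14))
        model = dbn_pretrain(X, [14, 10, 4], epochs=2, seed=0)
        assert model.rbms[0].W.shape == (14, 10)
        assert model.rbms[1].W.shape == (10, 4)
        assert model.layer_sizes == [14, 10, 4]

    def test_pretrain_input_width_checked(self, rng):
        with pytest.raises(ValueError):
            dbn_pretrain(rng.uniform(size=(10, 5)), [4, 3], epochs=1)

    def test_one_layer_equals_single_rbm(self, rng):
        X = rng.uniform(size=(20, 5))
        model = dbn_pretrain(X, [5, 3], epochs=6, seed=11)
        # replicate the internal seed derivation
        child = np.random.SeedSequence(11).spawn(1)[0]
        init_rng = np.random.default_rng(child)
        rbm0 = RBM.initialize(5, 3, init_rng)
        train_seed = int(init_rng.integers(2**31))
        expected, _ = cd_train_rbm(rbm0, X, epochs=6, seed=train_seed)
        np.testing.assert_array_equal(model.rbms[0].W, expected.W)

    def test_layer_chain_validated(self):
        r1 = RBM(W=np.zeros((3, 2)), a=np.zeros(2), b=np.zeros(3))
        r2 = RBM(W=np.zeros((4, 1)), a=np.zeros(1), b=np.zeros(4))
        with pytest.raises(ValueError, match="chain"):
            DBNModel(rbms=[r1, r2])


class TestFinetune:
    def make_latent(self, rng, n=60):
        X = rng.uniform(size=(n, 4))
        y = (X[:, 0] + X[:, 1] > X[:, 2] + X[:, 3]).astype(int)
        return X, y

    def test_zero_epochs_leaves_rbms_unchanged(self, rng):
        X, y = self.make_latent(rng)
        model = dbn_pretrain(X, [4, 3], epochs=2, seed=0)
        tuned = dbn_finetune(model, X, y, epochs=0, seed=1)
        np.testing.assert_array_equal(tuned.rbms[0].W, model.rbms[0].W)
        np.testing.assert_array_equal(tuned.rbms[0].a, model.rbms[0].a)

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = self.make_latent(rng)
        model = dbn_pretrain(X, [4, 4, 3], epochs=3, seed=0)
        before = dbn_finetune(model, X, y, epochs=0, seed=1)
        loss0 = finetune_loss(before, X, y)
        tuned = dbn_finetune(model, X, y, epochs=1000, learning_rate=2.0, seed=1)
        loss1 = finetune_loss(tuned, X, y)
        assert loss1 <= 0.9 * loss0

    def test_head_gradient_matches_finite_differences(self, rng):
        X, y = self.make_latent(rng, n=3)
        model = dbn_pretrain(X, [4, 3], epochs=2, seed=0)
        model = dbn_finetune(model, X, y, epochs=1, learning_rate=0.1, seed=2)
        grad_w, grad_b = head_gradient(model, X, y)
        eps = 1e-6
        for idx in range(3):
            w0 = model.head_w[idx]
            model.head_w[idx] = w0 + eps
            up = finetune_loss(model, X, y)
            model.head_w[idx] = w0 - eps
            down = finetune_loss(model, X, y)
            model.head_w[idx] = w0
            fd = (up - down) / (2 * eps)
            assert grad_w[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_non_binary_labels_rejected(self, rng):
        X, _ = self.make_latent(rng)
        model = dbn_pretrain(X, [4, 3], epochs=1, seed=0)
        with pytest.raises(ValueError):
            dbn_finetune(model, X, np.full(X.shape[0], 2), epochs=1)


class TestTransform:
    def test_zero_weight_model_gives_half(self):
        model = DBNModel(rbms=[RBM(W=np.zeros((3, 2)), a=np.zeros(2), b=np.zeros(3))])
        out = dbn_transform(model, np.random.default_rng(0).uniform(size=(5, 3)))
        np.testing.assert_allclose(out, 0.5)

    def test_default_output_width(self, rng):
        X = rng.uniform(size=(12, 14))
        model = dbn_pretrain(X, [14, 10, 4], epochs=1, seed=0)
        assert dbn_transform(model, X).shape == (12, 4)

    def test_concatenation_consistency(self, rng):
        X = rng.uniform(size=(10, 5))
        model = dbn_pretrain(X, [5, 3], epochs=2, seed=0)
        whole = dbn_transform(model, X)
        parts = np.vstack([dbn_transform(model, X[:4]), dbn_transform(model, X[4:])])
        np.testing.assert_array_equal(whole, parts)

    def test_full_chain_determinism(self, rng):
        X = rng.uniform(size=(25, 5))
        y = (X[:, 0] > 0.5).astype(int)

        def chain():
            m = dbn_pretrain(X, [5, 4, 2], epochs=4, seed=3)
            m = dbn_finetune(m, X, y, epochs=20, seed=4)
            return dbn_transform(m, X)

        np.testing.assert_array_equal(chain(), chain())

    def test_dimension_mismatch(self, rng):
        model = dbn_pretrain(rng.uniform(size=(8, 5)), [5, 3], epochs=1, seed=0)
        with pytest.raises(ValueError):
            dbn_transform(model, rng.uniform(size=(4, 6)))

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.uniform(size=(10, 5))
        y = (X[:, 0] > 0.5).astype(int)
        model = dbn_pretrain(X, [5, 4, 3], epochs=2, seed=0)
        model = dbn_finetune(model, X, y, epochs=5, seed=1)
        path = tmp_path / "dbn.npz"
        model.save(path)
        back = DBNModel.load(path)
        np.testing.assert_array_equal(back.rbms[1].W, model.rbms[1].W)
        np.testing.assert_array_equal(
            dbn_transform(back, X), dbn_transform(model, X)
        )
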