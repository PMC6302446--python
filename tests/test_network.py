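"""Architecture contracts, gradient correctness, training behavior,
drug-slot symmetry, and checkpointing of the response network."""

import numpy as np
import pytest

from comboscreen.estimator import PairResponseRegressor
from comboscreen.network import ConfigurationError, MLPBlock, PairResponseNetwork, train_network

CELL_DIMS = {"expression": 7, "microrna": 4}
DRUG_DIM = 5
N_COLS = sum(CELL_DIMS.values()) + 2 * DRUG_DIM


def tiny_estimator(**overrides):
    params = dict(
        cell_dims=CELL_DIMS,
        drug_dim=DRUG_DIM,
        encoder_layers=(8, 8),
        drug_encoder_layers=(8, 8),
        tower_layers=(8, 8, 8),
        epochs=5,
        batch_size=16,
        validation_fraction=0.0,
        random_state=0,
    )
    params.update(overrides)
    return PairResponseRegressor(**params)


def random_X(rng, n=40):
    return rng.uniform(size=(n, N_COLS))


class TestArchitecture:
    def test_residual_requires_equal_widths(self, rng):
        MLPBlock(5, [8, 8, 8], residual=True, rng=rng)  # fine
        with pytest.raises(ConfigurationError, match="equal"):
            MLPBlock(5, [8, 4], residual=True, rng=rng)

    def test_zero_feature_types_rejected(self):
        est = tiny_estimator(cell_dims={})
        with pytest.raises(ConfigurationError):
            est.fit(np.zeros((10, 2 * DRUG_DIM)), np.zeros(10))

    def test_drug_encoder_weights_shared(self, rng):
        net = PairResponseNetwork(
            CELL_DIMS, DRUG_DIM, (8, 8), (8, 8), (8, 8), residual=True,
            merge="concat", dropout=0.0, rng=rng,
        )
        # one drug-encoder parameter set, listed once
        n_unique = len({id(p) for p in net.parameters()})
        assert n_unique == len(net.parameters())

    def test_parameter_count_reported(self, rng):
        est = tiny_estimator()
        est.fit(random_X(rng), rng.uniform(-1, 1, size=40))
        assert est.n_parameters_ == est.network_.n_parameters() > 0


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients against central finite differences.

        Checked at a generic point: biases start at exactly zero, where dead
        units put ReLU pre-activations exactly on the kink and central
        differences straddle it, so all parameters are jittered first.
        """
        net = PairResponseNetwork(
            {"a": 3}, 2, (4, 4), (4, 4), (4, 4), residual=True,
            merge="concat", dropout=0.0, rng=rng,
        )
        for p in net.parameters():
            p += rng.normal(scale=0.05, size=p.shape)
        blocks = {"a": rng.normal(size=(6, 3))}
        da, db = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        y = rng.normal(size=6)

        def loss():
            pred, _ = net.forward(blocks, da, db)
            return float(np.mean((pred - y) ** 2))

        pred, caches = net.forward(blocks, da, db)
        grads = net.backward(2.0 * (pred - y) / len(y), caches)
        params = net.parameters()
        eps = 1e-6
        rs = np.random.default_rng(0)
        for p, g in zip(params, grads):
            idx = tuple(rs.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = loss()
            p[idx] = orig - eps
            down = loss()
            p[idx] = orig
            fd = (up - down) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, rng):
        X = random_X(rng, n=200)
        w = rng.normal(size=N_COLS)
        y = np.tanh(X @ w / 4)
        est = tiny_estimator(epochs=30)
        est.fit(X, y)
        assert est.history_.train_mse[-1] < est.history_.train_mse[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        X, y = random_X(rng), rng.uniform(-1, 1, size=40)
        est = tiny_estimator(learning_rate=0.0, reduce_on_plateau=None)
        est.fit(X, y)
        before = [p.copy() for p in est.network_.parameters()]
        # refit with identical config reproduces the same init; compare to a
        # second zero-rate run to confirm no updates happened
        est2 = tiny_estimator(learning_rate=0.0, reduce_on_plateau=None)
        est2.fit(X, y)
        for p1, p2 in zip(before, est2.network_.parameters()):
            np.testing.assert_array_equal(p1, p2)
        assert len(set(np.round(est.history_.train_mse, 12))) == 1  # flat history

    def test_same_seed_identical_final_loss(self, rng):
        X, y = random_X(rng, n=100), rng.uniform(-1, 1, size=100)
        runs = [tiny_estimator(epochs=8).fit(X, y).history_.train_mse[-1] for _ in range(2)]
        assert runs[0] == runs[1]

    def test_non_finite_loss_aborts_with_diagnostic(self, rng):
        X, y = random_X(rng), rng.uniform(-1, 1, size=40)
        est = tiny_estimator(learning_rate=1e6, optimizer="sgd", epochs=10)
        with pytest.raises(RuntimeError, match="non-finite"):
            est.fit(X, y * 1e6)

    def test_residual_helps_deep_tower(self, rng):
        """Trend-level: a deep residual tower beats the plain one in >= 3 of
        5 seeds under plain SGD, where skip connections genuinely ease
        optimization (adaptive preconditioning masks the effect)."""
        X = random_X(rng, n=150)
        w = rng.normal(size=N_COLS)
        y = np.tanh(X @ w / 4)
        wins = 0
        for seed in range(5):
            losses = {}
            for res in (True, False):
                est = tiny_estimator(tower_layers=(8,) * 10, residual=res,
                                     optimizer="sgd", learning_rate=1e-2,
                                     reduce_on_plateau=None, epochs=30,
                                     random_state=seed)
                est.fit(X, y)
                losses[res] = est.history_.train_mse[-1]
            wins += losses[True] < losses[False]
        assert wins >= 3


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(3)
        X, y = random_X(rng, n=80), rng.uniform(-1, 1, size=80)
        return tiny_estimator().fit(X, y)

    def _swap_slots(self, X):
        n_cell = sum(CELL_DIMS.values())
        out = X.copy()
        out[:, n_cell:n_cell + DRUG_DIM] = X[:, n_cell + DRUG_DIM:]
        out[:, n_cell + DRUG_DIM:] = X[:, n_cell:n_cell + DRUG_DIM]
        return out

    def test_slot_symmetry_under_averaged_inference(self, fitted, rng):
        X = random_X(rng, n=100)
        np.testing.assert_allclose(
            fitted.predict(X), fitted.predict(self._swap_slots(X)), atol=1e-6
        )

    def test_slot_symmetry_under_sum_merge(self, rng):
        X, y = random_X(rng, n=60), rng.uniform(-1, 1, size=60)
        est = tiny_estimator(symmetrize="sum").fit(X, y)
        np.testing.assert_allclose(
            est.predict(X), est.predict(self._swap_slots(X)), atol=1e-9
        )

    def test_ordered_concat_is_order_sensitive(self, rng):
        """The literal design without symmetrization depends on slot order."""
        X, y = random_X(rng, n=60), rng.uniform(-1, 1, size=60)
        est = tiny_estimator(symmetrize="none").fit(X, y)
        diff = np.abs(est.predict(X) - est.predict(self._swap_slots(X)))
        assert diff.max() > 1e-6

    def test_single_drug_equals_replicated_slots(self, fitted, rng):
        n_cell = sum(CELL_DIMS.values())
        Xs = rng.uniform(size=(20, n_cell + DRUG_DIM))
        drug = Xs[:, n_cell:]
        np.testing.assert_array_equal(
            fitted.predict_single(Xs), fitted.predict(np.hstack([Xs, drug]))
        )

    def test_batch_order_invariance_and_duplicates(self, fitted, rng):
        X = random_X(rng, n=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(fitted.predict(X)[perm], fitted.predict(X[perm]), atol=1e-12)
        X2 = np.vstack([X[:1], X[:1]])
        p = fitted.predict(X2)
        assert p[0] == p[1]
        assert np.isfinite(fitted.predict(X)).all()

    def test_width_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError, match="columns"):
            fitted.predict(np.zeros((3, N_COLS + 1)))


def test_checkpoint_roundtrip(tmp_path, rng):
    X, y = random_X(rng, n=50), rng.uniform(-1, 1, size=50)
    est = tiny_estimator(n_ensemble=2).fit(X, y)
    path = tmp_path / "model.npz"
    est.save(path)
    back = PairResponseRegressor.load(path)
    np.testing.assert_array_equal(est.predict(X), back.predict(X))
    assert back.get_params() == est.get_params()
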