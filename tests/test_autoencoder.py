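import math

import numpy as np
import pytest

from kinlatent import (
    TrainingConfig,
    adam_step,
    decode,
    encode,
    fit_pca,
    forward,
    hyperparameter_sweep,
    init_model,
    loss_and_gradients,
    pca_decode,
    pca_encode,
    train,
    vaf,
)
from kinlatent.autoencoder import (
    AdamState,
    AutoencoderError,
    AutoencoderModel,
    TrainingDivergenceError,
)


def _toy_model():
    """2 channels -> 2 hidden -> 1 CU -> 2 hidden -> 2 channels, fixed weights."""
    return AutoencoderModel(
        w1=np.array([[0.1, -0.2], [0.3, 0.4]]),
        b1=np.array([0.05, -0.1]),
        w2=np.array([[0.7], [-0.5]]),
        b2=np.array([0.2]),
        w3=np.array([[0.6, -0.3]]),
        b3=np.array([0.1, 0.2]),
        w4=np.array([[0.8, -0.4], [0.5, 0.9]]),
        b4=np.array([0.0, 0.1]),
        hidden_size=2,
        bottleneck_size=1,
        activation="tanh",
    )


class TestInit:
    def test_same_seed_identical_parameters(self):
        a = init_model(20, 10, 2, seed=3)
        b = init_model(20, 10, 2, seed=3)
        for key, p in a.params().items():
            np.testing.assert_array_equal(p, b.params()[key])

    def test_shapes_chain_and_biases_zero(self):
        m = init_model(20, 10, 2, seed=0)
        assert m.w1.shape == (20, 10)
        assert m.w2.shape == (10, 2)
        assert m.w3.shape == (2, 10)
        assert m.w4.shape == (10, 20)
        for b in (m.b1, m.b2, m.b3, m.b4):
            assert (b == 0).all()

    def test_glorot_bounds_respected(self):
        m = init_model(20, 10, 2, seed=1)
        assert np.abs(m.w1).max() <= math.sqrt(6 / 30)
        assert np.abs(m.w2).max() <= math.sqrt(6 / 12)

    def test_non_bottleneck_rejected(self):
        with pytest.raises(AutoencoderError):
            init_model(20, 10, 20, seed=0)


class TestForwardPass:
    def test_zero_weights_give_zero_latent(self):
        m = _toy_model()
        m = m.with_params({k: np.zeros_like(v) for k, v in m.params().items()})
        Z = encode(m, np.random.default_rng(0).standard_normal((5, 2)))
        assert (Z.A == 0).all()

    def test_zero_first_layer_latent_is_bottleneck_bias(self):
        m = _toy_model()
        params = m.params()
        params["w1"] = np.zeros_like(params["w1"])
        params["b1"] = np.zeros_like(params["b1"])
        m = m.with_params(params)
        Z = encode(m, np.ones((4, 2)))
        np.testing.assert_allclose(Z.A, np.full((4, 1), 0.2))

    def test_constant_output_from_zero_decoder_weights(self):
        m = _toy_model()
        params = m.params()
        params["w4"] = np.zeros_like(params["w4"])
        params["b4"] = np.array([2.5, -1.0])
        m = m.with_params(params)
        out = decode(m, np.linspace(-1, 1, 7)[:, None])
        np.testing.assert_allclose(out, np.tile([2.5, -1.0], (7, 1)))

    def test_hand_computed_single_sample(self):
        """Independent scalar arithmetic through all four layers."""
        m = _toy_model()
        x1, x2 = 0.3, -0.6
        l1a = math.tanh(x1 * 0.1 + x2 * 0.3 + 0.05)
        l1b = math.tanh(x1 * -0.2 + x2 * 0.4 - 0.1)
        z = l1a * 0.7 + l1b * -0.5 + 0.2
        l3a = math.tanh(z * 0.6 + 0.1)
        l3b = math.tanh(z * -0.3 + 0.2)
        y1 = l3a * 0.8 + l3b * 0.5
        y2 = l3a * -0.4 + l3b * 0.9 + 0.1
        X = np.array([[x1, x2]])
        np.testing.assert_allclose(encode(m, X).A, [[z]], atol=1e-12)
        np.testing.assert_allclose(forward(m, X), [[y1, y2]], atol=1e-12)

    def test_decode_of_encode_equals_forward(self):
        m = init_model(6, 4, 2, seed=5)
        X = np.random.default_rng(5).uniform(-1, 1, (30, 6))
        np.testing.assert_allclose(decode(m, encode(m, X)), forward(m, X))

    def test_column_mismatch_rejected(self):
        m = _toy_model()
        with pytest.raises(AutoencoderError, match="columns"):
            encode(m, np.zeros((3, 5)))


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "sigmoid", "relu"])
    def test_backprop_matches_central_finite_differences(self, activation):
        rng = np.random.default_rng(17)
        m = init_model(4, 3, 2, activation=activation, seed=17)
        X = rng.uniform(-1, 1, (6, 4))
        _, grads = loss_and_gradients(m, X)
        eps = 1e-6
        for key, p in m.params().items():
            numeric = np.zeros_like(p)
            flat = p.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = loss_and_gradients(m, X)
                flat[i] = orig - eps
                lm, _ = loss_and_gradients(m, X)
                flat[i] = orig
                numeric.ravel()[i] = (lp - lm) / (2 * eps)
            denom = max(np.abs(numeric).max(), np.abs(grads[key]).max(), 1e-8)
            rel = np.abs(grads[key] - numeric).max() / denom
            assert rel < 1e-5, f"{activation}/{key}: rel err {rel}"

    def test_perfect_reconstruction_has_zero_loss_and_gradients(self):
        # identity activation + identity weight blocks reproduce X exactly
        c = 3
        m = AutoencoderModel(
            w1=np.eye(c, 4), b1=np.zeros(4),
            w2=np.eye(4, 2), b2=np.zeros(2),
            w3=np.eye(2, 4), b3=np.zeros(4),
            w4=np.eye(4, c), b4=np.zeros(c),
            hidden_size=4, bottleneck_size=2, activation="identity",
        )
        X = np.random.default_rng(0).standard_normal((10, c))
        X[:, 2] = 0.0  # confine data to the preserved 2-D coordinates
        X[:, :2] = X[:, :2]
        loss, grads = loss_and_gradients(m, X)
        assert loss == pytest.approx(0.0, abs=1e-24)
        for g in grads.values():
            assert np.abs(g).max() < 1e-12

    def test_loss_is_quadratic_in_residual(self):
        m = _toy_model()
        X = np.zeros((4, 2))
        params = m.params()
        params = {k: np.zeros_like(v) for k, v in params.items()}
        params["b4"] = np.array([1.0, 1.0])
        loss1, _ = loss_and_gradients(m.with_params(params), X)
        params["b4"] = np.array([2.0, 2.0])
        loss2, _ = loss_and_gradients(m.with_params(params), X)
        assert loss2 == pytest.approx(4 * loss1)


class TestAdam:
    def test_first_step_is_signed_learning_rate(self):
        params = {"w": np.array([1.0, -2.0, 3.0])}
        grads = {"w": np.array([0.5, -0.1, 2.0])}
        state = AdamState.zeros_like(params)
        config = TrainingConfig(learning_rate=0.01)
        new, _ = adam_step(params, grads, state, config)
        np.testing.assert_allclose(
            new["w"], params["w"] - 0.01 * np.sign(grads["w"]), atol=1e-6
        )

    def test_zero_gradient_never_moves(self):
        params = {"w": np.array([1.5])}
        state = AdamState.zeros_like(params)
        config = TrainingConfig()
        for _ in range(20):
            params, state = adam_step(params, {"w": np.zeros(1)}, state, config)
        assert params["w"][0] == 1.5

    def test_descends_a_scalar_quadratic(self):
        params = {"w": np.array([1.0])}
        state = AdamState.zeros_like(params)
        config = TrainingConfig(learning_rate=0.01)
        history = []
        for _ in range(100):
            grads = {"w": 2.0 * params["w"]}
            params, state = adam_step(params, grads, state, config)
            history.append(abs(params["w"][0]))
        assert all(b < a for a, b in zip(history[10:-1], history[11:]))
        assert history[-1] < 1.0


class TestTraining:
    def test_zero_steps_returns_initial_model(self, linear_clean_active):
        m = init_model(20, 10, 2, seed=0)
        trained, trace = train(m, linear_clean_active.X, TrainingConfig(steps=0))
        assert trace.steps_run == 0
        for key, p in m.params().items():
            np.testing.assert_array_equal(p, trained.params()[key])

    def test_training_is_seed_deterministic(self, linear_clean_active):
        X = linear_clean_active.X[:400]
        config = TrainingConfig(steps=50)
        out = []
        for _ in range(2):
            m = init_model(20, 8, 2, seed=9)
            trained, trace = train(m, X, config)
            out.append((trained, trace))
        for key, p in out[0][0].params().items():
            np.testing.assert_array_equal(p, out[1][0].params()[key])
        np.testing.assert_array_equal(out[0][1].loss_per_step, out[1][1].loss_per_step)

    def test_loss_trace_finite_and_decreasing_overall(self, nonlinear_active):
        m = init_model(20, 10, 2, seed=0)
        trained, trace = train(m, nonlinear_active.X, TrainingConfig(steps=300))
        assert np.isfinite(trace.loss_per_step).all()
        assert trace.loss_per_step[-1] < trace.loss_per_step[0]
        assert trace.final_vaf_train > 50.0

    def test_divergence_raises_with_step_number(self, nonlinear_active):
        m = init_model(20, 10, 2, seed=0)
        # absurd learning rate on relu drives the loss to overflow
        config = TrainingConfig(learning_rate=1e80, steps=10, activation="relu")
        with pytest.raises(TrainingDivergenceError, match="step"):
            train(m, nonlinear_active.X * 1e3, config)

    def test_linear_limit_matches_pca_subspace(self, linear_clean_active):
        """Identity activations recover the classical linear-AE/PCA equivalence."""
        X = linear_clean_active.X
        model = init_model(20, 10, 2, activation="identity", seed=2)
        trained, _ = train(
            model, X, TrainingConfig(steps=1500, activation="identity")
        )
        ae_vaf = vaf(X, forward(trained, X)).aggregate_vaf
        pca_model = fit_pca(X)
        pca_vaf = vaf(
            X, pca_decode(pca_model, pca_encode(pca_model, X, 2))
        ).aggregate_vaf
        assert ae_vaf == pytest.approx(pca_vaf, abs=2.0)


@pytest.fixture(scope="module")
def small_X(nonlinear_active):
    return nonlinear_active.X[::6]


class TestSweep:
    def test_single_point_grid_equals_direct_cv(self, small_X):
        from kinlatent import kfold_indices

        table = hyperparameter_sweep(
            small_X, {"learning_rate": [0.01], "steps": [40]}, folds=3, seed=0
        )
        assert len(table) == 3
        direct = []
        for tr, te in kfold_indices(small_X.shape[0], k=3, seed=0):
            m = init_model(small_X.shape[1], 10, 2, activation="tanh", seed=0)
            trained, _ = train(
                m, small_X[tr], TrainingConfig(learning_rate=0.01, steps=40, seed=0)
            )
            direct.append(vaf(small_X[te], forward(trained, small_X[te])).aggregate_vaf)
        np.testing.assert_allclose(np.sort(table["vaf"]), np.sort(direct), atol=1e-9)
        assert table["mean_vaf"].iloc[0] == pytest.approx(np.mean(direct))

    def test_reference_grid_is_expressible_and_largest_lr_not_best(self, small_X):
        grid = {
            "learning_rate": [0.001, 0.01, 0.025, 0.05],
            "steps": [60],
            "activation": ["tanh"],
        }
        table = hyperparameter_sweep(small_X, grid, folds=3, seed=1)
        means = table.groupby("learning_rate")["mean_vaf"].first()
        assert set(means.index) == {0.001, 0.01, 0.025, 0.05}
        assert means[0.05] <= means.max()

    def test_activation_aliases_accepted(self, small_X):
        table = hyperparameter_sweep(
            small_X,
            {"activation": ["tanh", "relu", "sig"], "steps": [30]},
            folds=3,
            seed=0,
        )
        assert set(table["activation"]) == {"tanh", "relu", "sig"}
        assert table["vaf"].notna().all()

    def test_empty_grid_rejected(self, small_X):
        with pytest.raises(AutoencoderError):
            hyperparameter_sweep(small_X, {})
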