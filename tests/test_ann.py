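"""Network core: activations, forward pass, backprop, Rprop training, SDAE."""

import json

import numpy as np
import pytest

from odormix.ann import (
    ANNModel,
    ANNStructure,
    DAEConfig,
    LEAKY_RELU,
    TANH,
    TrainConfig,
    ActivationKind,
    activation_eval,
    dae_reconstruction_losses,
    glorot_init,
    loss_and_gradients,
    pretrain_sdae,
    rprop_minimize,
    train_network,
    _forward,
)
from odormix.errors import ConfigError, TrainingError
from odormix.preprocessing import identity_normalizer, identity_output_scaler


def naive_forward(weights, activations, x):
    """Independent neuron-by-neuron evaluator used as an oracle."""
    y = list(x)
    for w, act in zip(weights, activations):
        z = []
        for row in w:
            acc = row[0]
            for wj, yj in zip(row[1:], y):
                acc += wj * yj
            z.append(acc)
        y = [float(activation_eval(act, zi)[0]) for zi in z]
    return y[0]


def random_model(structure, rng):
    weights = glorot_init(structure.layer_sizes, rng)
    for w in weights:
        w[:, 0] = rng.normal(0, 0.3, size=w.shape[0])  # nonzero thresholds
    return weights


class TestActivations:
    def test_tanh_at_zero(self):
        v, d = activation_eval(TANH, 0.0)
        assert v == 0.0 and d == 1.0

    def test_leaky_relu_negative(self):
        v, d = activation_eval(LEAKY_RELU, -2.0)
        assert v == pytest.approx(-0.06) and d == pytest.approx(0.03)

    def test_leaky_relu_positive(self):
        v, d = activation_eval(LEAKY_RELU, 5.0)
        assert v == 5.0 and d == 1.0

    def test_invalid_leak_rejected(self):
        with pytest.raises(ConfigError):
            ActivationKind("leaky_relu", 1.5)


class TestStructureParsing:
    def test_zero_middle_layer_dropped(self):
        s = ANNStructure.from_string("8-3-0-1")
        assert s.layer_sizes == (8, 3, 1)

    def test_two_hidden_layers(self):
        s = ANNStructure.from_string("8-5-4-1")
        assert s.layer_sizes == (8, 5, 4, 1)
        assert s.n_weights == 5 * 9 + 4 * 6 + 1 * 5

    def test_io_widths_enforced(self):
        with pytest.raises(ConfigError):
            ANNStructure((7, 3, 1))


class TestForwardPass:
    def test_zero_network(self):
        s = ANNStructure.from_string("8-3-3-1")
        weights = [np.zeros(shape) for shape in
                   [(3, 9), (3, 4), (1, 4)]]
        model = ANNModel(s, weights, identity_normalizer(), identity_output_scaler())
        pred, _ = model.forward_pass(np.ones(8), raw=False)
        assert pred == 0.0  # linear output of all-zero weights

    def test_single_linear_wiring(self):
        s = ANNStructure((8, 1), TANH)
        w = np.zeros((1, 9))
        w[0, 1] = 1.0
        model = ANNModel(s, [w], identity_normalizer(), identity_output_scaler())
        x = np.arange(8.0)
        pred, _ = model.forward_pass(x, raw=False)
        assert pred == x[0]

    @pytest.mark.parametrize("text,act", [("8-3-3-1", TANH), ("8-5-2-1", LEAKY_RELU)])
    def test_matches_naive_evaluator(self, text, act):
        rng = np.random.default_rng(4)
        s = ANNStructure.from_string(text, act)
        weights = random_model(s, rng)
        for _ in range(50):
            x = rng.normal(size=8)
            acts, _ = _forward(weights, s.activations(), x[None, :])
            assert acts[-1][0, 0] == pytest.approx(
                naive_forward(weights, s.activations(), x), abs=1e-12
            )


class TestGradients:
    def test_perfect_fit_zero_gradient(self):
        s = ANNStructure((8, 1), TANH)  # linear output layer only
        w = np.zeros((1, 9))
        w[0, 1:] = 1.0
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 8))
        y = X.sum(axis=1)
        mse, grads = loss_and_gradients([w], s.activations(), X, y)
        assert mse == pytest.approx(0.0, abs=1e-24)
        assert all(np.allclose(g, 0.0) for g in grads)

    def test_batch_duplication_invariance(self):
        rng = np.random.default_rng(5)
        s = ANNStructure.from_string("8-3-2-1", TANH)
        weights = random_model(s, rng)
        X = rng.normal(size=(9, 8))
        y = rng.normal(size=9)
        m1, g1 = loss_and_gradients(weights, s.activations(), X, y)
        m2, g2 = loss_and_gradients(
            weights, s.activations(), np.vstack([X, X]), np.concatenate([y, y])
        )
        assert m1 == pytest.approx(m2)
        for a, b in zip(g1, g2):
            np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("act", [TANH, LEAKY_RELU])
    def test_matches_finite_differences(self, act):
        rng = np.random.default_rng(6)
        s = ANNStructure.from_string("8-3-2-1", act)
        weights = random_model(s, rng)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        _, grads = loss_and_gradients(weights, s.activations(), X, y)
        h = 1e-6
        for li, w in enumerate(weights):
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[idx]
                w[idx] = orig + h
                up, _ = loss_and_gradients(weights, s.activations(), X, y)
                w[idx] = orig - h
                dn, _ = loss_and_gradients(weights, s.activations(), X, y)
                w[idx] = orig
                fd = (up - dn) / (2 * h)
                assert grads[li][idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestTraining:
    def test_fits_realizable_linear_target(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + 0.5
        model = train_network(
            ANNStructure((8, 1), TANH), X, y,
            TrainConfig(max_epochs=800, tol=1e-8, seed=0),
        )
        assert min(model.training_log) < 1e-6

    def test_seed_repeat_identical_weights(self, small_study):
        X = np.stack([r.sensors.as_array() for r in small_study.train_val_samples])
        y = np.array([r.panel.oi_mean for r in small_study.train_val_samples])
        Xn = (X - X.mean(0)) / X.std(0)
        s = ANNStructure.from_string("8-3-3-1", TANH)
        m1 = train_network(s, Xn, y, TrainConfig(max_epochs=50, seed=3))
        m2 = train_network(s, Xn, y, TrainConfig(max_epochs=50, seed=3))
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_best_so_far_loss_non_increasing(self, small_study):
        X = np.stack([r.sensors.as_array() for r in small_study.train_val_samples])
        y = np.array([r.panel.oi_mean for r in small_study.train_val_samples])
        Xn = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        model = train_network(
            ANNStructure.from_string("8-3-3-1", TANH), Xn, ys,
            TrainConfig(max_epochs=150, seed=1),
        )
        best = np.minimum.accumulate(model.training_log)
        assert np.all(np.diff(best) <= 0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises_with_epoch(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 8)) * 1e200
        y = rng.normal(size=10) * 1e200
        with pytest.raises(TrainingError):
            train_network(
                ANNStructure((8, 1), TANH), X, y,
                TrainConfig(max_epochs=60, initial_step=1.0, seed=0),
            )

    def test_minibatch_not_supported(self):
        with pytest.raises(ConfigError):
            TrainConfig(batch="minibatch:16")


class TestSDAE:
    def _normalized_inputs(self, study):
        X = np.stack([r.sensors.as_array() for r in study.train_val_samples])
        return (X - X.mean(0)) / X.std(0)

    def test_deterministic_given_seed(self, small_study):
        Xn = self._normalized_inputs(small_study)
        s = ANNStructure.from_string("8-3-3-1", TANH)
        w1 = pretrain_sdae(s, Xn, DAEConfig(seed=5))
        w2 = pretrain_sdae(s, Xn, DAEConfig(seed=5))
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_reconstruction_loss_halves(self, small_study):
        Xn = self._normalized_inputs(small_study)
        s = ANNStructure.from_string("8-3-3-1", TANH)
        for initial, final in dae_reconstruction_losses(s, Xn, DAEConfig(seed=0)):
            assert final <= 0.5 * initial

    def test_wide_autoencoder_beats_identity_start(self, small_study):
        # width == input dim: reconstruction is realizable; training should at
        # least match the identity-initialized autoencoder's clean loss
        Xn = self._normalized_inputs(small_study)
        cfg = DAEConfig(corruption_sd=0.0, epochs=400, seed=2)
        losses = dae_reconstruction_losses(ANNStructure((8, 8, 1), TANH), Xn, cfg)
        ident = [np.hstack([np.zeros((8, 1)), np.eye(8) * 0.5])] * 1  # tanh-scale identity
        enc = ident[0]
        hidden = np.tanh(Xn @ enc[:, 1:].T + enc[:, 0])
        dec = np.linalg.lstsq(np.hstack([np.ones((len(Xn), 1)), hidden]), Xn, rcond=None)[0]
        ident_mse = float(np.mean(np.sum((np.hstack([np.ones((len(Xn), 1)), hidden]) @ dec - Xn) ** 2, axis=1)))
        assert losses[0][1] <= ident_mse + 1e-6


class TestPersistence:
    def test_json_round_trip_bit_exact(self, small_study):
        X = np.stack([r.sensors.as_array() for r in small_study.train_val_samples])
        y = np.array([r.panel.oi_mean for r in small_study.train_val_samples])
        Xn = (X - X.mean(0)) / X.std(0)
        model = train_network(
            ANNStructure.from_string("8-3-2-1", LEAKY_RELU), Xn, y,
            TrainConfig(max_epochs=40, seed=2),
        )
        text = model.to_json()
        clone = ANNModel.from_json(text)
        assert clone.to_json() == text
        x = np.linspace(-1, 1, 8)
        assert clone.forward_pass(x, raw=False)[0] == model.forward_pass(x, raw=False)[0]
        json.loads(text)  # valid JSON document


def test_leaky_relu_positive_homogeneity():
    # zero thresholds: scaling a positive-cone input scales every layer output
    rng = np.random.default_rng(9)
    s = ANNStructure.from_string("8-4-3-1", LEAKY_RELU)
    weights = glorot_init(s.layer_sizes, rng)
    x = np.abs(rng.normal(size=8))
    acts1, _ = _forward(weights, s.activations(), x[None, :])
    acts2, _ = _forward(weights, s.activations(), (3.0 * x)[None, :])
    np.testing.assert_allclose(acts2[-1], 3.0 * acts1[-1], rtol=1e-12)
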