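"""Network mechanics (shapes, gradients, determinism) and the ML baselines."""

import numpy as np
import pytest

from tremorsep.classifiers import (ClassifierSpec, TrainConfig,
                                   build_conv_bilstm, build_conv_lstm,
                                   gnb_baseline, knn_baseline, predict,
                                   train_model)
from tremorsep.nn import BuildError, ConvRecurrentNet, sequence_lengths

from oracles import brute_force_knn

class TestArchitecture:
    def test_same_padding_shape_trace(self):
        # 50 -> 25 -> 25 -> 12 timesteps into the LSTM
        assert sequence_lengths(50, 20, 10, 2, "same") == [50, 25, 25, 12]
        net = build_conv_bilstm()
        assert net.seq_lens[-1] == 12

    def test_valid_padding_shape_trace(self):
        assert sequence_lengths(50, 20, 10, 2, "valid") == [31, 15, 6, 3]

    def test_collapsed_sequence_raises_with_shape_trace(self):
        with pytest.raises(BuildError):
            ConvRecurrentNet(input_len=20, conv1_kernel=20, conv2_kernel=10,
                             padding="valid")

    def test_output_strictly_in_unit_interval(self):
        net = build_conv_bilstm(seed=0)
        X = np.random.default_rng(0).standard_normal((8, 50)) * 10
        p = net.forward(X)
        assert np.all((p > 0) & (p < 1))

    def test_same_seed_identical_initial_weights(self):
        a, b = build_conv_bilstm(seed=3), build_conv_bilstm(seed=3)
        for k, v in a.parameters().items():
            np.testing.assert_array_equal(v, b.parameters()[k])

    def test_unidirectional_has_fewer_parameters(self):
        assert (build_conv_lstm(seed=0).n_parameters
                < build_conv_bilstm(seed=0).n_parameters)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        net = ConvRecurrentNet(input_len=20, conv1_filters=3, conv1_kernel=5,
                               conv2_filters=3, conv2_kernel=3, lstm_cells=4,
                               bidirectional=True, seed=0)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 20))
        y = (rng.random(5) > 0.5).astype(float)

        def loss():
            p = np.clip(net.forward(X), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        loss()
        grads = net.backward(y)
        eps = 1e-6
        for name, p in net.parameters().items():
            g = grads[name].reshape(p.shape)
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-5 * max(abs(num), abs(g[idx]), 1.0), \
                f"{name}: analytic {g[idx]} vs numeric {num}"


@pytest.fixture(scope="module")
def toy_tones():
    """Linearly separable: 6 Hz (tremor) vs 1 Hz (voluntary) windows."""
    rng = np.random.default_rng(0)
    t = np.arange(50) / 100
    X = np.stack([np.sin(2 * np.pi * (6.0 if i % 2 else 1.0) * t
                         + rng.uniform(0, 2 * np.pi)) for i in range(128)])
    y = np.arange(128) % 2
    return X, y


class TestTraining:

    def test_separable_tones_are_learned(self, toy_tones):
        X, y = toy_tones
        net = build_conv_bilstm(seed=0)
        hist = train_model(net, X, y, TrainConfig(epochs=60, seed=0))
        _, y_hat = predict(net, X)
        assert (y_hat == y).mean() >= 0.99
        assert np.all(np.isfinite(hist))
        assert hist[-1] < hist[0]

    def test_same_seed_identical_final_weights(self, toy_tones):
        X, y = toy_tones
        runs = []
        for _ in range(2):
            net = build_conv_bilstm(seed=1)
            train_model(net, X, y, TrainConfig(epochs=2, seed=1))
            runs.append({k: v.copy() for k, v in net.parameters().items()})
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_single_class_rejected(self):
        X = np.zeros((10, 50))
        with pytest.raises(ValueError):
            train_model(build_conv_bilstm(seed=0), X, np.ones(10),
                        TrainConfig(epochs=1))


class TestPredict:
    def test_threshold_tie_goes_positive(self):
        net = build_conv_bilstm(seed=0)
        scores = np.array([0.49, 0.5, 0.51])
        labels = (scores >= 0.5).astype(int)
        assert labels.tolist() == [0, 1, 1]  # documented >= convention
        # and the real path is deterministic across calls
        X = np.random.default_rng(0).standard_normal((4, 50))
        s1, l1 = predict(net, X)
        s2, l2 = predict(net, X)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(l1, l2)

    def test_batch_equals_per_sample(self):
        net = build_conv_bilstm(seed=2)
        X = np.random.default_rng(3).standard_normal((7, 50))
        batch, _ = predict(net, X)
        singles = np.array([predict(net, X[i:i + 1])[0][0]
                            for i in range(7)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_wrong_window_length_rejected(self):
        net = build_conv_bilstm(seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 40)))



class TestKNN:
    def test_duplicated_training_point_wins(self):
        F = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 1, 1, 0])
        assert knn_baseline(F, y, np.array([[0.0, 0.0]]))[0] == 1

    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(40, 4))
        b = rng.normal(10, 1, size=(40, 4))
        F = np.vstack([a, b])
        y = np.array([0] * 40 + [1] * 40)
        test = np.vstack([rng.normal(0, 1, size=(10, 4)),
                          rng.normal(10, 1, size=(10, 4))])
        expect = np.array([0] * 10 + [1] * 10)
        np.testing.assert_array_equal(knn_baseline(F, y, test), expect)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        F = rng.standard_normal((50, 4))
        y = (rng.random(50) > 0.5).astype(int)
        test = rng.standard_normal((20, 4))
        # oracle works in the same standardized space as the implementation
        mu, sd = F.mean(axis=0), F.std(axis=0)
        np.testing.assert_array_equal(
            knn_baseline(F, y, test),
            brute_force_knn((F - mu) / sd, y, (test - mu) / sd))

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            knn_baseline(np.zeros((2, 4)), np.array([0, 1]), np.zeros((1, 4)),
                         k=3)


class TestGNB:
    def test_symmetric_tie_goes_positive(self):
        F = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        labels, proba = gnb_baseline(F, y, np.array([[0.0]]),
                                     return_proba=True)
        assert proba[0] == pytest.approx(0.5, abs=1e-9)
        assert labels[0] == 1

    def test_decision_boundary_of_known_gaussians(self):
        rng = np.random.default_rng(0)
        n = 4000
        F = np.vstack([rng.normal(0, 1, size=(n, 1)),
                       rng.normal(4, 1, size=(n, 1))])
        y = np.array([0] * n + [1] * n)
        grid = np.linspace(0, 4, 401)[:, None]
        labels = gnb_baseline(F, y, grid)
        boundary = grid[np.argmax(labels), 0]
        assert boundary == pytest.approx(2.0, abs=0.15)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((40, 4))
        y = (rng.random(40) > 0.5).astype(int)
        test = rng.standard_normal((10, 4))
        _, p_pos = gnb_baseline(F, y, test, return_proba=True)
        assert np.all((p_pos >= 0) & (p_pos <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gnb_baseline(np.zeros((5, 2)), np.ones(5, dtype=int),
                         np.zeros((1, 2)))
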