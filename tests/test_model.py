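"""The masked LSTM classifier: closed forms, gradients, training, masking."""

import math

import numpy as np
import pytest
import scipy.special

from dragtraj.model import (
    ClassifierModel,
    DivergenceError,
    ModelConfig,
    build_model,
    cross_entropy,
    load_model,
    predict_label,
    predict_proba,
    save_model,
    softmax,
    train,
)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax([0.0, math.log(3.0)]), [0.25, 0.75], atol=1e-12
        )

    def test_overflow_safety_and_shift_invariance(self):
        np.testing.assert_allclose(softmax([1000.0, 1000.0]), [0.5, 0.5])
        z = np.array([1.3, -0.2, 4.0])
        np.testing.assert_allclose(softmax(z), softmax(z + 123.456), atol=1e-12)

    def test_matches_reference_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            z = rng.normal(0, 5, size=rng.integers(2, 6))
            np.testing.assert_allclose(
                softmax(z), scipy.special.softmax(z), atol=1e-9
            )


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0)

    def test_uninformative_prediction_is_ln2(self):
        assert cross_entropy([0.0, 1.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_confident_correct_prediction(self):
        assert cross_entropy([0.0, 1.0], [0.1, 0.9]) == pytest.approx(
            -math.log(0.9), abs=1e-9
        )

    def test_matches_reference_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.dirichlet(np.ones(2))
            y = np.eye(2)[rng.integers(0, 2)]
            expected = float(-scipy.special.xlogy(y, np.clip(p, 1e-12, None)).sum())
            assert cross_entropy(y, p) == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy([1.0, 0.0], [0.2, 0.3, 0.5])


class TestArchitecture:
    def test_model_accepts_69_by_2_sequences(self):
        model = build_model(ModelConfig(seed=0), "two_feature")
        probs = predict_proba(model, np.zeros((3, 69, 2)) + 0.5)
        assert probs.shape == (3, 2)

    def test_output_rows_are_probability_pairs(self):
        rng = np.random.default_rng(2)
        model = build_model(ModelConfig(seed=1), "four_feature")
        probs = predict_proba(model, rng.normal(size=(10, 69, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs > 0).all()

    def test_recurrent_width_matches_config(self):
        model = build_model(ModelConfig(lstm_units=64, seed=0), "two_feature")
        assert model.params["Wh"].shape == (64, 4 * 64)

    def test_feature_count_mismatch_rejected(self):
        model = build_model(ModelConfig(seed=0), "two_feature")
        with pytest.raises(ValueError, match="expected"):
            predict_proba(model, np.zeros((2, 69, 4)) + 1.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = ModelConfig(lstm_units=4, seed=3, dtype="float64")
        model = ClassifierModel(cfg, "two_feature")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 6, 2))
        X[1, 4:] = 0.0  # trailing padding on one sequence
        Y = np.eye(2)[[0, 1, 0]]
        _, grads, _ = model.loss_and_grads(X, Y)
        eps = 1e-6
        for key, P in model.params.items():
            flat = P.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 10)):
                old = flat[idx]
                flat[idx] = old + eps
                lp, _, _ = model.loss_and_grads(X, Y)
                flat[idx] = old - eps
                lm, _, _ = model.loss_and_grads(X, Y)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(num, abs=1e-7), key


class TestTraining:
    def test_separable_toy_problem_reaches_perfect_accuracy(self):
        # two constant sequences per class, well separated
        X = np.zeros((4, 10, 2))
        X[:2] = 1.0
        X[2:] = -1.0
        Y = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        cfg = ModelConfig(lstm_units=8, epochs=240, batch_size=4, seed=0)
        model = ClassifierModel(cfg, "two_feature")
        history = train(model, X, Y, cfg)
        assert history.accuracy[-1] == 1.0
        assert history.loss[-1] <= history.loss[0]

    def test_training_is_deterministic_for_a_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 12, 2))
        Y = np.eye(2)[rng.integers(0, 2, 16)]
        runs = []
        for _ in range(2):
            cfg = ModelConfig(lstm_units=8, epochs=5, seed=9)
            model = ClassifierModel(cfg, "two_feature")
            runs.append(train(model, X, Y, cfg).loss)
        assert runs[0] == runs[1]

    def test_history_length_matches_epochs(self):
        X = np.ones((4, 5, 2))
        Y = np.eye(2)[[0, 1, 0, 1]]
        cfg = ModelConfig(lstm_units=4, epochs=1, seed=0)
        model = ClassifierModel(cfg, "two_feature")
        history = train(model, X, Y, cfg)
        assert len(history.loss) == len(history.accuracy) == 1

    def test_divergence_is_reported_with_epoch(self):
        X = np.ones((4, 5, 2))
        Y = np.eye(2)[[0, 1, 0, 1]]
        cfg = ModelConfig(lstm_units=4, epochs=3, seed=0, dtype="float64")
        model = ClassifierModel(cfg, "two_feature")
        model.params["Wd"][:] = np.nan  # corrupted weights surface immediately
        with pytest.raises(DivergenceError, match="epoch"):
            train(model, X, Y, cfg)


class TestMasking:
    def test_trailing_padding_does_not_change_predictions(self):
        rng = np.random.default_rng(7)
        model = build_model(ModelConfig(seed=4), "two_feature")
        for _ in range(10):
            n = int(rng.integers(10, 40))
            seq = rng.normal(size=(n, 2))
            padded = np.zeros((69, 2))
            padded[:n] = seq
            p_short = predict_proba(model, seq[None])
            p_padded = predict_proba(model, padded[None])
            np.testing.assert_allclose(p_short, p_padded, atol=1e-6)

    def test_batch_context_does_not_change_predictions(self):
        rng = np.random.default_rng(8)
        model = build_model(ModelConfig(seed=4), "two_feature")
        padded = np.zeros((5, 69, 2))
        for k in range(5):
            n = int(rng.integers(10, 69))
            padded[k, :n] = rng.normal(size=(n, 2))
        alone = np.concatenate([predict_proba(model, padded[k:k + 1])
                                for k in range(5)])
        together = predict_proba(model, padded)
        np.testing.assert_allclose(alone, together, atol=1e-6)


class TestPredictions:
    def test_threshold_is_inclusive_for_asd(self):
        class Stub:
            n_features = 2
            feature_mode = "two_feature"
            cfg = ModelConfig(seed=0)

            def forward(self, X, want_cache=False):
                return np.full((X.shape[0], 2), 0.5), None

        labels = predict_label(Stub(), np.zeros((3, 69, 2)) + 1.0)
        assert labels == ["ASD", "ASD", "ASD"]


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    model = build_model(ModelConfig(lstm_units=6, seed=2), "four_feature")
    X = rng.normal(size=(4, 20, 4))
    before = predict_proba(model, X)
    path = tmp_path / "model.npz"
    save_model(model, path)
    restored = load_model(path)
    assert restored.feature_mode == "four_feature"
    assert restored.cfg.lstm_units == 6
    np.testing.assert_allclose(predict_proba(restored, X), before, atol=1e-12)
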