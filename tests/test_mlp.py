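"""Perceptron initialization, gradient correctness, training behavior."""

import numpy as np
import pytest

from pockethar.errors import ConfigError, DimensionError
from pockethar.mlp_classifier import (
    MLPConfig,
    _backprop,
    init_model,
    predict,
    train,
)
from pockethar.types import ACTIVITIES, Activity

TOY_DIMS = (4, 3, 3, 2)


def _toy_dataset(rng, n_per_class=50, gap=4.0):
    """Two linearly separable clusters in 4-D, labeled walking/running."""
    data = []
    for label, sign in ((Activity.WALKING, -1.0), (Activity.RUNNING, 1.0)):
        centers = sign * gap * np.ones(4)
        for _ in range(n_per_class):
            data.append((centers + rng.normal(0, 1.0, size=4), label))
    return data


def test_xavier_bounds_and_zero_biases():
    bound0 = np.sqrt(6.0 / (120 + 18))
    for seed in range(200):
        model = init_model(MLPConfig(seed=seed))
        assert np.all(np.abs(model.weights[0]) <= bound0)
        assert np.all(np.abs(model.weights[1]) <= np.sqrt(6.0 / 27))
        assert np.all(np.abs(model.weights[2]) <= np.sqrt(6.0 / 15))
        assert all(np.all(b == 0) for b in model.biases)


def test_init_deterministic_per_seed():
    a = init_model(MLPConfig(seed=3))
    b = init_model(MLPConfig(seed=3))
    c = init_model(MLPConfig(seed=4))
    for w1, w2 in zip(a.weights, b.weights):
        np.testing.assert_array_equal(w1, w2)
    assert any(np.any(w1 != w3) for w1, w3 in zip(a.weights, c.weights))


def test_zero_epochs_leaves_weights_at_init():
    rng = np.random.default_rng(0)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=0, seed=1)
    model = init_model(config)
    trained = train(model, _toy_dataset(rng), config)
    for w1, w2 in zip(model.weights, trained.weights):
        np.testing.assert_array_equal(w1, w2)


def test_backprop_matches_central_differences():
    """Analytic gradients agree with numeric ones on a small random net."""
    rng = np.random.default_rng(12)
    config = MLPConfig(layer_dims=TOY_DIMS, seed=12)
    model = init_model(config)
    x = rng.normal(size=4)
    target = np.array([1.0, -1.0])
    _, gw, gb = _backprop(model, x, target)
    eps = 1e-6

    def loss_at():
        loss, _, _ = _backprop(model, x, target)
        return loss

    for layer in range(3):
        w = model.weights[layer]
        for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1), (0, w.shape[1] // 2)]:
            orig = w[idx]
            w[idx] = orig + eps
            up = loss_at()
            w[idx] = orig - eps
            down = loss_at()
            w[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert gw[layer][idx] == pytest.approx(numeric, rel=1e-5, abs=1e-10)
        b = model.biases[layer]
        orig = b[0]
        b[0] = orig + eps
        up = loss_at()
        b[0] = orig - eps
        down = loss_at()
        b[0] = orig
        assert gb[layer][0] == pytest.approx((up - down) / (2 * eps), rel=1e-5, abs=1e-10)


def test_separable_classes_reach_perfect_training_accuracy():
    rng = np.random.default_rng(5)
    dataset = _toy_dataset(rng)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=30, seed=2)
    model = train(init_model(config), dataset, config)
    losses = model.training_loss
    assert all(b < a for a, b in zip(losses[:10], losses[1:11]))
    correct = sum(
        predict(model, vec).predicted is label for vec, label in dataset
    )
    assert correct == len(dataset)


def test_loss_non_increasing_at_small_learning_rate():
    rng = np.random.default_rng(8)
    dataset = _toy_dataset(rng, n_per_class=20, gap=2.0)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=40, seed=3, learning_rate=0.01)
    model = train(init_model(config), dataset, config)
    diffs = np.diff(model.training_loss)
    assert np.all(diffs <= 1e-6)


def test_training_reproducible_under_seed():
    rng = np.random.default_rng(1)
    dataset = _toy_dataset(rng)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=10, seed=6)
    m1 = train(init_model(config), dataset, config)
    m2 = train(init_model(config), dataset, config)
    for w1, w2 in zip(m1.weights, m2.weights):
        np.testing.assert_array_equal(w1, w2)
    assert m1.training_loss == m2.training_loss


def test_probabilities_sum_to_one_and_match_argmax():
    model = init_model(MLPConfig(seed=0))
    rng = np.random.default_rng(0)
    for _ in range(20):
        scores = predict(model, rng.normal(size=120))
        assert scores.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((scores.raw > -1) & (scores.raw < 1))
        assert scores.predicted is ACTIVITIES[int(np.argmax(scores.raw))]
        assert int(np.argmax(scores.raw)) == int(np.argmax(scores.probabilities))


def test_label_permutation_permutes_scores():
    """Relabeling the output units permutes raw scores identically."""
    rng = np.random.default_rng(4)
    dataset = _toy_dataset(rng)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=5, seed=11)
    base = init_model(config)
    m1 = train(base, dataset, config)

    perm_labels = (Activity.RUNNING, Activity.WALKING)
    base2 = init_model(config)
    base2.labels = perm_labels
    # permute the output layer of the init so unit k still serves label k
    base2.weights[-1] = base.weights[-1][::-1].copy()
    base2.biases[-1] = base.biases[-1][::-1].copy()
    m2 = train(base2, dataset, config)
    for vec, _ in dataset[:5]:
        np.testing.assert_allclose(
            predict(m2, vec).raw, predict(m1, vec).raw[::-1], atol=1e-12
        )
        assert predict(m2, vec).predicted is predict(m1, vec).predicted


def test_dimension_and_label_validation():
    config = MLPConfig(layer_dims=TOY_DIMS)
    model = init_model(config)
    with pytest.raises(DimensionError):
        predict(model, np.zeros(5))
    with pytest.raises(DimensionError):
        train(model, [(np.zeros(3), Activity.WALKING)], config)
    with pytest.raises(DimensionError):
        train(model, [], config)
    with pytest.raises(ConfigError):
        MLPConfig(learning_rate=0.0)


def test_normalization_statistics_fitted_on_training_set():
    rng = np.random.default_rng(9)
    dataset = _toy_dataset(rng)
    config = MLPConfig(layer_dims=TOY_DIMS, epochs=1, seed=0)
    model = train(init_model(config), dataset, config)
    X = np.array([v for v, _ in dataset])
    np.testing.assert_allclose(model.norm_mean, X.mean(axis=0))
    np.testing.assert_allclose(model.norm_scale, X.std(axis=0))
    config_off = MLPConfig(layer_dims=TOY_DIMS, epochs=1, seed=0,
                           normalize_features=False)
    raw = train(init_model(config_off), dataset, config_off)
    np.testing.assert_array_equal(raw.norm_mean, np.zeros(4))
    np.testing.assert_array_equal(raw.norm_scale, np.ones(4))


def test_matches_independent_reference_classifier():
    """Our online-SGD perceptron lands within a few points of an
    independently trained scikit-learn MLP on identical features."""
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler

    from pockethar.evaluation import evaluate
    from pockethar.features import extract_features
    from pockethar.synthetic_data import generate_dataset
    from pockethar.windowing import segment

    train_windows = [w for r in generate_dataset(30, seed=101) for w in segment(r)]
    test_windows = [w for r in generate_dataset(15, seed=202) for w in segment(r)]
    rows = [(extract_features(w).values, w.label) for w in train_windows]

    config = MLPConfig(seed=7)
    ours = train(init_model(config), rows, config)
    _, report = evaluate(ours, test_windows)

    X = np.array([vec for vec, _ in rows])
    y = [lab.value for _, lab in rows]
    scaler = StandardScaler().fit(X)
    reference = MLPClassifier(
        hidden_layer_sizes=(18, 9), max_iter=2000, random_state=0
    ).fit(scaler.transform(X), y)
    Xte = np.array([extract_features(w).values for w in test_windows])
    yte = [w.label.value for w in test_windows]
    ref_acc = reference.score(scaler.transform(Xte), yte)

    assert abs(report.average - ref_acc) <= 0.10
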