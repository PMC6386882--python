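"""Three-layer perceptron trained with online backpropagation.

The network is deliberately small — 120 inputs, two tanh hidden layers
of 18 and 9 units, and 6 tanh outputs, one per activity — so it can run
comfortably on a phone-class device. Training is classic delta-rule
stochastic gradient descent: samples are presented one at a time, the
squared error between the tanh outputs and a +/-1 one-hot target (+1
for the true activity, -1 elsewhere) is backpropagated, and every weight
moves by ``-learning_rate * gradient``. Weights start from
Xavier/Glorot-uniform draws, biases at zero.

Because tanh saturates on raw accelerometer magnitudes (~10 m/s^2),
features are z-scored with statistics fitted on the training set and
stored in the model; ``normalize_features=False`` disables this.
Class scores are reported both raw (tanh outputs in (-1, 1)) and as a
softmax over the raw outputs, which yields a proper probability vector
without changing the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from pockethar.errors import ConfigError, DimensionError
from pockethar.types import ACTIVITIES, Activity

DEFAULT_LAYER_DIMS = (120, 18, 9, 6)


@dataclass(frozen=True)
class MLPConfig:
    layer_dims: tuple[int, ...] = DEFAULT_LAYER_DIMS
    learning_rate: float = 0.1
    epochs: int = 100
    seed: int = 0
    normalize_features: bool = True

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 2 or any(d < 1 for d in self.layer_dims):
            raise ConfigError(f"invalid layer dims {self.layer_dims}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be nonnegative")


@dataclass
class MLPModel:
    config: MLPConfig
    weights: list[np.ndarray]  # weights[l] has shape (dims[l+1], dims[l])
    biases: list[np.ndarray]
    norm_mean: np.ndarray
    norm_scale: np.ndarray
    labels: tuple[Activity, ...] = ACTIVITIES
    training_loss: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = self.config.layer_dims
        if len(self.labels) != dims[-1]:
            raise ConfigError(
                f"{len(self.labels)} labels for {dims[-1]} output units"
            )
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[i + 1], dims[i]) or b.shape != (dims[i + 1],):
                raise DimensionError(
                    f"layer {i} parameter shapes {w.shape}/{b.shape} do not "
                    f"match dims {dims}"
                )
        if np.any(self.norm_scale <= 0):
            raise ConfigError("normalization scale must be positive")


@dataclass
class ClassScores:
    """Raw tanh outputs, softmax probabilities, and the argmax label."""

    raw: np.ndarray
    probabilities: np.ndarray
    predicted: Activity
    labels: tuple[Activity, ...] = ACTIVITIES


def init_model(config: MLPConfig = MLPConfig()) -> MLPModel:
    """Xavier-uniform weights (bound sqrt(6/(fan_in+fan_out))), zero biases."""
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    dims = config.layer_dims
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    if dims[-1] > len(ACTIVITIES):
        raise ConfigError(
            f"output layer of {dims[-1]} units exceeds the "
            f"{len(ACTIVITIES)}-activity label set"
        )
    return MLPModel(
        config=config,
        weights=weights,
        biases=biases,
        norm_mean=np.zeros(dims[0]),
        norm_scale=np.ones(dims[0]),
        labels=ACTIVITIES[: dims[-1]],
    )


def _forward(model: MLPModel, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer, input included; tanh at every layer."""
    acts = [x]
    for w, b in zip(model.weights, model.biases):
        acts.append(np.tanh(w @ acts[-1] + b))
    return acts


def _target_matrix(labels: tuple[Activity, ...], n_out: int) -> dict[Activity, np.ndarray]:
    targets = {}
    for i, lab in enumerate(labels):
        t = -np.ones(n_out)
        t[i] = 1.0
        targets[lab] = t
    return targets


def _backprop(
    model: MLPModel, x: np.ndarray, target: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Per-sample mean-squared-error loss and its exact gradients.

    The cost is E = (1/(2*n_out)) * sum((out - target)^2): squared error
    averaged over the output units, halved so the delta-rule error
    signal keeps its clean (out - target) form.
    """
    acts = _forward(model, x)
    err = acts[-1] - target
    n_out = err.shape[0]
    loss = 0.5 * float(err @ err) / n_out
    delta = (err / n_out) * (1.0 - acts[-1] ** 2)  # tanh' = 1 - tanh^2
    grads_w: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore
    for layer in range(len(model.weights) - 1, -1, -1):
        grads_w[layer] = np.outer(delta, acts[layer])
        grads_b[layer] = delta
        if layer > 0:
            delta = (model.weights[layer].T @ delta) * (1.0 - acts[layer] ** 2)
    return loss, grads_w, grads_b


def train(
    model: MLPModel,
    dataset: Sequence[tuple[np.ndarray, Activity]],
    config: MLPConfig | None = None,
) -> MLPModel:
    """Online gradient-descent training; returns a new trained model.

    Runs ``epochs`` full passes over the dataset, presenting samples one
    at a time in a per-epoch shuffled order (seeded from the model seed)
    and applying ``w -= learning_rate * grad`` after each sample. The
    z-score normalization is fitted on the dataset before the first
    epoch; per-epoch mean loss is logged in ``training_loss``.
    """
    if config is None:
        config = model.config
    if not dataset:
        raise DimensionError("training dataset is empty")
    n_in = config.layer_dims[0]
    X = np.empty((len(dataset), n_in))
    targets = _target_matrix(model.labels, config.layer_dims[-1])
    T = np.empty((len(dataset), config.layer_dims[-1]))
    for i, (vec, label) in enumerate(dataset):
        values = np.asarray(getattr(vec, "values", vec), dtype=np.float64)
        if values.shape != (n_in,):
            raise DimensionError(
                f"sample {i}: expected {n_in} features, got shape {values.shape}"
            )
        if label not in targets:
            raise ConfigError(f"sample {i}: label '{label}' not in model labels")
        X[i] = values
        T[i] = targets[label]

    if config.normalize_features:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant features pass through centered
    else:
        mean = np.zeros(n_in)
        scale = np.ones(n_in)
    Xn = (X - mean) / scale

    out = MLPModel(
        config=config,
        weights=[w.copy() for w in model.weights],
        biases=[b.copy() for b in model.biases],
        norm_mean=mean,
        norm_scale=scale,
        labels=model.labels,
        training_loss=list(model.training_loss),
    )
    lr = config.learning_rate
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    for _ in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for i in order:
            loss, gw, gb = _backprop(out, Xn[i], T[i])
            epoch_loss += loss
            for layer in range(len(out.weights)):
                out.weights[layer] -= lr * gw[layer]
                out.biases[layer] -= lr * gb[layer]
        out.training_loss.append(epoch_loss / len(dataset))
    return out


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def predict(model: MLPModel, features: np.ndarray) -> ClassScores:
    """Forward pass for one feature vector.

    Applies the stored normalization, returns raw tanh scores, softmax
    probabilities, and the argmax label (ties break toward the earliest
    label in canonical activity order, which is what argmax does).
    """
    values = np.asarray(getattr(features, "values", features), dtype=np.float64)
    n_in = model.config.layer_dims[0]
    if values.shape != (n_in,):
        raise DimensionError(
            f"expected {n_in} features, got shape {values.shape}"
        )
    x = (values - model.norm_mean) / model.norm_scale
    raw = _forward(model, x)[-1]
    probs = _softmax(raw)
    return ClassScores(
        raw=raw,
        probabilities=probs,
        predicted=model.labels[int(np.argmax(raw))],
        labels=model.labels,
    )
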