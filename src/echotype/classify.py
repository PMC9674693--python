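"""Dilated CNN classifiers (1D for waveform/spectrum, 2D for spectrogram)
and the classical baselines (linear SVM, logistic regression, MLP).

The CNNs are shallow VGG-style stacks: seven dilated convolutions with
kernel 3 (3x3 in 2D), batch normalization after every convolution, dropout
after every activation, four max-poolings, then three fully connected
layers ending in a sigmoid unit trained with binary cross-entropy.  L2
regularization is applied to both weights and biases; all parameters use
Xavier-normal initialization.  Baselines consume the same (flattened)
features the CNNs see, so comparisons isolate the model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import nn


@dataclass
class Conv1DClassifierSpec:
    filters: tuple = (16, 16, 32, 32, 64, 64, 128)
    dilations: tuple = (1, 1, 2, 2, 4, 4, 8)
    kernel: int = 3
    fc_widths: tuple = (256, 64)
    dropout_rate: float = 0.2
    pool_size: int = 2
    l2: float = 1e-4

    def __post_init__(self):
        if len(self.filters) != 7 or len(self.dilations) != 7:
            raise ValueError("the classifier takes 7 conv layers")
        if len(self.fc_widths) != 2:
            raise ValueError("two hidden FC layers plus the sigmoid output")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class Conv2DClassifierSpec(Conv1DClassifierSpec):
    pool_size: tuple = (2, 2)


@dataclass
class BaselineSpec:
    family: str  # "svm" | "logit" | "mlp"
    svm_kernel: str = "linear"
    mlp_hidden: tuple = (100,) * 5
    mlp_epochs: int = 100
    mlp_batch_size: int = 12
    mlp_learning_rate: float = 0.001

    def __post_init__(self):
        if self.family not in ("svm", "logit", "mlp"):
            raise ValueError(f"unknown baseline family: {self.family!r}")


@dataclass
class ClassifierTrainSpec:
    epochs: int = 50
    learning_rate: float = 0.001
    batch_size: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class Prediction:
    score: float  # sigmoid output in [0, 1]
    label: int  # 1 iff score >= threshold


@dataclass
class TrainedClassifier:
    kind: str  # "cnn1d" | "cnn2d" | baseline family
    input_shape: tuple
    net: "nn.Sequential | None" = None
    sk_model: object = None
    training_history: list[float] = field(default_factory=list)

    def scores(self, features: np.ndarray) -> np.ndarray:
        x = _check_features(features, self.input_shape)
        if self.net is not None:
            return self.net.forward(x[..., None], train=False)[:, 0]
        flat = x.reshape(x.shape[0], -1)
        if hasattr(self.sk_model, "predict_proba"):
            return self.sk_model.predict_proba(flat)[:, 1]
        margin = self.sk_model.decision_function(flat)
        return 1.0 / (1.0 + np.exp(-margin))


def _check_features(features, expected_shape) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == len(expected_shape):  # single example
        x = x[None]
    if x.shape[1:] != tuple(expected_shape):
        raise ValueError(f"feature shape {x.shape[1:]} does not match trained shape {expected_shape}")
    return x


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if len(uniq) < 2:
        raise ValueError("training data contains a single class")
    return y.astype(float)


def _conv_stack(spec, conv_cls, pool_cls, pool_after=(1, 3, 5, 6)):
    layers = []
    for i in range(7):
        layers += [
            conv_cls(spec.filters[i], spec.kernel, spec.dilations[i], bias_init="xavier"),
            nn.BatchNorm(),
            nn.ReLU(),
            nn.Dropout(spec.dropout_rate),
        ]
        if i in pool_after:
            layers.append(pool_cls(spec.pool_size))
    layers.append(nn.Flatten())
    for width in spec.fc_widths:
        layers += [nn.Dense(width, bias_init="xavier"), nn.ReLU()]
    layers += [nn.Dense(1, bias_init="xavier"), nn.Sigmoid()]
    return layers


def build_1d_classifier(spec: Conv1DClassifierSpec, input_length: int, seed: int = 0) -> "nn.Sequential":
    layers = _conv_stack(spec, nn.Conv1D, nn.MaxPool1D)
    return nn.Sequential(layers, input_shape=(input_length, 1), seed=seed, dtype=np.float32)


def build_2d_classifier(spec: Conv2DClassifierSpec, input_shape: tuple, seed: int = 0) -> "nn.Sequential":
    layers = _conv_stack(spec, nn.Conv2D, nn.MaxPool2D)
    return nn.Sequential(layers, input_shape=(*input_shape, 1), seed=seed, dtype=np.float32)


def _fit_cnn(net, x, y, spec, tspec):
    return nn.fit(
        net,
        x,
        y[:, None],
        loss="bce",
        epochs=tspec.epochs,
        lr=tspec.learning_rate,
        batch_size=tspec.batch_size,
        seed=tspec.seed,
        l2=spec.l2,
    )


def train_1d_classifier(
    features, labels, spec: Conv1DClassifierSpec | None = None, tspec: ClassifierTrainSpec | None = None
) -> TrainedClassifier:
    spec = spec or Conv1DClassifierSpec()
    tspec = tspec or ClassifierTrainSpec()
    x = np.stack([np.asarray(f, dtype=float) for f in features])
    if x.ndim != 2:
        raise ValueError("1D classifier expects equal-length feature vectors")
    y = _check_labels(labels)
    net = build_1d_classifier(spec, x.shape[1], seed=tspec.seed)
    history = _fit_cnn(net, x[..., None], y, spec, tspec)
    return TrainedClassifier("cnn1d", (x.shape[1],), net=net, training_history=history)


def train_2d_classifier(
    spectrograms, labels, spec: Conv2DClassifierSpec | None = None, tspec: ClassifierTrainSpec | None = None
) -> TrainedClassifier:
    spec = spec or Conv2DClassifierSpec()
    tspec = tspec or ClassifierTrainSpec()
    shapes = {np.asarray(s).shape for s in spectrograms}
    if len(shapes) != 1 or len(next(iter(shapes))) != 2:
        raise ValueError(f"2D classifier expects equal-shape matrices, got shapes {sorted(shapes)}")
    x = np.stack([np.asarray(s, dtype=float) for s in spectrograms])
    y = _check_labels(labels)
    net = build_2d_classifier(spec, x.shape[1:], seed=tspec.seed)
    history = _fit_cnn(net, x[..., None], y, spec, tspec)
    return TrainedClassifier("cnn2d", x.shape[1:], net=net, training_history=history)


def train_baseline(features, labels, spec: BaselineSpec, seed: int = 0) -> TrainedClassifier:
    x = np.stack([np.asarray(f, dtype=float) for f in features])
    flat = x.reshape(x.shape[0], -1)
    y = _check_labels(labels).astype(int)
    if spec.family == "svm":
        model = SVC(kernel=spec.svm_kernel, random_state=seed)
    elif spec.family == "logit":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    else:
        model = MLPClassifier(
            hidden_layer_sizes=spec.mlp_hidden,
            activation="relu",
            solver="adam",
            learning_rate_init=spec.mlp_learning_rate,
            batch_size=spec.mlp_batch_size,
            max_iter=spec.mlp_epochs,
            random_state=seed,
        )
    model.fit(flat, y)
    return TrainedClassifier(spec.family, x.shape[1:], sk_model=model)


def predict_labels(model: TrainedClassifier, features, threshold: float = 0.5) -> list[Prediction]:
    """Threshold sigmoid scores; a score exactly at threshold goes positive."""
    scores = model.scores(features)
    return [Prediction(score=float(s), label=int(s >= threshold)) for s in scores]
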