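"""Base 5-class CNN: declarative architecture, builder, and training loop.

Architecture (input 112x112x1):

    conv 3x3x32 (x3, ReLU, same) -> maxpool 2x2 -> dropout 0.25
    conv 3x3x64 -> avgpool 2x2 -> dropout 0.5
    conv 3x3x128 -> avgpool 2x2 -> dropout 0.75
    flatten (25088) -> dense 200 (ReLU) -> dropout 0.5 -> dense k softmax

which yields 5,129,973 trainable parameters for k=5. Spatial sizes follow
112 -> 56 -> 28 -> 14 under the three 2x2 poolings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, DivergenceError, InvalidInputError

INPUT_SIZE = (112, 112, 1)
FEATURE_LAYER = "fc200"  # penultimate dense layer used for deep features
N_DEEP_FEATURES = 200


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 256
    epochs: int = 50
    loss: str = "categorical"  # or "binary" (sigmoid single-unit head)
    seed: int = 0
    shuffle: bool = True
    chunk_size: int = 16  # compute micro-batch; gradients still span batch_size

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.loss not in ("categorical", "binary"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")


def build_base_cnn(n_classes: int = 5, seed: int = 0) -> nn.Sequential:
    """Instantiate the base CNN with Glorot-uniform init from ``seed``."""
    if n_classes < 2:
        raise ConfigurationError("n_classes must be >= 2")
    flat_dim = 14 * 14 * 128  # 25088 after three 2x2 poolings of 112
    layers = [
        nn.Conv2D(1, 32, name="conv1"),
        nn.Conv2D(32, 32, name="conv2"),
        nn.Conv2D(32, 32, name="conv3"),
        nn.MaxPool2D("pool1"),
        nn.Dropout(0.25, name="drop1"),
        nn.Conv2D(32, 64, name="conv4"),
        nn.AvgPool2D("pool2"),
        nn.Dropout(0.5, name="drop2"),
        nn.Conv2D(64, 128, name="conv5"),
        nn.AvgPool2D("pool3"),
        nn.Dropout(0.75, name="drop3"),
        nn.Flatten("flatten"),
        nn.Dense(flat_dim, N_DEEP_FEATURES, activation="relu", name=FEATURE_LAYER),
        nn.Dropout(0.5, name="drop4"),
        nn.Dense(N_DEEP_FEATURES, n_classes, activation="softmax", name="output"),
    ]
    return nn.Sequential(layers, seed=seed)

#: Names of the convolutional backbone layers (everything before flatten).
CONV_BACKBONE = ("conv1", "conv2", "conv3", "pool1", "drop1", "conv4", "pool2",
                 "drop2", "conv5", "pool3", "drop3")


def count_parameters(model: nn.Sequential, only_trainable: bool = False) -> int:
    """Sum of weight + bias element counts over the model's layers."""
    return model.count_parameters(only_trainable=only_trainable)


def layer_output_shapes(model: nn.Sequential, input_size=INPUT_SIZE) -> dict[str, tuple]:
    """Map layer name -> output shape (batch axis dropped) via a probe forward."""
    x = np.zeros((1,) + tuple(input_size), dtype=np.float32)
    shapes = {}
    for layer in model.layers:
        x = layer.forward(x, train=False, rng=np.random.default_rng(0))
        shapes[layer.name] = x.shape[1:]
    return shapes


def predict_proba(model: nn.Sequential, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Inference-mode class probabilities (dropout inactive), chunked."""
    x = np.asarray(x, dtype=np.float32)
    return np.concatenate(
        [model.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
    )


def predict_classes(model: nn.Sequential, x: np.ndarray) -> np.ndarray:
    probs = predict_proba(model, x)
    if probs.shape[1] == 1:  # sigmoid binary head
        return (probs[:, 0] >= 0.5).astype(int)
    return probs.argmax(axis=1)


def _targets(labels: np.ndarray, loss: str, n_out: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if loss == "binary":
        if labels.min() < 0 or labels.max() > 1:
            raise InvalidInputError("binary loss requires labels in {0, 1}")
        return labels.reshape(-1, 1).astype(np.float32)
    if labels.min() < 0 or labels.max() >= n_out:
        raise InvalidInputError(f"labels out of range for {n_out}-way softmax")
    onehot = np.zeros((len(labels), n_out), dtype=np.float32)
    onehot[np.arange(len(labels)), labels] = 1.0
    return onehot


def _loss_value(probs, targets, loss):
    if loss == "binary":
        return nn.binary_cross_entropy(probs, targets)
    return nn.categorical_cross_entropy(probs, targets)


def _accuracy(probs, labels, loss):
    if loss == "binary":
        pred = (probs[:, 0] >= 0.5).astype(int)
    else:
        pred = probs.argmax(axis=1)
    return float((pred == np.asarray(labels)).mean())


def evaluate_loss(model, x, y, loss="categorical", chunk=64):
    probs = predict_proba(model, x, chunk=chunk)
    targets = _targets(y, loss, probs.shape[1])
    return _loss_value(probs, targets, loss), _accuracy(probs, y, loss)


def train(
    model: nn.Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    x_valid: np.ndarray | None = None,
    y_valid: np.ndarray | None = None,
) -> dict[str, list[float]]:
    """Mini-batch Adam training; returns per-epoch loss/accuracy history.

    Large mini-batches are processed in ``chunk_size`` micro-batches whose
    gradients are accumulated before each optimizer step, so the configured
    batch size is honored without holding all activations at once.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=int)
    if x_train.ndim not in (2, 4):
        raise InvalidInputError(
            f"expected NHWC images or (n, d) features, got shape {x_train.shape}"
        )
    if len(x_train) != len(y_train):
        raise InvalidInputError("images and labels disagree in length")

    n_out = model.layers[-1].units
    targets = _targets(y_train, config.loss, n_out)
    optimizer = nn.Adam(
        model, lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2
    )
    rng = np.random.default_rng(config.seed)
    history: dict[str, list[float]] = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}

    n = len(x_train)
    for _epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            m = len(batch)
            model.zero_grads()
            for cstart in range(0, m, config.chunk_size):
                idx = batch[cstart:cstart + config.chunk_size]
                probs = model.forward(x_train[idx], train=True)
                t = targets[idx]
                chunk_loss = _loss_value(probs, t, config.loss)
                if not np.isfinite(chunk_loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {_epoch}; try a lower "
                        f"learning rate or check input scaling"
                    )
                loss_sum += chunk_loss * len(idx)
                correct += int(round(_accuracy(probs, y_train[idx], config.loss) * len(idx)))
                model.backward_from_logits((probs - t) / m)
            optimizer.step()
        history["loss"].append(loss_sum / n)
        history["acc"].append(correct / n)
        if x_valid is not None and len(x_valid):
            vl, va = evaluate_loss(model, x_valid, y_valid, loss=config.loss)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
    return history


def write_history_csv(history: dict[str, list[float]], path: str | Path) -> None:
    keys = [k for k in ("loss", "val_loss", "acc", "val_acc") if history.get(k)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch"] + keys)
        for i in range(len(history["loss"])):
            writer.writerow([i] + [history[k][i] for k in keys])
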