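"""Transfer-learning variants: frozen conv backbone + new 512/256/k head.

The trained base CNN's convolutional blocks are frozen and reused; the
original dense head is replaced by three new fully connected layers
(512 with dropout 0.5, then 256, then the k-way output - softmax for k > 2,
a single sigmoid unit for k = 2). Only the new head is trained, for the
coarse 4/3/2-class grade groupings. The fine-tuned network then feeds the
same MinMax -> PCA -> SVM hybrid head, reading 256-dim features from its
penultimate dense layer.

Because the backbone is frozen, its outputs are computed once per dataset
(inference mode, dropout inactive) and the head is trained on those cached
activations; this is mathematically identical to training the composite
network with frozen weights and inference-mode backbone dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cnn, dhl, nn
from .errors import ConfigurationError
from .preprocess import GroupingScheme, map_grades

TL_FEATURE_LAYER = "fc256"
TL_SCHEMES = ("FOUR", "THREE", "TWO")


@dataclass(frozen=True)
class FineTuneSpec:
    scheme: str = "FOUR"
    epochs: int = 20
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.scheme.upper() not in TL_SCHEMES:
            raise ConfigurationError(
                f"transfer learning supports schemes {TL_SCHEMES}, got {self.scheme!r}"
            )


def _head_layers(n_classes: int) -> list[nn.Layer]:
    flat_dim = 14 * 14 * 128
    if n_classes == 2:
        out = nn.Dense(256, 1, activation="sigmoid", name="output")
    else:
        out = nn.Dense(256, n_classes, activation="softmax", name="output")
    return [
        nn.Dense(flat_dim, 512, activation="relu", name="fc512"),
        nn.Dropout(0.5, name="drop_fc512"),
        nn.Dense(512, 256, activation="relu", name=TL_FEATURE_LAYER),
        out,
    ]


def build_tl_model(base_model: nn.Sequential, n_classes: int, seed: int = 0) -> nn.Sequential:
    """Frozen copy of the conv backbone plus a freshly initialized 512/256/k head."""
    if n_classes < 2:
        raise ConfigurationError("n_classes must be >= 2")
    backbone = [
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
    ]
    model = nn.Sequential(backbone + _head_layers(n_classes), seed=seed)
    for name in cnn.CONV_BACKBONE:
        layer = model[name]
        for i, p in enumerate(base_model[name].params):
            layer.params[i][...] = p
        layer.trainable = False
    return model


@dataclass
class FineTuneResult:
    model: nn.Sequential
    history: dict[str, list[float]]
    scheme: GroupingScheme


def fine_tune(
    base_model: nn.Sequential,
    x_train: np.ndarray,
    grouped_labels: np.ndarray,
    spec: FineTuneSpec,
    x_valid: np.ndarray | None = None,
    grouped_valid: np.ndarray | None = None,
) -> FineTuneResult:
    """Train the new head on cached backbone activations; backbone untouched.

    ``grouped_labels`` must already be mapped through the spec's scheme.
    """
    scheme = GroupingScheme.by_name(spec.scheme)
    grouped_labels = np.asarray(grouped_labels, dtype=int)
    if grouped_labels.size and grouped_labels.max() >= scheme.n_classes:
        raise ConfigurationError(
            f"labels exceed scheme {scheme.name} range ({scheme.n_classes} classes)"
        )
    model = build_tl_model(base_model, scheme.n_classes, seed=spec.seed)

    feats_train = dhl.extract_features(base_model, x_train, layer="flatten")
    feats_valid = None
    if x_valid is not None and len(x_valid):
        feats_valid = dhl.extract_features(base_model, x_valid, layer="flatten")

    head = nn.Sequential(_head_layers(scheme.n_classes), seed=spec.seed)
    # start the head from the composite model's init so weights stay in sync
    head.set_weights({k: v for k, v in model.get_weights().items() if _is_head(k)})

    config = cnn.TrainConfig(
        learning_rate=spec.learning_rate,
        beta1=spec.beta1,
        beta2=spec.beta2,
        batch_size=spec.batch_size,
        epochs=spec.epochs,
        loss="binary" if scheme.n_classes == 2 else "categorical",
        seed=spec.seed,
        chunk_size=256,
    )
    history = cnn.train(head, feats_train, grouped_labels, config,
                        x_valid=feats_valid, y_valid=grouped_valid)
    model.set_weights({**model.get_weights(), **head.get_weights()})
    return FineTuneResult(model=model, history=history, scheme=scheme)


def _is_head(key: str) -> bool:
    return key.split("/")[0] in ("fc512", "drop_fc512", TL_FEATURE_LAYER, "output")


def extract_tl_features(model: nn.Sequential, images: np.ndarray) -> np.ndarray:
    """256-dim penultimate-layer activations of a fine-tuned model."""
    return dhl.extract_features(model, images, layer=TL_FEATURE_LAYER)


def run_dhl2(
    base_model: nn.Sequential,
    x_train: np.ndarray,
    grades_train: np.ndarray,
    x_test: np.ndarray,
    grades_test: np.ndarray,
    scheme: str | GroupingScheme,
    spec: FineTuneSpec | None = None,
    x_valid: np.ndarray | None = None,
    grades_valid: np.ndarray | None = None,
    variance_target: float = 0.99,
    svm_params: dhl.SVMParams = dhl.SVMParams(),
) -> tuple[dhl.DHLResult, FineTuneResult]:
    """Group labels -> fine-tune -> extract 256-dim features -> hybrid head."""
    if isinstance(scheme, GroupingScheme):
        scheme_name = scheme.name
    else:
        scheme_name = scheme.upper()
    if spec is None:
        spec = FineTuneSpec(scheme=scheme_name)
    elif spec.scheme.upper() != scheme_name:
        raise ConfigurationError("spec.scheme disagrees with requested scheme")

    y_train = map_grades(grades_train, scheme_name)
    y_test = map_grades(grades_test, scheme_name)
    y_valid = map_grades(grades_valid, scheme_name) if grades_valid is not None else None

    ft = fine_tune(base_model, x_train, y_train, spec,
                   x_valid=x_valid, grouped_valid=y_valid)
    result = dhl.run_dhl(
        ft.model,
        x_train,
        y_train,
        x_test,
        y_test,
        variance_target=variance_target,
        svm_params=svm_params,
        feature_layer=TL_FEATURE_LAYER,
    )
    return result, ft
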