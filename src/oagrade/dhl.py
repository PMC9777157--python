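"""Hybrid classification head: deep features -> MinMax -> PCA(0.99) -> RBF-SVM.

Deep features are the inference-mode activations of the penultimate dense
layer (200-dim for the base CNN, 256-dim for the fine-tuned variants). The
scaler and PCA are fitted on the training partition only; test features may
legitimately fall outside [0, 1] after scaling.

PCA here is a covariance eigendecomposition (not an SVD wrapper) because the
component-selection rule - the minimal count whose cumulative explained
variance reaches the target - is part of the method's contract and is
verified against a dense eigensolver oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.svm import SVC

from . import cnn, metrics, nn
from .errors import ConfigurationError, InvalidInputError, StageError


def extract_features(
    model: nn.Sequential,
    images: np.ndarray,
    layer: str = cnn.FEATURE_LAYER,
    chunk: int = 64,
) -> np.ndarray:
    """Inference-mode activations of ``layer`` for each image; (n, d) float32."""
    images = np.asarray(images, dtype=np.float32)
    return np.concatenate(
        [model.forward(images[i:i + chunk], stop_at=layer) for i in range(0, len(images), chunk)]
    )


@dataclass
class ScalerParams:
    """Per-feature min/max fitted on the training partition."""

    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self):
        if np.any(self.max_ < self.min_):
            raise InvalidInputError("scaler max must be >= min elementwise")


def fit_minmax(train_features: np.ndarray) -> ScalerParams:
    x = np.asarray(train_features, dtype=np.float64)
    if x.ndim != 2 or len(x) == 0:
        raise InvalidInputError("expected a non-empty (n, d) feature matrix")
    return ScalerParams(min_=x.min(axis=0), max_=x.max(axis=0))


def minmax_transform(features: np.ndarray, params: ScalerParams) -> np.ndarray:
    """(x - min) / (max - min); constant features map to 0."""
    x = np.asarray(features, dtype=np.float64)
    span = params.max_ - params.min_
    safe = np.where(span > 0, span, 1.0)
    out = (x - params.min_) / safe
    out[:, span == 0] = 0.0
    return out


@dataclass
class PCAModel:
    """Covariance-eigendecomposition PCA with variance-target selection."""

    mean_: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray          # descending, clipped at 0
    components: np.ndarray           # (d, d); column j = j-th eigenvector
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float = 0.99


def fit_pca(train_features: np.ndarray, variance_target: float = 0.99) -> PCAModel:
    if not 0.0 < variance_target <= 1.0:
        raise ConfigurationError("variance_target must lie in (0, 1]")
    x = np.asarray(train_features, dtype=np.float64)
    if x.ndim != 2 or len(x) < 2:
        raise InvalidInputError("PCA needs at least 2 samples")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    cumulative = np.cumsum(ratio)
    if total > 0:
        n_comp = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
        n_comp = min(n_comp, len(evals))
    else:
        n_comp = 1
    return PCAModel(
        mean_=mean,
        covariance=cov,
        eigenvalues=evals,
        components=evecs,
        explained_variance_ratio=ratio,
        n_components=n_comp,
        variance_target=variance_target,
    )


def pca_reduce(features: np.ndarray, model: PCAModel) -> np.ndarray:
    x = np.asarray(features, dtype=np.float64)
    return (x - model.mean_) @ model.components[:, : model.n_components]


@dataclass
class SVMParams:
    kernel: str = "rbf"
    C: float = 1000.0
    gamma: float = 0.001

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ConfigurationError("C and gamma must be positive")


def rbf_kernel(xa: np.ndarray, xb: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||xa - xb||^2); equals 1 at zero distance."""
    d = np.asarray(xa, dtype=np.float64) - np.asarray(xb, dtype=np.float64)
    return float(np.exp(-gamma * np.dot(d, d)))


def fit_svm(features: np.ndarray, labels: np.ndarray, params: SVMParams = SVMParams()) -> SVC:
    """RBF-SVM; one-vs-one internally with one-vs-rest decision aggregation."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("SVM training requires at least 2 classes")
    clf = SVC(
        kernel=params.kernel,
        C=params.C,
        gamma=params.gamma,
        decision_function_shape="ovr",
    )
    clf.fit(features, labels)
    return clf


def svm_predict(clf: SVC, features: np.ndarray) -> np.ndarray:
    return clf.predict(features)


def svm_scores(clf: SVC, features: np.ndarray) -> np.ndarray:
    """(n, k) continuous per-class decision scores for ROC construction."""
    d = clf.decision_function(features)
    if d.ndim == 1:  # binary: single margin -> two-column score matrix
        return np.column_stack([-d, d])
    return d


@dataclass
class DHLResult:
    report: metrics.MetricsReport
    n_components: int
    feature_dim: int
    predictions: np.ndarray
    scores: np.ndarray
    scaler: ScalerParams = field(repr=False, default=None)
    pca: PCAModel = field(repr=False, default=None)
    svm: Optional[SVC] = field(repr=False, default=None)
    stage_log: list = field(default_factory=list)


def run_dhl(
    model: nn.Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    variance_target: float = 0.99,
    svm_params: SVMParams = SVMParams(),
    feature_layer: str = cnn.FEATURE_LAYER,
) -> DHLResult:
    """Full hybrid head: extract -> scale -> PCA -> SVM -> evaluate on test."""
    log = []

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, str(exc)) from exc
        return out

    f_train = stage("extract-features", lambda: extract_features(model, x_train, feature_layer))
    f_test = stage("extract-features", lambda: extract_features(model, x_test, feature_layer))
    log.append(("extract-features", f_train.shape, f_test.shape))

    scaler = stage("minmax", lambda: fit_minmax(f_train))
    s_train = minmax_transform(f_train, scaler)
    s_test = minmax_transform(f_test, scaler)
    log.append(("minmax", s_train.shape, s_test.shape))

    pca = stage("pca", lambda: fit_pca(s_train, variance_target))
    r_train = pca_reduce(s_train, pca)
    r_test = pca_reduce(s_test, pca)
    log.append(("pca", r_train.shape, r_test.shape))

    clf = stage("svm", lambda: fit_svm(r_train, y_train, svm_params))
    pred = svm_predict(clf, r_test)
    scores = svm_scores(clf, r_test)
    log.append(("svm", pred.shape, scores.shape))

    k = int(max(np.max(y_train), np.max(y_test))) + 1
    report = stage("evaluate", lambda: metrics.full_report(y_test, pred, k, scores=scores))
    return DHLResult(
        report=report,
        n_components=pca.n_components,
        feature_dim=f_train.shape[1],
        predictions=pred,
        scores=scores,
        scaler=scaler,
        pca=pca,
        svm=clf,
        stage_log=log,
    )
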