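"""Softmax (multinomial logistic) categorization head over C2 features.

Features are standardized per column before the fit — the detector-score and
relative-position components of a C2 vector live on different scales — and
the standardization parameters are stored with the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax as _softmax
from sklearn.linear_model import LogisticRegression

from .exceptions import InsufficientDataError, ParameterError


@dataclass
class SoftmaxModel:
    """Multinomial logistic model: class scores are W z + b on standardized
    features z = (x - mean) / scale."""

    weights: np.ndarray     # (n_classes, n_features)
    biases: np.ndarray      # (n_classes,)
    class_names: list
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


def train_softmax(features: np.ndarray, labels, l2_penalty: float = 1e-4,
                  seed: int = 0, tol: float = 1e-8) -> SoftmaxModel:
    """Fit the softmax head by penalized maximum likelihood.

    Minimizes the mean cross-entropy plus an L2 penalty on the weights;
    deterministic given the inputs.  Raises on single-class input.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise InsufficientDataError("train_softmax: need at least 2 classes")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    clf = LogisticRegression(C=1.0 / (l2_penalty * len(X)), tol=tol,
                             max_iter=5000, random_state=seed)
    clf.fit(Z, y)
    # sklearn collapses binary problems to one row; expand to per-class rows.
    if clf.coef_.shape[0] == 1 and len(classes) == 2:
        W = np.vstack([-clf.coef_[0] / 2, clf.coef_[0] / 2])
        b = np.array([-clf.intercept_[0] / 2, clf.intercept_[0] / 2])
    else:
        W, b = clf.coef_.copy(), clf.intercept_.copy()
    order = np.argsort(clf.classes_)
    names = [str(clf.classes_[i]) for i in order]
    return SoftmaxModel(weights=W[order], biases=b[order], class_names=names,
                        feature_mean=mean, feature_scale=scale)


def predict_proba(model: SoftmaxModel, features: np.ndarray) -> np.ndarray:
    """Class-probability rows (each non-negative, summing to 1)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"predict_proba: feature length {X.shape[1]} != model "
            f"{model.n_features}")
    Z = (X - model.feature_mean) / model.feature_scale
    logits = Z @ model.weights.T + model.biases
    return _softmax(logits, axis=1)


def predict(model: SoftmaxModel, features: np.ndarray) -> list:
    proba = predict_proba(model, features)
    return [model.class_names[i] for i in proba.argmax(axis=1)]


def evaluate(predictions, labels) -> tuple:
    """Accuracy and per-class confusion table (rows = true class)."""
    preds = list(predictions)
    truth = list(labels)
    if len(preds) != len(truth):
        raise ParameterError(f"evaluate: {len(preds)} predictions vs "
                             f"{len(truth)} labels")
    classes = sorted(set(truth) | set(preds))
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    correct = 0
    for p, t in zip(preds, truth):
        table.loc[t, p] += 1
        correct += p == t
    accuracy = correct / len(truth) if truth else 0.0
    return accuracy, table


def save_model(model: SoftmaxModel, path: str | Path) -> None:
    data = {"weights": model.weights.tolist(), "biases": model.biases.tolist(),
            "class_names": model.class_names,
            "feature_mean": model.feature_mean.tolist(),
            "feature_scale": model.feature_scale.tolist()}
    Path(path).write_text(json.dumps(data))


def load_model(path: str | Path) -> SoftmaxModel:
    data = json.loads(Path(path).read_text())
    return SoftmaxModel(weights=np.asarray(data["weights"]),
                        biases=np.asarray(data["biases"]),
                        class_names=list(data["class_names"]),
                        feature_mean=np.asarray(data["feature_mean"]),
                        feature_scale=np.asarray(data["feature_scale"]))
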