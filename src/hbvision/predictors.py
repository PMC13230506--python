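"""Penalized linear (ridge) and gradient-boosted tree models.

Two families, each in a regression (continuous Hb, mmol/L) and a three-class
corridor classification variant.  The ridge solution is the closed-form
penalized least-squares solve with an unpenalized intercept on internally
standardized features.  The boosted-tree family wraps scikit-learn's
histogram gradient boosting (a LightGBM-style implementation) behind the
same contract; predictions are deterministic given a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
)

from .corridor_decision import LABEL_ORDER, CorridorLabel

__all__ = [
    "RidgeModel",
    "GbmParams",
    "GbmModel",
    "RidgeClassifier",
    "GbmClassifier",
    "fit_ridge",
    "fit_gbm",
    "fit_classifier",
    "predict",
]


@dataclass
class RidgeModel:
    """Closed-form ridge fit.  ``weights`` = [intercept, coef_1..coef_p] on the
    original (unstandardized) feature scale; ``penalty`` applies to the
    standardized coefficients."""

    weights: np.ndarray
    penalty: float
    feature_means: np.ndarray
    feature_scales: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.weights[0])

    @property
    def coef(self) -> np.ndarray:
        return self.weights[1:]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "penalty": self.penalty,
                "feature_means": self.feature_means.tolist(),
                "feature_scales": self.feature_scales.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RidgeModel":
        payload = json.loads(text)
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            penalty=float(payload["penalty"]),
            feature_means=np.asarray(payload["feature_means"], dtype=float),
            feature_scales=np.asarray(payload["feature_scales"], dtype=float),
        )


def fit_ridge(X: np.ndarray, y: np.ndarray, penalty: float = 1.0) -> RidgeModel:
    """Fit ridge regression by solving the penalized normal equations.

    Features are standardized internally (training mean/scale stored); the
    intercept is unpenalized.  With ``penalty`` -> infinity the slopes shrink
    to 0 and the intercept to mean(y).

    Raises
    ------
    ValueError
        For N < 2, missing values, negative penalty, or a singular system at
        penalty 0 (the message advises penalty > 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two training rows")
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in the training data")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")

    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    Z = (X - means) / scales
    G = np.column_stack([np.ones(n), Z])
    A = G.T @ G + penalty * np.diag([0.0] + [1.0] * p)
    b = G.T @ y
    if penalty == 0.0 and np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("singular system at penalty=0; use penalty > 0")
    w_std = np.linalg.solve(A, b)
    coef = w_std[1:] / scales
    intercept = w_std[0] - float(np.dot(w_std[1:], means / scales))
    return RidgeModel(
        weights=np.concatenate([[intercept], coef]),
        penalty=float(penalty),
        feature_means=means,
        feature_scales=scales,
    )


@dataclass(frozen=True)
class GbmParams:
    """Boosted-tree hyperparameters.  Defaults: 500 trees, depth <= 6,
    learning rate 0.05.  Internal early stopping (seeded, 15% holdout,
    patience 25) keeps validation behavior sane on null-signal data."""

    n_trees: int = 500
    max_depth: int = 6
    learning_rate: float = 0.05
    min_samples_leaf: int = 20
    l2_regularization: float = 0.0
    early_stopping: bool = True
    validation_fraction: float = 0.15
    n_iter_no_change: int = 25
    seed: int = 0

    def to_estimator_kwargs(self) -> dict:
        return {
            "max_iter": self.n_trees,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "min_samples_leaf": self.min_samples_leaf,
            "l2_regularization": self.l2_regularization,
            "early_stopping": self.early_stopping,
            "validation_fraction": self.validation_fraction,
            "n_iter_no_change": self.n_iter_no_change,
            "random_state": self.seed,
        }


@dataclass
class GbmModel:
    """Fitted gradient-boosted ensemble plus its hyperparameter record."""

    estimator: HistGradientBoostingRegressor
    params: GbmParams
    n_features: int

    def manifest(self) -> dict:
        return {"family": "gbm", "task": "regression", **asdict(self.params)}


def fit_gbm(
    X: np.ndarray, y: np.ndarray, params: Optional[GbmParams] = None
) -> GbmModel:
    """Fit the boosted-tree regressor; run-to-run reproducible given the seed."""
    params = params or GbmParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    est = HistGradientBoostingRegressor(**params.to_estimator_kwargs())
    est.fit(X, y)
    return GbmModel(estimator=est, params=params, n_features=X.shape[1])


@dataclass
class RidgeClassifier:
    """One-vs-rest penalized linear scorer with severity tie-break."""

    models: dict  # CorridorLabel -> RidgeModel
    classes: tuple

    @property
    def n_features(self) -> int:
        first = next(iter(self.models.values()))
        return first.coef.size


@dataclass
class GbmClassifier:
    estimator: HistGradientBoostingClassifier
    params: GbmParams
    classes: tuple
    n_features: int


def fit_classifier(
    X: np.ndarray,
    corridor_labels: Sequence[CorridorLabel],
    family: str = "ridge",
    ridge_penalty: float = 1.0,
    gbm_params: Optional[GbmParams] = None,
):
    """Fit a three-class corridor classifier.

    The ridge variant scores each class one-vs-rest with a penalized linear
    model and takes the argmax; exact score ties resolve to the more severe
    corridor (Red > Yellow > Green).  The GBM variant wraps the histogram
    gradient-boosting classifier with the same tie-break on probabilities.

    Raises
    ------
    ValueError
        If fewer than two classes are present in the training labels.
    """
    labels = [
        lab if isinstance(lab, CorridorLabel) else CorridorLabel.from_string(lab)
        for lab in corridor_labels
    ]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    present = tuple(lab for lab in LABEL_ORDER if lab in set(labels))
    if len(present) < 2:
        raise ValueError("classifier training requires at least two classes")
    if family == "ridge":
        models = {}
        for cls in present:
            y_bin = np.asarray([1.0 if lab is cls else 0.0 for lab in labels])
            models[cls] = fit_ridge(X, y_bin, penalty=ridge_penalty)
        return RidgeClassifier(models=models, classes=present)
    if family == "gbm":
        params = gbm_params or GbmParams()
        est = HistGradientBoostingClassifier(**params.to_estimator_kwargs())
        est.fit(X, np.asarray([lab.value for lab in labels]))
        return GbmClassifier(
            estimator=est, params=params, classes=present, n_features=X.shape[1]
        )
    raise ValueError(f"unknown family {family!r}")


def _check_dim(n_features: int, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return X.reshape(0, n_features)
    X = np.atleast_2d(X)
    if X.shape[1] != n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {n_features}, got {X.shape[1]}"
        )
    return X


def _argmax_severe(scores: np.ndarray, classes: tuple) -> list[CorridorLabel]:
    """Row-wise argmax over class scores; ties go to the more severe label."""
    out = []
    for row in scores:
        best = None
        for cls, val in zip(classes, row):
            if (
                best is None
                or val > best[1] + 0.0
                or (val == best[1] and cls.severity > best[0].severity)
            ):
                best = (cls, val)
        out.append(best[0])
    return out


def predict(model, X: np.ndarray):
    """Predict with any fitted model; deterministic, finite, empty-safe.

    Regression models return an array of Hb values (mmol/L); classifiers
    return a list of :class:`CorridorLabel`.
    """
    if isinstance(model, RidgeModel):
        X = _check_dim(model.coef.size, X)
        if X.shape[0] == 0:
            return np.empty(0)
        return model.intercept + X @ model.coef
    if isinstance(model, GbmModel):
        X = _check_dim(model.n_features, X)
        if X.shape[0] == 0:
            return np.empty(0)
        return model.estimator.predict(X)
    if isinstance(model, RidgeClassifier):
        X = _check_dim(model.n_features, X)
        if X.shape[0] == 0:
            return []
        scores = np.column_stack(
            [predict(model.models[cls], X) for cls in model.classes]
        )
        return _argmax_severe(scores, model.classes)
    if isinstance(model, GbmClassifier):
        X = _check_dim(model.n_features, X)
        if X.shape[0] == 0:
            return []
        proba = model.estimator.predict_proba(X)
        est_classes = tuple(
            CorridorLabel.from_string(c) for c in model.estimator.classes_
        )
        return _argmax_severe(proba, est_classes)
    raise TypeError(f"unsupported model type {type(model).__name__}")
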