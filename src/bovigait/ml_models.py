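"""Classical learners on the aggregated gait features, under leave-one-out.

The feature vector per passage is (spine_value, head_min, head_drop,
legs_value).  Six model families are exposed; ``gradient_boosting`` is
backed by XGBoost when available (falling back to scikit-learn's
estimator), the rest map directly onto scikit-learn.  ``svr`` is a
regressor whose output is rounded half-up to the nearest valid grade.

Leave-one-out (LOO) evaluation trains one model per row on all other
rows; sentinel (missing) head/leg features are imputed with the training
fold's column medians, so row i's own values never leak into its fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeClassifier

try:  # the study's gradient-boosted learner; sklearn otherwise
    from xgboost import XGBClassifier

    _HAVE_XGB = True
except ImportError:  # pragma: no cover
    _HAVE_XGB = False

logger = logging.getLogger("bovigait")

__all__ = ["ModelSpec", "FittedModel", "FAMILIES", "fit_predict_loo",
           "train_final", "predict", "save_model", "load_model"]

FAMILIES = ("decision_tree", "random_forest", "adaboost", "gradient_boosting", "knn", "svr")
FEATURE_COLUMNS = ["spine_value", "head_min", "head_drop", "legs_value"]


@dataclass(frozen=True)
class ModelSpec:
    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    task: str = "grade7"  # or "binary"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.task not in ("grade7", "binary"):
            raise ValueError("task must be 'grade7' or 'binary'")


def _as_matrix(features) -> np.ndarray:
    """Feature table -> (n, 4) float matrix with NaN for sentinels."""
    if isinstance(features, pd.DataFrame):
        return features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    from .aggregation import features_to_frame

    return features_to_frame(list(features))[FEATURE_COLUMNS].to_numpy(dtype=float)


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        col[~np.isfinite(col)] = medians[j]
    return X


def _train_medians(X: np.ndarray) -> np.ndarray:
    med = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        med[j] = np.median(finite) if finite.size else 0.0
    return med


def _encode_labels(labels, task: str) -> tuple[np.ndarray, list]:
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y.tolist()]), classes


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        if _HAVE_XGB:
            return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0, **hp)
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "svr":
        return SVR(**hp)
    raise AssertionError(spec.family)


def _round_to_classes(pred: np.ndarray, classes: list) -> np.ndarray:
    """Round regression output half-up onto the encoded class indices."""
    idx = np.floor(pred + 0.5).astype(int)
    return np.clip(idx, 0, len(classes) - 1)


@dataclass
class FittedModel:
    """A trained model plus everything needed to reproduce predictions:
    imputation medians and the label encoding."""

    spec: ModelSpec
    estimator: object
    medians: np.ndarray
    classes: list


def train_final(features, labels, spec: ModelSpec) -> FittedModel:
    """Fit one model on the full table (deployment counterpart of LOO)."""
    X = _as_matrix(features)
    y_enc, classes = _encode_labels(labels, spec.task)
    if len(classes) == 1:
        logger.warning("single-class training set; model will always predict %s", classes[0])
    medians = _train_medians(X)
    est = _make_estimator(spec)
    target = y_enc.astype(float) if spec.family == "svr" else y_enc
    est.fit(_impute(X, medians), target)
    return FittedModel(spec=spec, estimator=est, medians=medians, classes=classes)


def predict(model: FittedModel, features) -> np.ndarray:
    """Predict grades / binary labels for feature rows."""
    if not isinstance(model, FittedModel):
        raise TypeError("predict requires a FittedModel from train_final")
    X = _impute(_as_matrix(features), model.medians)
    raw = model.estimator.predict(X)
    if model.spec.family == "svr":
        idx = _round_to_classes(np.asarray(raw, dtype=float), model.classes)
    else:
        idx = np.asarray(raw, dtype=int)
    return np.array([model.classes[i] for i in idx])


def fit_predict_loo(features, labels, spec: ModelSpec) -> np.ndarray:
    """Leave-one-out predictions: row i is predicted by a model trained
    on every row except i.  Deterministic given the seed."""
    X = _as_matrix(features)
    y = np.asarray(labels)
    n = len(y)
    if n < 2:
        raise ValueError("LOO needs at least 2 rows")
    values, counts = np.unique(y, return_counts=True)
    for v, c in zip(values, counts):
        if c == 1:
            logger.warning("class %r has a single row; it is absent from its own "
                           "training fold", v)
    preds = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        model = train_final(X[keep], y[keep], spec)
        preds.append(predict(model, X[i : i + 1])[0])
    return np.array(preds)


def save_model(model: FittedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> FittedModel:
    model = joblib.load(path)
    if not isinstance(model, FittedModel):
        raise TypeError(f"{path} does not contain a FittedModel")
    return model
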