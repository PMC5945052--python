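"""Linear-SVM training, cross-validation and prediction.

Macro classification is multi-class (one-vs-rest) over candidate white
regions; micro classification is binary over pixels.  Feature z-scoring is
learned on the training data and stored inside the model, and class-balanced
instance weighting is on by default because annotated class sizes are skewed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import metrics as _metrics
from .metrics import ConfusionMatrix


@dataclass
class TrainedModel:
    kind: str                       # "macro" | "micro"
    classes: list[str]
    coef: np.ndarray                # (n_classes or 1, n_features)
    intercept: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: list[str]
    bank_config: str = ""           # serialized GaborBank parameters
    C: float = 1.0

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) one-vs-rest decision values, column per class."""
        Xs = (np.asarray(X, dtype=np.float64) - self.scaler_mean) / self.scaler_scale
        raw = Xs @ self.coef.T + self.intercept
        if len(self.classes) == 2 and raw.shape[1] == 1:
            return np.column_stack([-raw[:, 0], raw[:, 0]])
        return raw


@dataclass
class CVResult:
    fold_count: int
    confusion: ConfusionMatrix
    per_class_precision: dict[str, float | None]
    per_class_recall: dict[str, float | None]
    accuracy: float                 # percent
    auroc: float                    # percent, one-vs-rest for positive class
    positive_class: str | None = None
    fold_assignment: np.ndarray | None = field(default=None, repr=False)


def _validate_matrix(X: np.ndarray, feature_names: list[str] | None) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    bad = ~np.isfinite(X)
    if bad.any():
        col = int(np.argwhere(bad)[0][1])
        name = feature_names[col] if feature_names else f"column {col}"
        raise ValueError(f"non-finite feature values in {name}")
    return X


def train(X, y, C: float = 1.0, seed: int = 0,
          feature_names: list[str] | None = None, kind: str = "macro",
          bank_config: str = "", class_weight: str | None = "balanced",
          ) -> TrainedModel:
    """Fit a one-vs-rest linear SVM with internal per-feature z-scoring."""
    y = np.asarray(y)
    X = _validate_matrix(X, feature_names)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match matrix width")
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    svm = LinearSVC(C=C, class_weight=class_weight, random_state=seed,
                    max_iter=20000)
    svm.fit(Xs, y)
    scale = scaler.scale_.copy()
    scale[scale == 0] = 1.0
    return TrainedModel(kind=kind, classes=classes, coef=svm.coef_.copy(),
                        intercept=svm.intercept_.copy(),
                        scaler_mean=scaler.mean_.copy(), scaler_scale=scale,
                        feature_names=list(feature_names),
                        bank_config=bank_config, C=C)


def predict(model: TrainedModel, X,
            feature_names: list[str] | None = None,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus per-class decision scores.

    If ``feature_names`` is given it must match the order the model was
    trained with; a trained model refuses reordered matrices.
    """
    if feature_names is not None and list(feature_names) != model.feature_names:
        raise ValueError("feature column order does not match the trained model")
    X = _validate_matrix(X, model.feature_names)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    scores = model.decision_scores(X)
    idx = np.argmax(scores, axis=1)  # ties break toward earlier class order
    labels = np.array([model.classes[i] for i in idx])
    return labels, scores


def cross_validate(X, y, folds: int = 10, seed: int = 0,
                   positive_class: str | None = None, C: float = 1.0,
                   class_weight: str | None = "balanced") -> CVResult:
    """Stratified k-fold CV; out-of-fold predictions pooled into one table."""
    X = _validate_matrix(X, None)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    counts = {c: int((y == c).sum()) for c in classes}
    rare = [c for c, n in counts.items() if n < folds]
    if rare:
        raise ValueError(
            f"classes {rare} have fewer than {folds} members; "
            f"use at most {min(counts.values())} folds")
    if positive_class is None:
        positive_class = classes[-1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    pos_scores = np.empty(len(y), dtype=np.float64)
    assignment = np.empty(len(y), dtype=np.int64)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = train(X[tr], y[tr], C=C, seed=seed, class_weight=class_weight)
        labels, scores = predict(model, X[te])
        pred[te] = labels
        pos_scores[te] = scores[:, model.classes.index(positive_class)]
        assignment[te] = f
    cm = _metrics.confusion(y, pred, classes)
    auroc_pct = 100.0 * _metrics.auroc(pos_scores, y == positive_class)
    report = _metrics.metrics_report(cm)
    return CVResult(
        fold_count=folds, confusion=cm,
        per_class_precision={c: report["per_class"][c]["precision_pct"]
                             for c in classes},
        per_class_recall={c: report["per_class"][c]["recall_pct"]
                          for c in classes},
        accuracy=report["accuracy_pct"], auroc=auroc_pct,
        positive_class=positive_class, fold_assignment=assignment)


def save_model(model: TrainedModel, path: str | os.PathLike) -> None:
    """Persist as a single JSON document (floats round-trip exactly)."""
    doc = {
        "kind": model.kind, "classes": model.classes, "C": model.C,
        "feature_names": model.feature_names, "bank_config": model.bank_config,
        "coef": model.coef.tolist(), "intercept": model.intercept.tolist(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
    }
    with open(os.fspath(path), "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | os.PathLike) -> TrainedModel:
    with open(os.fspath(path)) as fh:
        doc = json.load(fh)
    return TrainedModel(
        kind=doc["kind"], classes=doc["classes"],
        coef=np.array(doc["coef"], dtype=np.float64),
        intercept=np.array(doc["intercept"], dtype=np.float64),
        scaler_mean=np.array(doc["scaler_mean"], dtype=np.float64),
        scaler_scale=np.array(doc["scaler_scale"], dtype=np.float64),
        feature_names=doc["feature_names"], bank_config=doc["bank_config"],
        C=doc["C"])
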