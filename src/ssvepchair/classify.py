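"""Five-class SSVEP classification with a polynomial-kernel SVM.

The five classes are the four stimulation frequencies plus rest.  Features
are standardized (per-feature z-scores learned on the training partition
only — polynomial kernels are scale-sensitive) and fed to a degree-3
polynomial-kernel SVM with the native one-vs-one multiclass scheme.
Evaluation follows the stratified 80/20 train/validation protocol and
reports a confusion matrix, overall accuracy, and per-class recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decode import FeatureVector
from .simulate import CLASSES

logger = logging.getLogger(__name__)


@dataclass
class TrainedModel:
    """A fitted scaler + polynomial-SVM pipeline with its class order."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    feature_set: str = "fft"

    @property
    def n_features(self) -> int:
        return self.pipeline.named_steps["scaler"].mean_.size


@dataclass
class EvaluationReport:
    """Validation results: confusion matrix (rows = true), accuracy, recall."""

    confusion_matrix: np.ndarray
    accuracy: float
    per_class_recall: np.ndarray
    classes: tuple[str, ...]

    @property
    def n_total(self) -> int:
        return int(self.confusion_matrix.sum())


def split_dataset(
    features: list[FeatureVector],
    train_fraction: float = 0.8,
    seed: int = 0,
    require_classes: tuple[str, ...] | None = CLASSES,
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Stratified train/validation split of labeled feature vectors.

    All five decoder classes must be represented (pass
    ``require_classes=None`` for ad-hoc label sets); splitting is
    deterministic given ``seed``.  ``train_fraction=1.0`` returns an empty
    validation set with a warning.
    """
    if not 0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if len(features) < 5:
        raise ValueError("need at least 5 labeled feature vectors")
    labels = [fv.label for fv in features]
    if any(lbl is None for lbl in labels):
        raise ValueError("all feature vectors must be labeled")
    present = set(labels)
    if require_classes is not None:
        missing = [c for c in require_classes if c not in present]
        if missing:
            raise ValueError(f"classes {missing} are absent from the dataset")
    if train_fraction == 1.0:
        logger.warning("train_fraction=1.0: validation set is empty")
        return list(features), []
    counts = {c: labels.count(c) for c in present}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes {thin} have fewer than 2 examples; "
                         "cannot stratify")
    train, val = train_test_split(
        features,
        test_size=1.0 - train_fraction,
        stratify=labels,
        random_state=seed,
    )
    return list(train), list(val)


def _to_xy(
    feature_vectors: list[FeatureVector], feature_set: str
) -> tuple[np.ndarray, np.ndarray]:
    x = np.vstack([fv.as_array(feature_set) for fv in feature_vectors])
    y = np.array([fv.label for fv in feature_vectors])
    return x, y


def train(
    train_set: list[FeatureVector],
    feature_set: str = "fft",
    degree: int = 3,
    c: float = 1.0,
) -> TrainedModel:
    """Fit the standardizer and degree-3 polynomial SVM on the training set."""
    if not train_set:
        raise ValueError("training set is empty")
    x, y = _to_xy(train_set, feature_set)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("svm", SVC(kernel="poly", degree=degree, C=c)),
    ])
    pipe.fit(x, y)
    fitted = tuple(pipe.named_steps["svm"].classes_)
    # report classes in canonical order, extras (if any) appended
    ordered = tuple(c for c in CLASSES if c in fitted) + tuple(
        c for c in fitted if c not in CLASSES
    )
    return TrainedModel(pipeline=pipe, classes=ordered, feature_set=feature_set)


def predict(model: TrainedModel, feature_vectors: list[FeatureVector]) -> list[str]:
    """Predicted class labels for a list of feature vectors."""
    if not feature_vectors:
        return []
    x, _ = _to_xy(feature_vectors, model.feature_set)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimensionality {x.shape[1]} != model's {model.n_features}"
        )
    return list(model.pipeline.predict(x))


def evaluate(
    model: TrainedModel, validation_set: list[FeatureVector]
) -> EvaluationReport:
    """Confusion matrix, accuracy and per-class recall on held-out windows."""
    if not validation_set:
        raise ValueError("validation set is empty")
    x, y_true = _to_xy(validation_set, model.feature_set)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimensionality {x.shape[1]} != model's {model.n_features}"
        )
    y_pred = model.pipeline.predict(x)
    cm = _sk_confusion(y_true, y_pred, labels=list(model.classes))
    accuracy = float(np.trace(cm)) / float(cm.sum())
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, np.diag(cm) / row_sums, np.nan)
    return EvaluationReport(
        confusion_matrix=cm,
        accuracy=accuracy,
        per_class_recall=recall,
        classes=model.classes,
    )
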