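"""k-nearest-neighbor activity-class gate and its leave-one-subject-out
evaluation.

The classifier assigns each 60-s window to one of four activity classes
(sedentary, low-intensity, high-intensity, walking) from five features of the
ankle, chest and wrist signals. Neighbors vote with squared-inverse-distance
weights; exact matches (distance 0) decide by majority among themselves; ties
break by the fixed class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ACTIVITY_CLASSES
from .presets import CLASSIFIER_FEATURES

_CLASS_RANK = {c: i for i, c in enumerate(ACTIVITY_CLASSES)}


@dataclass
class ClassifierConfig:
    k: int = 10
    features: tuple = CLASSIFIER_FEATURES
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FittedKnn:
    config: ClassifierConfig
    X: np.ndarray          # standardized training matrix (n, p)
    labels: np.ndarray     # training class labels (n,)
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class ConfusionReport:
    """Pooled 4x4 confusion matrix (rows true, cols predicted)."""

    matrix: pd.DataFrame
    accuracy: float
    per_class_sensitivity: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, true: Sequence[str], pred: Sequence[str]) -> "ConfusionReport":
        classes = list(ACTIVITY_CLASSES)
        mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(true, pred):
            mat.loc[t, p] += 1
        total = mat.to_numpy().sum()
        acc = float(np.trace(mat.to_numpy()) / total) if total else float("nan")
        sens = {}
        for c in classes:
            row = mat.loc[c].sum()
            sens[c] = float(mat.loc[c, c] / row) if row else float("nan")
        return cls(matrix=mat, accuracy=acc, per_class_sensitivity=sens)


def _extract(table: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in selected classifier features")
    return X


def fit_knn(table: pd.DataFrame, labels: Sequence[str],
            config: ClassifierConfig | None = None) -> FittedKnn:
    """Store (standardized) training points and labels. Deterministic."""
    config = config or ClassifierConfig()
    X = _extract(table, config.features)
    labels = np.asarray(labels)
    if X.shape[0] < config.k:
        raise ValueError(f"need at least k={config.k} training rows, got {X.shape[0]}")
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    return FittedKnn(config=config, X=(X - mean) / scale, labels=labels,
                     mean=mean, scale=scale)


def classify(fitted: FittedKnn, table: pd.DataFrame) -> np.ndarray:
    """Predict class labels for the rows of ``table``.

    Vote weight is 1/d^2 over the k nearest training points. Any
    zero-distance neighbors short-circuit to a majority vote among
    themselves. Ties break by the canonical class order.
    """
    Q = fitted.transform(_extract(table, fitted.config.features))
    k = fitted.config.k
    preds = []
    for q in Q:
        d2 = np.sum((fitted.X - q) ** 2, axis=1)
        order = np.argsort(d2, kind="stable")[:k]
        nd2 = d2[order]
        nlab = fitted.labels[order]
        if np.any(nd2 == 0):
            votes = {}
            for lab in nlab[nd2 == 0]:
                votes[lab] = votes.get(lab, 0) + 1
        else:
            votes = {}
            for lab, dd in zip(nlab, nd2):
                votes[lab] = votes.get(lab, 0.0) + 1.0 / dd
        best = max(votes.items(), key=lambda kv: (kv[1], -_CLASS_RANK[kv[0]]))
        preds.append(best[0])
    return np.asarray(preds)


def loso_cv(table: pd.DataFrame, config: ClassifierConfig | None = None) -> ConfusionReport:
    """Leave-one-subject-out cross-validation of the activity classifier.

    ``table`` must carry ``subject_id`` and ``activity_class`` columns plus
    the classifier features. One fold per subject; the pooled confusion
    matrix over all held-out predictions is returned.
    """
    config = config or ClassifierConfig()
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("LOSO cross-validation needs at least 2 subjects")
    true_all, pred_all = [], []
    for sid in subjects:
        test = table[table["subject_id"] == sid]
        train = table[table["subject_id"] != sid]
        if len(test) == 0:
            continue
        fitted = fit_knn(train, train["activity_class"].to_numpy(), config)
        pred = classify(fitted, test)
        true_all.extend(test["activity_class"].tolist())
        pred_all.extend(pred.tolist())
    return ConfusionReport.from_labels(true_all, pred_all)
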