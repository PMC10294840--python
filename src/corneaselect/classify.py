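"""Data splitting, linear-SVM training and the accuracy metric.

The classifier is a linear-kernel SVM on per-map mean descriptors, with
train-estimated feature standardization on by default (SVM margins are
scale-sensitive).  Splits are 70/30 stratified by default; the training
fraction is floored (712 samples -> 498 train / 214 test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "split",
    "train_svm",
    "confusion",
    "accuracy",
    "evaluate_split",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification (default 70/30, stratified)."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; class 1 ("ulcer present") is positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def split(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index sets.

    Training size is ``floor(train_fraction * n)``; stratified splits
    preserve class proportions within rounding.  Deterministic for a fixed
    seed.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    strat = labels if spec.stratified else None
    if spec.stratified:
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples per class")
    train, test = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=strat,
        random_state=spec.seed,
        shuffle=True,
    )
    return np.sort(train), np.sort(test)


def train_svm(
    table: FeatureTable,
    train_idx,
    C: float = 1.0,
    standardize: bool = True,
) -> Pipeline:
    """Fit a linear-kernel SVM on the training rows of a feature table.

    Standardization parameters, when enabled, are estimated on the
    training rows only.
    """
    train_idx = np.asarray(train_idx)
    y = table.labels[train_idx]
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="linear", C=C)))
    model = Pipeline(steps)
    model.fit(table.values[train_idx], y)
    return model


def confusion(model, table: FeatureTable, test_idx) -> ConfusionCounts:
    """Confusion counts of a fitted model on the test rows."""
    test_idx = np.asarray(test_idx)
    y_true = table.labels[test_idx]
    y_pred = np.asarray(model.predict(table.values[test_idx]))
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def evaluate_split(
    table: FeatureTable,
    spec: SplitSpec,
    C: float = 1.0,
    standardize: bool = True,
) -> float:
    """Train on the split's training rows, return test accuracy."""
    train_idx, test_idx = split(table.labels, spec)
    model = train_svm(table, train_idx, C=C, standardize=standardize)
    return accuracy(confusion(model, table, test_idx))
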