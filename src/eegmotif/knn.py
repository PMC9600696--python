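"""Weighted k-nearest-neighbour classification and cross-validation.

The classifier uses L1 (Manhattan) distance with squared-inverse distance
weighting: each of the k nearest training points votes for its class with
weight 1/d^2.  All tie rules are deterministic:

* equal distances rank by lower training index (stable sort);
* a zero-distance neighbour gives its class infinite score; with several
  zero-distance neighbours the majority class among them wins, ties going
  to the smaller label;
* equal class scores go to the smaller label.

Two cross-validation harnesses produce out-of-fold prediction vectors in
record order: seeded stratified 10-fold, and leave-one-subject-out (LOSO),
where every record of one subject is held out together so no subject ever
appears in both train and test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = ["KNNParams", "PredictionVector", "knn_predict", "crossval_predict"]


@dataclass(frozen=True)
class KNNParams:
    """k, with L1 distance and squared-inverse weighting implied."""

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class PredictionVector:
    """Out-of-fold predicted labels aligned with record order."""

    labels: np.ndarray
    channel: int | None = None
    scheme: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.labels)


def _majority_smallest(labels: np.ndarray) -> int:
    """Most frequent label; frequency ties go to the smaller label."""
    counts = Counter(int(v) for v in labels)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    params: KNNParams | None = None,
) -> np.ndarray:
    """Predict test labels with the weighted kNN rule described above."""
    params = params or KNNParams()
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] < params.k:
        raise ValueError(
            f"k={params.k} exceeds the {train_X.shape[0]} training records"
        )
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    D = cdist(test_X, train_X, metric="cityblock")
    preds = np.empty(test_X.shape[0], dtype=int)
    for t in range(test_X.shape[0]):
        order = np.argsort(D[t], kind="stable")[: params.k]
        dists = D[t, order]
        labels = train_y[order]
        zero = dists == 0.0
        if np.any(zero):
            preds[t] = _majority_smallest(labels[zero])
            continue
        scores: dict[int, float] = {}
        for lab, dv in zip(labels, dists):
            scores[int(lab)] = scores.get(int(lab), 0.0) + 1.0 / (dv * dv)
        best = max(scores.items(), key=lambda kv: (kv[1], -kv[0]))
        preds[t] = best[0]
    return preds


def _loso_folds(subject_ids: list[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    subjects = np.asarray(subject_ids)
    folds = []
    for subj in sorted(set(subject_ids)):
        test = np.flatnonzero(subjects == subj)
        train = np.flatnonzero(subjects != subj)
        folds.append((train, test))
    return folds


def crossval_predict(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str = "tenfold",
    subject_ids: list[str] | None = None,
    params: KNNParams | None = None,
    seed: int = 0,
    channel: int | None = None,
) -> PredictionVector:
    """Out-of-fold kNN predictions under ten-fold or LOSO cross-validation.

    ``tenfold`` uses a seeded stratified split (10 folds, each within one
    record of the global class proportions); ``loso`` makes one fold per
    subject id and requires ``subject_ids``.
    """
    params = params or KNNParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if scheme == "tenfold":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 10:
            raise ValueError("ten-fold CV needs at least 10 records per class")
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    elif scheme == "loso":
        if subject_ids is None:
            raise ValueError("LOSO requires subject_ids")
        if len(set(subject_ids)) < 2:
            raise ValueError("LOSO needs at least 2 subjects")
        folds = _loso_folds(list(subject_ids))
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}; use 'tenfold' or 'loso'")

    preds = np.full(len(y), -1, dtype=int)
    for train, test in folds:
        if scheme == "loso" and subject_ids is not None:
            train_subj = {subject_ids[i] for i in train}
            test_subj = {subject_ids[i] for i in test}
            assert not (train_subj & test_subj), "subject leaked across a LOSO fold"
        preds[test] = knn_predict(X[train], y[train], X[test], params)
    assert np.all(preds >= 0), "some record received no out-of-fold prediction"
    return PredictionVector(labels=preds, channel=channel, scheme=scheme, seed=seed)
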