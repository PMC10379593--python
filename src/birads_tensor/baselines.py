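"""Classical baselines on one-hot encoded BI-RADS characteristics.

KNN scores a query by the malignant fraction among its k nearest training
images; the maximum-margin baseline is a kernel SVM scored by its signed
distance to the separating hyperplane. Both sit behind thin wrappers over
scikit-learn with a small validation grid for their hyperparameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .records import CHARACTERISTICS, MALIGNANT, AnnotationRecord

__all__ = [
    "one_hot_features",
    "baseline_nearest_neighbour",
    "baseline_max_margin",
]


def one_hot_features(
    records: list[AnnotationRecord], vocabulary: dict[str, list[str]] | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, list[str]]]:
    """One-hot encode the ten characteristics; labels 1 = malignant.

    Returns (X, y, vocabulary); pass the training vocabulary back in to
    encode test records into the same columns.
    """
    if vocabulary is None:
        vocabulary = {c: [] for c in CHARACTERISTICS}
        for rec in records:
            for c in CHARACTERISTICS:
                v = rec.characteristics.get(c)
                if v is not None and v not in vocabulary[c]:
                    vocabulary[c].append(v)
    cols = sum(len(v) for v in vocabulary.values())
    X = np.zeros((len(records), cols))
    y = np.zeros(len(records), dtype=int)
    for i, rec in enumerate(records):
        offset = 0
        for c in CHARACTERISTICS:
            values = vocabulary[c]
            v = rec.characteristics.get(c)
            if v in values:
                X[i, offset + values.index(v)] = 1.0
            offset += len(values)
        y[i] = int(rec.pathology == MALIGNANT)
    return X, y, vocabulary


def baseline_nearest_neighbour(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int | None = None,
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9, 15),
    seed: int = 0,
) -> np.ndarray:
    """KNN malignancy scores (fraction of malignant among k nearest).

    With ``k=None``, k is chosen from ``k_grid`` by cross-validated
    accuracy on the training set.
    """
    n = len(train_features)
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds training size {n}")
    if k is None:
        cv = _max_cv(train_labels)
        # k must fit inside a CV training split, not just the full set
        fit_size = n * (cv - 1) // cv if cv >= 2 else n
        grid = [kk for kk in k_grid if kk <= max(1, fit_size)]
        if not grid:
            raise ValueError("no admissible k in grid")
        if len(grid) == 1 or cv < 2:
            k = grid[0]
        else:
            search = GridSearchCV(
                KNeighborsClassifier(),
                {"n_neighbors": grid},
                cv=cv,
                scoring="accuracy",
            )
            search.fit(train_features, train_labels)
            k = int(search.best_params_["n_neighbors"])
    clf = KNeighborsClassifier(n_neighbors=k).fit(train_features, train_labels)
    return clf.predict_proba(test_features)[:, list(clf.classes_).index(1)]


def baseline_max_margin(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    kernel: str = "rbf",
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    seed: int = 0,
) -> np.ndarray:
    """Maximum-margin (SVM) decision-value scores for the malignant class."""
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set contains a single class")
    cv = _max_cv(train_labels)
    if len(c_grid) == 1 or cv < 2:
        clf = SVC(kernel=kernel, C=c_grid[0]).fit(train_features, train_labels)
    else:
        search = GridSearchCV(
            SVC(kernel=kernel),
            {"C": list(c_grid)},
            cv=cv,
            scoring="accuracy",
        )
        search.fit(train_features, train_labels)
        clf = search.best_estimator_
    return clf.decision_function(test_features)


def _max_cv(labels) -> int:
    """Largest stratified fold count the class counts allow, capped at 5."""
    _, counts = np.unique(labels, return_counts=True)
    return int(min(5, counts.min()))
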