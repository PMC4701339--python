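"""Local-mean and pseudo nearest-neighbour classifiers.

Three k-NN variants designed to resist outliers in small samples. All of them
first find, for a query ``x`` and *each class separately*, that class's k
nearest training points by Euclidean distance (k truncated to the class size),
then score each class and pick the minimum:

- LMKNN: distance from ``x`` to the mean of the class's k nearest neighbours.
- PNN: the 1/j-weighted sum of distances to the class's j-th nearest
  neighbours, j = 1..k (closer neighbours weigh more).
- LMPNN: the 1/j-weighted sum of distances to the class's *cumulative* local
  means over its first j neighbours.

At k=1 all three reduce to per-class nearest neighbour. Ties between training
points at equal distance are broken by original row index; ties between class
scores are broken toward the class listed earlier in the class order (for the
fall-risk task the faller class comes first, so ambiguity resolves toward
sensitivity).

The classes follow the scikit-learn estimator protocol (``fit`` / ``predict``
/ ``get_params``) and compose with sklearn model selection; the module-level
``*_classify`` functions are one-shot wrappers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError

__all__ = [
    "LocalMeanKNN",
    "PseudoNearestNeighbor",
    "LocalMeanPseudoNearestNeighbor",
    "knn_per_class",
    "lmknn_classify",
    "pnn_classify",
    "lmpnn_classify",
]


def _check_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError("X must be a 2-D array of shape (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ParameterError("X must not contain NaN or infinite values")
    return X


def _resolve_classes(y: np.ndarray, class_order) -> np.ndarray:
    present = np.unique(y)
    if class_order is None:
        return present
    ordered = np.asarray(class_order)
    if set(ordered.tolist()) != set(present.tolist()):
        raise ParameterError(
            f"class_order {ordered.tolist()} does not match labels {present.tolist()}"
        )
    return ordered


def _sorted_class_neighbors(x, X, indices, k):
    """Distances and vectors of a class's k nearest members, stable order."""
    d = np.linalg.norm(X[indices] - x, axis=1)
    order = np.argsort(d, kind="stable")  # equal distances: lower row index first
    k_eff = min(k, indices.size)
    take = order[:k_eff]
    return indices[take], d[take]


def knn_per_class(x, X, y, k: int, class_order=None) -> dict:
    """Per class: indices and distances of its k nearest neighbours of ``x``.

    k is truncated to the class size; every class must have at least one
    member. Returns ``{label: (indices, distances)}`` in class order.
    """
    X = _check_matrix(X)
    y = np.asarray(y)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != X.shape[1]:
        raise ParameterError(
            f"query has {x.size} features, training data has {X.shape[1]}"
        )
    if k < 1:
        raise ParameterError("k must be >= 1")
    out = {}
    for label in _resolve_classes(y, class_order):
        members = np.flatnonzero(y == label)
        idx, dist = _sorted_class_neighbors(x, X, members, k)
        out[label] = (idx, dist)
    return out


class _LocalNeighborClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses define the per-class score."""

    def __init__(self, k: int = 1, class_order=None):
        self.k = k
        self.class_order = class_order

    def fit(self, X, y):
        X = _check_matrix(X)
        y = np.asarray(y)
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ParameterError("y must be 1-D with one label per row of X")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ParameterError("k must be an integer >= 1")
        classes = _resolve_classes(y, self.class_order)
        if classes.size < 2:
            raise ParameterError("need at least two classes")
        self.classes_ = classes
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        self._class_members_ = [np.flatnonzero(y == c) for c in classes]
        return self

    def _score_class(self, x, sorted_dist, sorted_vectors) -> float:
        raise NotImplementedError

    def decision_scores(self, X) -> np.ndarray:
        """Per-class scores, shape (n_queries, n_classes); lower is closer."""
        check_is_fitted(self, "X_")
        X = _check_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"query has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        scores = np.empty((X.shape[0], len(self.classes_)))
        for i, x in enumerate(X):
            for c, members in enumerate(self._class_members_):
                idx, dist = _sorted_class_neighbors(x, self.X_, members, self.k)
                scores[i, c] = self._score_class(x, dist, self.X_[idx])
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmin returns the first minimum: ties go to the earlier class.
        return self.classes_[np.argmin(scores, axis=1)]


class LocalMeanKNN(_LocalNeighborClassifier):
    """Classify to the class whose local mean of k nearest neighbours is closest."""

    def _score_class(self, x, sorted_dist, sorted_vectors) -> float:
        return float(np.linalg.norm(x - sorted_vectors.mean(axis=0)))


class PseudoNearestNeighbor(_LocalNeighborClassifier):
    """Classify by the minimal 1/j-weighted sum of per-class neighbour distances."""

    def _score_class(self, x, sorted_dist, sorted_vectors) -> float:
        weights = 1.0 / np.arange(1, sorted_dist.size + 1)
        return float(np.dot(weights, sorted_dist))


class LocalMeanPseudoNearestNeighbor(_LocalNeighborClassifier):
    """Classify by the minimal 1/j-weighted sum of distances to cumulative local means."""

    def _score_class(self, x, sorted_dist, sorted_vectors) -> float:
        counts = np.arange(1, sorted_vectors.shape[0] + 1)
        cummeans = np.cumsum(sorted_vectors, axis=0) / counts[:, None]
        dists = np.linalg.norm(x - cummeans, axis=1)
        return float(np.dot(1.0 / counts, dists))


CLASSIFIERS = {
    "lmknn": LocalMeanKNN,
    "pnn": PseudoNearestNeighbor,
    "lmpnn": LocalMeanPseudoNearestNeighbor,
}


def make_classifier(name: str, k: int = 1, class_order=None) -> _LocalNeighborClassifier:
    try:
        cls = CLASSIFIERS[name]
    except KeyError:
        raise ParameterError(
            f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}"
        ) from None
    return cls(k=k, class_order=class_order)


def _classify_one(name, x, X, y, k, class_order):
    est = make_classifier(name, k=k, class_order=class_order).fit(X, y)
    return est.predict(np.atleast_2d(np.asarray(x, dtype=float)))[0]


def lmknn_classify(x, X, y, k: int, class_order=None):
    """One-shot LMKNN decision for a single query vector."""
    return _classify_one("lmknn", x, X, y, k, class_order)


def pnn_classify(x, X, y, k: int, class_order=None):
    """One-shot PNN decision for a single query vector."""
    return _classify_one("pnn", x, X, y, k, class_order)


def lmpnn_classify(x, X, y, k: int, class_order=None):
    """One-shot LMPNN decision for a single query vector."""
    return _classify_one("lmpnn", x, X, y, k, class_order)
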