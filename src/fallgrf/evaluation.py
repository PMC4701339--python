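"""Leave-one-out evaluation, exhaustive subset search and subset selection.

Every nonempty subset of the eight entropy features (255 masks) is scored by
leave-one-out cross-validation (LOOCV) for each classifier and each k. A
held-out prediction for every subject is aggregated into one confusion matrix
per (subset, classifier, k), from which accuracy, sensitivity and specificity
follow. The winning subset per classifier is the maximum under a
sensitivity-first total order (sensitivity, then accuracy, then specificity,
then smaller subset, lexicographic mask, smaller k), reflecting that for fall
screening a missed faller is the costly error.

``full_search`` uses a vectorized LOOCV path that scores all three decision
rules and every k in one pass per subset; its equivalence with the per-fold
estimator route (``loocv``) is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classifiers import CLASSIFIERS, make_classifier, _check_matrix, _resolve_classes
from .data import FEATURE_NAMES
from .exceptions import FoldError, ParameterError

#: Decision-rule order used by the vectorized LOOCV path.
RULE_NAMES = ("lmknn", "pnn", "lmpnn")

METRIC_NAMES = ("sensitivity", "accuracy", "specificity")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with the faller (at-risk) class as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ParameterError(f"confusion count {name} must be a count >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as proportions in [0, 1].

    A zero denominator (no positives, or no negatives) yields NaN for the
    affected rate rather than an exception; selection ranks NaN below any
    defined value.
    """
    if cm.n < 1:
        raise ParameterError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.n
    sensitivity = cm.tp / cm.n_positive if cm.n_positive else float("nan")
    specificity = cm.tn / cm.n_negative if cm.n_negative else float("nan")
    return accuracy, sensitivity, specificity


@dataclass(frozen=True)
class SubsetEvaluation:
    """One LOOCV result: feature subset, classifier, k and its metrics."""

    subset: tuple[int, ...]
    classifier: str
    k: int
    cm: ConfusionMatrix
    accuracy: float = field(default=None)
    sensitivity: float = field(default=None)
    specificity: float = field(default=None)
    winning_k: tuple[int, ...] = ()

    def __post_init__(self):
        acc, sens, spec = metrics(self.cm)
        object.__setattr__(self, "accuracy", acc if self.accuracy is None else self.accuracy)
        object.__setattr__(self, "sensitivity", sens if self.sensitivity is None else self.sensitivity)
        object.__setattr__(self, "specificity", spec if self.specificity is None else self.specificity)
        if not self.winning_k:
            object.__setattr__(self, "winning_k", (self.k,))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(FEATURE_NAMES[i] for i in self.subset)


def enumerate_subsets(n_features: int) -> list[tuple[int, ...]]:
    """All nonempty feature index subsets: ascending size, lexicographic within."""
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    masks: list[tuple[int, ...]] = []
    for size in range(1, n_features + 1):
        masks.extend(combinations(range(n_features), size))
    return masks


def _prepare_labels(y, class_order, positive_label):
    y = np.asarray(y)
    classes = _resolve_classes(y, class_order)
    if classes.size != 2:
        raise ParameterError("evaluation requires exactly two classes")
    if positive_label is None:
        positive_label = classes[0]
    elif positive_label not in classes:
        raise ParameterError(f"positive label {positive_label!r} not among classes")
    return y, classes, positive_label


def _confusion_from_predictions(y_true, y_pred, positive_label) -> ConfusionMatrix:
    pos = y_true == positive_label
    pred_pos = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pos & pred_pos)),
        fn=int(np.count_nonzero(pos & ~pred_pos)),
        fp=int(np.count_nonzero(~pos & pred_pos)),
        tn=int(np.count_nonzero(~pos & ~pred_pos)),
    )


def loocv(
    X,
    y,
    subset=None,
    classifier: str = "lmpnn",
    k: int = 1,
    class_order=None,
    positive_label=None,
) -> ConfusionMatrix:
    """Leave-one-out confusion matrix for one (subset, classifier, k).

    Each subject is predicted by a model trained on all others; the n held-out
    predictions form one confusion matrix. Entirely deterministic. A class
    with a single member would vanish from its fold's training set, which
    raises :class:`FoldError`.
    """
    X = _check_matrix(X)
    y, classes, positive_label = _prepare_labels(y, class_order, positive_label)
    n = X.shape[0]
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 samples")
    if subset is None:
        subset = tuple(range(X.shape[1]))
    subset = tuple(subset)
    if len(subset) == 0:
        raise ParameterError("feature subset must be nonempty")
    Xs = X[:, subset]

    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if np.unique(y_train).size < classes.size:
            raise FoldError(
                f"fold {i}: a class has no training members (singleton class)"
            )
        est = make_classifier(classifier, k=k, class_order=classes).fit(
            Xs[mask], y_train
        )
        preds[i] = est.predict(Xs[i : i + 1])[0]
    return _confusion_from_predictions(y, preds, positive_label)


def _loocv_rule_grid(Xs, y_codes, n_classes, k_values):
    """Held-out predictions for all rules and k values in one pass.

    Returns an integer array of class codes, shape
    ``(len(RULE_NAMES), len(k_values), n)``. Mirrors the estimator classes:
    stable sort for distance ties, k truncated per class, argmin with
    earlier-class preference.
    """
    n = Xs.shape[0]
    k_values = np.asarray(k_values, dtype=int)
    k_max = int(k_values.max())
    diff = Xs[:, None, :] - Xs[None, :, :]
    d_full = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    members = [np.flatnonzero(y_codes == c) for c in range(n_classes)]
    preds = np.empty((len(RULE_NAMES), k_values.size, n), dtype=int)
    scores = np.empty((len(RULE_NAMES), n_classes, k_values.size))
    for i in range(n):
        for c in range(n_classes):
            idx = members[c]
            idx = idx[idx != i]
            if idx.size == 0:
                raise FoldError(
                    f"fold {i}: class code {c} has no training members"
                )
            d = d_full[i, idx]
            order = np.argsort(d, kind="stable")
            k_eff = min(k_max, idx.size)
            take = order[:k_eff]
            sorted_d = d[take]
            vectors = Xs[idx[take]]
            counts = np.arange(1, k_eff + 1)
            cummeans = np.cumsum(vectors, axis=0) / counts[:, None]
            d_lm = np.linalg.norm(Xs[i] - cummeans, axis=1)
            w = 1.0 / counts
            pnn_cum = np.cumsum(w * sorted_d)
            lmpnn_cum = np.cumsum(w * d_lm)
            j = np.minimum(k_values, k_eff) - 1
            scores[0, c] = d_lm[j]
            scores[1, c] = pnn_cum[j]
            scores[2, c] = lmpnn_cum[j]
        preds[:, :, i] = np.argmin(scores, axis=1)
    return preds


def _rank_key(ev: SubsetEvaluation, priority):
    def neg(v):
        return float("inf") if v is None or np.isnan(v) else -v

    vals = {"accuracy": ev.accuracy, "sensitivity": ev.sensitivity,
            "specificity": ev.specificity}
    key = [neg(vals[m]) for m in priority]
    key += [len(ev.subset), ev.subset, ev.k]
    return tuple(key)


def _full_priority(priority) -> tuple[str, ...]:
    priority = tuple(priority)
    for m in priority:
        if m not in METRIC_NAMES:
            raise ParameterError(f"unknown metric {m!r} in selection priority")
    return priority + tuple(m for m in METRIC_NAMES if m not in priority)


def select_best(evals, priority=("sensitivity", "accuracy")) -> SubsetEvaluation:
    """The maximal evaluation under the sensitivity-first total order.

    Ordering: the metrics in ``priority`` (remaining metrics appended in
    sensitivity/accuracy/specificity order), then fewer features, then
    lexicographically smaller mask, then smaller k. NaN metrics rank below any
    defined value. The order is total, so the winner is unique and duplicates
    of the winner cannot change it.
    """
    evals = list(evals)
    if not evals:
        raise ParameterError("cannot select from an empty list of evaluations")
    priority = _full_priority(priority)
    return min(evals, key=lambda ev: _rank_key(ev, priority))


@dataclass
class SearchResult:
    """Exhaustive-search output: full grid, per-classifier winners, k profile."""

    grid: pd.DataFrame
    best: dict[str, SubsetEvaluation]
    best_overall: SubsetEvaluation
    rate_by_k: pd.DataFrame


def full_search(
    X,
    y,
    classifiers=RULE_NAMES,
    k_values=None,
    k_max: int = 10,
    class_order=None,
    positive_label=None,
    priority=("sensitivity", "accuracy"),
) -> SearchResult:
    """LOOCV over every nonempty feature subset x classifier x k.

    ``k_values`` defaults to ``1..min(k_max, smallest class size - 1)`` so a
    fold can never ask for more neighbours than a class can provide without
    truncation dominating. Returns the full results grid (one row per subset/
    classifier/k with confusion counts and metrics), the winning evaluation
    per classifier (with every k achieving the winning metrics reported), the
    overall winner, and the best accuracy attainable at each k per classifier.
    """
    X = _check_matrix(X)
    y, classes, positive_label = _prepare_labels(y, class_order, positive_label)
    for name in classifiers:
        if name not in CLASSIFIERS:
            raise ParameterError(f"unknown classifier {name!r}")
    code_of = {label: c for c, label in enumerate(classes)}
    y_codes = np.array([code_of[label] for label in y])
    pos_code = code_of[positive_label]
    class_sizes = np.bincount(y_codes, minlength=2)
    if class_sizes.min() < 2:
        raise FoldError("each class needs at least 2 members for LOOCV")
    if k_values is None:
        k_cap = max(1, min(k_max, int(class_sizes.min()) - 1))
        k_values = list(range(1, k_cap + 1))
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 1:
        raise ParameterError("k values must be positive integers")

    rule_idx = [RULE_NAMES.index(name) for name in classifiers]
    subsets = enumerate_subsets(X.shape[1])
    pos_mask = y_codes == pos_code
    records = []
    evaluations: dict[str, list[SubsetEvaluation]] = {name: [] for name in classifiers}
    for subset in subsets:
        preds = _loocv_rule_grid(X[:, subset], y_codes, classes.size, k_values)
        for name, ri in zip(classifiers, rule_idx):
            for ki, k in enumerate(k_values):
                pred_pos = preds[ri, ki] == pos_code
                cm = ConfusionMatrix(
                    tp=int(np.count_nonzero(pos_mask & pred_pos)),
                    fn=int(np.count_nonzero(pos_mask & ~pred_pos)),
                    fp=int(np.count_nonzero(~pos_mask & pred_pos)),
                    tn=int(np.count_nonzero(~pos_mask & ~pred_pos)),
                )
                ev = SubsetEvaluation(subset=subset, classifier=name, k=k, cm=cm)
                evaluations[name].append(ev)
                records.append({
                    "subset": "+".join(ev.feature_names),
                    "subset_indices": ",".join(map(str, subset)),
                    "n_features": len(subset),
                    "classifier": name,
                    "k": k,
                    "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                    "accuracy": ev.accuracy,
                    "sensitivity": ev.sensitivity,
                    "specificity": ev.specificity,
                })
    grid = pd.DataFrame.from_records(records)

    best: dict[str, SubsetEvaluation] = {}
    for name in classifiers:
        winner = select_best(evaluations[name], priority=priority)
        winning_k = tuple(
            ev.k for ev in evaluations[name]
            if ev.subset == winner.subset
            and (ev.accuracy, ev.sensitivity, ev.specificity)
            == (winner.accuracy, winner.sensitivity, winner.specificity)
        )
        best[name] = SubsetEvaluation(
            subset=winner.subset, classifier=name, k=winner.k, cm=winner.cm,
            winning_k=winning_k,
        )
    best_overall = select_best(best.values(), priority=priority)

    rate_rows = []
    for name in classifiers:
        for k in k_values:
            sub = grid[(grid["classifier"] == name) & (grid["k"] == k)]
            rate_rows.append({
                "classifier": name, "k": k,
                "best_accuracy": float(sub["accuracy"].max()),
                "best_sensitivity": float(sub["sensitivity"].max()),
            })
    rate_by_k = pd.DataFrame.from_records(rate_rows)
    return SearchResult(grid=grid, best=best, best_overall=best_overall,
                        rate_by_k=rate_by_k)


class ExhaustiveSubsetSearch(BaseEstimator):
    """Estimator-style wrapper around :func:`full_search`.

    After ``fit(X, y)`` the fitted attributes hold the full grid
    (``grid_``), the per-classifier winners (``best_``) and the overall
    winner (``best_overall_``).
    """

    def __init__(self, classifiers=RULE_NAMES, k_max: int = 10,
                 class_order=None, positive_label=None,
                 priority=("sensitivity", "accuracy")):
        self.classifiers = classifiers
        self.k_max = k_max
        self.class_order = class_order
        self.positive_label = positive_label
        self.priority = priority

    def fit(self, X, y):
        result = full_search(
            X, y, classifiers=self.classifiers, k_max=self.k_max,
            class_order=self.class_order, positive_label=self.positive_label,
            priority=self.priority,
        )
        self.grid_ = result.grid
        self.best_ = result.best
        self.best_overall_ = result.best_overall
        self.rate_by_k_ = result.rate_by_k
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def summary(self) -> pd.DataFrame:
        """One row per classifier: winning subset, k values and rates."""
        rows = []
        for name, ev in self.best_.items():
            rows.append({
                "classifier": name,
                "selected_features": "+".join(ev.feature_names),
                "k": "/".join(map(str, ev.winning_k)),
                "accuracy": ev.accuracy,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
            })
        return pd.DataFrame(rows)
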