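"""LOOCV scoring, subset enumeration, selection and the exhaustive search."""

import numpy as np
import pytest

from fallgrf.evaluation import (
    ConfusionMatrix,
    SubsetEvaluation,
    _loocv_rule_grid,
    enumerate_subsets,
    full_search,
    loocv,
    metrics,
    select_best,
)
from fallgrf.classifiers import make_classifier
from fallgrf.exceptions import FoldError, ParameterError


class TestMetrics:
    def test_formulas_on_backsolved_confusion_matrix(self):
        acc, sens, spec = metrics(ConfusionMatrix(tp=11, fn=3, fp=0, tn=24))
        assert acc == pytest.approx(35 / 38)
        assert sens == pytest.approx(11 / 14)
        assert spec == pytest.approx(1.0)

    def test_perfect_classifier(self):
        acc, sens, spec = metrics(ConfusionMatrix(tp=14, fn=0, fp=0, tn=24))
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_zero_positive_denominator_gives_nan(self):
        acc, sens, spec = metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert np.isnan(sens) and spec == pytest.approx(0.6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=1)

    def test_count_identities(self):
        cm = ConfusionMatrix(tp=5, fn=2, fp=3, tn=7)
        assert cm.n_positive == 7 and cm.n_negative == 10 and cm.n == 17


class TestEnumerateSubsets:
    def test_eight_features_give_255_masks(self):
        masks = enumerate_subsets(8)
        assert len(masks) == 255
        assert len(set(masks)) == 255
        assert all(masks)

    def test_order_is_size_then_lexicographic(self):
        masks = enumerate_subsets(3)
        assert masks == [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]

    def test_single_feature(self):
        assert enumerate_subsets(1) == [(0,)]


class TestLoocv:
    def test_hand_traced_four_subject_folds(self):
        X = np.array([[0.0], [3.0], [4.0], [10.0]])
        y = np.array(["faller", "faller", "nonfaller", "nonfaller"])
        cm = loocv(X, y, classifier="lmknn", k=1, positive_label="faller")
        # fold-by-fold 1-NN: 0->faller, 3->nonfaller(4), 4->faller(3), 10->nonfaller
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_well_separated_groups_classified_perfectly(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0.0, 0.05, (6, 2)),
                       rng.normal(5.0, 0.05, (9, 2))])
        y = np.array(["faller"] * 6 + ["nonfaller"] * 9)
        for clf in ("lmknn", "pnn", "lmpnn"):
            cm = loocv(X, y, classifier=clf, k=2, positive_label="faller")
            assert (cm.tp, cm.tn) == (6, 9) and cm.fn == cm.fp == 0

    def test_permuted_labels_do_not_beat_majority_baseline(self, rng):
        """With labels shuffled there is nothing to learn: held-out accuracy
        must not exceed the majority rate beyond binomial noise."""
        n1, n2 = 12, 8
        X = rng.standard_normal((n1 + n2, 3))
        accs = []
        for _ in range(50):
            y = np.array(["faller"] * n1 + ["nonfaller"] * n2)
            rng.shuffle(y)
            cm = loocv(X, y, classifier="lmpnn", k=3, positive_label="faller")
            accs.append((cm.tp + cm.tn) / cm.n)
        majority = n1 / (n1 + n2)
        noise = np.sqrt(majority * (1 - majority) / (n1 + n2))
        assert np.mean(accs) <= majority + 2 * noise

    def test_singleton_class_fold_raises(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array(["faller", "nonfaller", "nonfaller", "nonfaller"])
        with pytest.raises(FoldError):
            loocv(X, y, classifier="pnn", k=1)

    def test_fast_grid_matches_estimator_route(self, rng):
        """The vectorized all-rules/all-k LOOCV path agrees with the per-fold
        estimator route on random data (decision-level equivalence)."""
        for _ in range(5):
            n = int(rng.integers(8, 16))
            X = rng.standard_normal((n, 3))
            y_codes = rng.integers(0, 2, n)
            while min(np.bincount(y_codes, minlength=2)) < 3:
                y_codes = rng.integers(0, 2, n)
            k_values = [1, 2, 3, 5]
            preds = _loocv_rule_grid(X, y_codes, 2, k_values)
            for ri, rule in enumerate(("lmknn", "pnn", "lmpnn")):
                for ki, k in enumerate(k_values):
                    for i in range(n):
                        mask = np.ones(n, dtype=bool)
                        mask[i] = False
                        est = make_classifier(rule, k=k).fit(
                            X[mask], y_codes[mask])
                        assert est.predict(X[i:i + 1])[0] == preds[ri, ki, i]


class TestSelectBest:
    def _ev(self, subset, sens, acc, spec=1.0, k=1, clf="lmpnn"):
        # build a confusion matrix realizing the requested rates (n=20/20)
        tp = round(sens * 20)
        tn = round(spec * 20)
        cm = ConfusionMatrix(tp=tp, fn=20 - tp, fp=20 - tn, tn=tn)
        ev = SubsetEvaluation(subset=subset, classifier=clf, k=k, cm=cm)
        assert ev.accuracy == pytest.approx(acc, abs=0.03)
        return ev

    def test_sensitivity_outranks_accuracy(self):
        lo_acc = self._ev((0,), sens=0.9, acc=0.95)
        hi_acc = self._ev((1,), sens=0.8, acc=0.9, spec=1.0)
        assert select_best([hi_acc, lo_acc]).subset == (0,)

    def test_smaller_subset_wins_on_metric_tie(self):
        small = self._ev((0, 1, 2, 3), sens=0.9, acc=0.95)
        large = self._ev((0, 1, 2, 3, 4), sens=0.9, acc=0.95)
        assert select_best([large, small]).subset == (0, 1, 2, 3)

    def test_single_candidate_returned(self):
        ev = self._ev((2,), sens=0.5, acc=0.75)
        assert select_best([ev]) is ev

    def test_duplicate_of_winner_does_not_change_selection(self):
        a = self._ev((0,), sens=1.0, acc=1.0)
        b = self._ev((1,), sens=0.9, acc=0.95)
        assert select_best([a, b, a]).subset == (0,)

    def test_nan_metric_ranks_below_defined(self):
        defined = SubsetEvaluation(subset=(0,), classifier="pnn", k=1,
                                   cm=ConfusionMatrix(tp=1, fn=1, fp=0, tn=2))
        undefined = SubsetEvaluation(subset=(1,), classifier="pnn", k=1,
                                     cm=ConfusionMatrix(tp=0, fn=0, fp=1, tn=3))
        assert select_best([undefined, defined]).subset == (0,)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            select_best([])


class TestFullSearch:
    def test_minimal_two_per_class_runs(self, rng):
        X = rng.standard_normal((4, 3))
        y = np.array(["faller", "faller", "nonfaller", "nonfaller"])
        res = full_search(X, y, positive_label="faller")
        assert len(res.grid) == 7 * 3 * 1  # 2^3-1 subsets, 3 rules, k capped at 1
        assert set(res.best) == {"lmknn", "pnn", "lmpnn"}

    def test_single_perfect_feature_recovered(self, rng):
        n = 10
        X = rng.standard_normal((2 * n, 4)) * 0.5
        X[:n, 2] += 10.0  # feature 2 separates the groups perfectly
        y = np.array(["faller"] * n + ["nonfaller"] * n)
        res = full_search(X, y, positive_label="faller")
        for ev in res.best.values():
            assert ev.sensitivity == 1.0 and ev.specificity == 1.0
            assert 2 in ev.subset

    def test_search_is_deterministic(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array(["faller"] * 5 + ["nonfaller"] * 5)
        a = full_search(X, y, positive_label="faller")
        b = full_search(X, y, positive_label="faller")
        assert a.grid.equals(b.grid)
        assert a.best_overall.subset == b.best_overall.subset

    def test_grid_metric_identities(self, rng):
        X = rng.standard_normal((8, 2))
        y = np.array(["faller"] * 4 + ["nonfaller"] * 4)
        res = full_search(X, y, positive_label="faller")
        g = res.grid
        assert ((g.tp + g.fn) == 4).all() and ((g.fp + g.tn) == 4).all()
        np.testing.assert_allclose(
            g.accuracy, (g.tp + g.tn) / 8, atol=1e-12)
        np.testing.assert_allclose(g.sensitivity, g.tp / 4, atol=1e-12)

    def test_winning_k_reports_all_tied_k(self, rng):
        # widely separated clusters: every k wins identically
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 8.0)])
        X += rng.normal(0, 0.01, X.shape)
        y = np.array(["faller"] * 5 + ["nonfaller"] * 5)
        res = full_search(X, y, positive_label="faller", k_values=[1, 2, 3, 4])
        for ev in res.best.values():
            assert ev.winning_k == (1, 2, 3, 4)
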