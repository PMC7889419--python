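"""Fold construction, ROC/AUC, cutoff selection and the permutation null,
each checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scindex
from scindex.errors import DegenerateLabelsError, InvalidParameterError, LeakageError
from scindex.evaluation import EvalReport


def pairwise_auc(scores, labels):
    """Exhaustive concordance: P(random positive > random negative), ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_cutoff(scores, labels):
    """Scan every candidate threshold for max sensitivity + specificity."""
    best = (-1.0, np.inf)
    for t in sorted(set(scores)) + [np.inf]:
        sens = np.mean(scores[labels == 1] >= t)
        spec = np.mean(scores[labels == 0] < t)
        if sens + spec > best[0] + 1e-12:
            best = (sens + spec, t)
    return best[1]


class TestFolds:
    def test_published_fold_sizes_for_100_subjects(self):
        ids = [f"P{i:03d}" for i in range(100)]
        folds = scindex.make_subject_folds(ids, k=5, val_fraction=0.1, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test_subjects) == 20
            assert len(f.train_subjects) == 73
            assert len(f.validation_subjects) == 7

    def test_test_sets_partition_cohort(self):
        ids = [f"P{i}" for i in range(47)]
        folds = scindex.make_subject_folds(ids, k=5, seed=3)
        seen = [s for f in folds for s in f.test_subjects]
        assert sorted(seen) == sorted(ids)
        assert all(f.all_subjects == set(ids) for f in folds)

    def test_within_fold_disjointness_enforced(self):
        with pytest.raises(LeakageError):
            scindex.FoldSplit(0, ("A",), ("A", "B"), ("C",))

    def test_too_many_folds_rejected(self):
        with pytest.raises(InvalidParameterError):
            scindex.make_subject_folds(["A", "B"], k=5)

    def test_seeded_reproducibility(self):
        ids = [f"P{i}" for i in range(30)]
        assert scindex.make_subject_folds(ids, seed=9) == \
            scindex.make_subject_folds(ids, seed=9)


class TestAUC:
    def test_worked_example(self):
        auc, fpr, tpr = scindex.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_perfect_separation(self):
        auc, _, _ = scindex.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_chance_level_for_independent_labels(self):
        rng = np.random.default_rng(0)
        auc, _, _ = scindex.roc_auc(rng.normal(size=20000),
                                    rng.integers(0, 2, 20000))
        assert abs(auc - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            scindex.roc_auc([1.0, 2.0], [1, 1])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.data())
    def test_rank_auc_equals_pairwise_concordance(self, data):
        n = data.draw(st.integers(4, 50))
        scores = np.array(data.draw(st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1),
                                             min_size=n, max_size=n)))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, _, _ = scindex.roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-9)


class TestCutoff:
    def test_separated_example_lowest_tie(self):
        cutoff, sens, spec = scindex.best_fit_cutoff(
            [10, 20, 60, 70], [0, 0, 1, 1])
        assert cutoff == 60  # lowest threshold achieving sens=spec=100%
        assert sens == 100.0 and spec == 100.0

    def test_anti_separated_degenerates_to_extreme_threshold(self):
        cutoff, sens, spec = scindex.best_fit_cutoff(
            [60, 70, 10, 20], [0, 0, 1, 1])
        assert sens + spec == pytest.approx(100.0)

    def test_all_scores_equal_degenerate(self):
        cutoff, sens, spec = scindex.best_fit_cutoff(
            [5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        assert sens + spec == pytest.approx(100.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_scan(self, data):
        n = data.draw(st.integers(4, 40))
        scores = np.array(data.draw(st.lists(
            st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1),
                                             min_size=n, max_size=n)))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        cutoff, sens, spec = scindex.best_fit_cutoff(scores, labels)
        assert cutoff == pytest.approx(brute_force_cutoff(scores, labels))
        s2, p2, _ = scindex.confusion_metrics(scores, labels, cutoff)
        assert (sens, spec) == pytest.approx((s2, p2))


class TestConfusion:
    def test_published_balanced_accuracies(self):
        # (sensitivity + specificity) / 2 worked examples
        assert (68.1 + 73.8) / 2 == pytest.approx(70.95)
        sens, spec = 68.1, 73.8
        scores = np.concatenate([np.ones(681), np.zeros(319),      # positives
                                 np.zeros(738), np.ones(262)])     # negatives
        labels = np.concatenate([np.ones(1000), np.zeros(1000)]).astype(int)
        s, p, ba = scindex.confusion_metrics(scores, labels, cutoff=0.5)
        assert (s, p) == pytest.approx((sens, spec))
        assert ba == pytest.approx(70.95)

    def test_equal_rates_give_that_rate(self):
        scores = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        s, p, ba = scindex.confusion_metrics(scores, labels, 0.5)
        assert s == p == ba == 50.0

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(InvalidParameterError):
            scindex.confusion_metrics([1.0], [1], np.inf)


class TestPermutationNull:
    def test_centred_at_50_under_exchangeability(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=1200)
        labels = rng.integers(0, 2, 1200)
        null = scindex.permutation_null_balanced_accuracy(
            scores, labels, n_perm=100, seed=2)
        assert abs(null.mean - 50.0) < 2 * null.sd / np.sqrt(100) + 0.5
        assert null.sd < 1.5
        assert null.values.size == 100

    def test_refit_rule_never_below_50(self):
        rng = np.random.default_rng(3)
        null = scindex.permutation_null_balanced_accuracy(
            rng.normal(size=200), rng.integers(0, 2, 200),
            n_perm=50, cutoff_rule="refit", seed=4)
        assert null.min >= 50.0
        assert null.mean >= 50.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(InvalidParameterError):
            scindex.permutation_null_balanced_accuracy([1, 2], [0, 1], n_perm=1)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        scores, labels = rng.normal(size=100), rng.integers(0, 2, 100)
        a = scindex.permutation_null_balanced_accuracy(scores, labels, seed=6)
        b = scindex.permutation_null_balanced_accuracy(scores, labels, seed=6)
        np.testing.assert_array_equal(a.values, b.values)


class TestReports:
    def test_balanced_accuracy_invariant_enforced(self):
        with pytest.raises(InvalidParameterError):
            EvalReport(level="patch", auc=0.8, cutoff=50.0, sensitivity=60.0,
                       specificity=80.0, balanced_accuracy=75.0, n_pos=5, n_neg=5)

    def test_crossvalidate_small_cohort(self):
        from conftest import cohort_patch_arrays
        params = scindex.SynthCohortParams(n_subjects=10, duration_s=30.0, seed=13)
        x, y, subjects = cohort_patch_arrays(params)
        result = scindex.crossvalidate(
            x, y, subjects, k=5,
            train_config=scindex.TrainConfig(max_epochs=2, seed=0),
            seed=0, train_patches_per_group=3)
        # every emitted report satisfies the balanced-accuracy identity
        for fold in result.fold_reports:
            for rep in fold.values():
                assert rep.balanced_accuracy == pytest.approx(
                    (rep.sensitivity + rep.specificity) / 2)
        pooled = result.pooled_test_patch
        assert pooled.n_pos == pooled.n_neg == x.shape[0] // 2
        # pooled test scores cover every subject exactly once
        assert set(result.test_subject_ids) == set(subjects)
        assert result.pooled_test_subject.n_pos == 10
        # the separable cohort must score above chance out of sample
        assert pooled.auc > 0.6

    def test_crossvalidate_rejects_folds_not_covering_data(self):
        x = np.zeros((4, 124, 124), dtype=np.float32)
        y = np.array([0, 1, 0, 1])
        subjects = np.array(["A", "A", "B", "B"])
        folds = scindex.make_subject_folds(["A", "B", "C"], k=2)
        with pytest.raises(LeakageError):
            scindex.crossvalidate(x, y, subjects, folds=folds)
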