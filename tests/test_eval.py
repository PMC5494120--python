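import numpy as np
import pytest

from admorph import (
    ConfusionMatrix,
    KernelSpec,
    ValidationError,
    binary_metrics,
    confusion,
    cross_validate,
    fit_svm,
    ova_metrics,
    permutation_test,
)
from admorph.classifiers import make_classifier, register
from admorph.data_io import FeatureTable
from admorph.evaluate import DEFAULT_REPEATS
from admorph.synthetic import CohortSpec, generate_cohort


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion(["a", "b", "c", "a"], ["a", "b", "c", "a"], ["a", "b", "c"])
        np.testing.assert_array_equal(cm.counts,
                                      [[2, 0, 0], [0, 1, 0], [0, 0, 1]])

    def test_binary_cells(self):
        cm = confusion(["S1", "S1", "S2"], ["S1", "S2", "S2"], ["S1", "S2"])
        # TP=1, FN=1, FP=0, TN=1 with first class positive
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_matches_brute_force_tally(self, rng):
        classes = ["x", "y", "z"]
        t = rng.choice(classes, 200)
        p = rng.choice(classes, 200)
        cm = confusion(t, p, classes)
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                expected = sum(1 for a, b in zip(t, p) if a == ci and b == cj)
                assert cm.counts[i, j] == expected

    def test_length_mismatch_and_unknown_label(self):
        with pytest.raises(ValidationError):
            confusion(["a"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValidationError):
            confusion(["a"], ["q"], ["a", "b"])


class TestBinaryMetrics:
    def test_hand_counts(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ("pos", "neg"))
        acc, sen, spe = binary_metrics(cm)
        assert acc == pytest.approx(0.7)
        assert sen == pytest.approx(0.75)
        assert spe == pytest.approx(2 / 3)

    def test_all_correct(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 5]]), ("pos", "neg"))
        assert binary_metrics(cm) == (1.0, 1.0, 1.0)

    def test_no_positives_warns_nan_sensitivity(self):
        cm = ConfusionMatrix(np.array([[0, 0], [1, 9]]), ("pos", "neg"))
        with pytest.warns(UserWarning, match="sensitivity"):
            _, sen, _ = binary_metrics(cm)
        assert np.isnan(sen)

    def test_requires_two_classes(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int), ("a", "b", "c"))
        with pytest.raises(ValidationError):
            binary_metrics(cm)


class TestOvaMetrics:
    def test_binary_symmetry(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ("pos", "neg"))
        acc, msen, mspe = ova_metrics(cm)
        a1, s1, p1 = binary_metrics(cm)
        flipped = ConfusionMatrix(cm.counts[::-1, ::-1], ("neg", "pos"))
        a2, s2, p2 = binary_metrics(flipped)
        assert acc == pytest.approx(a1)
        assert msen == pytest.approx((s1 + s2) / 2)
        assert mspe == pytest.approx((p1 + p2) / 2)

    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(np.diag([4, 5, 6]), ("a", "b", "c"))
        assert ova_metrics(cm) == (1.0, 1.0, 1.0)

    def test_fixed_three_class_matrix_hand_summed(self):
        cm = ConfusionMatrix(np.array([[5, 1, 0], [2, 6, 1], [0, 2, 7]]),
                             ("a", "b", "c"))
        acc, msen, mspe = ova_metrics(cm)
        assert acc == pytest.approx(18 / 24)
        # per-class one-vs-rest collapses done by hand:
        # a: TP=5 FN=1 FP=2 TN=16 -> sen 5/6, spe 16/18
        # b: TP=6 FN=3 FP=3 TN=12 -> sen 6/9, spe 12/15
        # c: TP=7 FN=2 FP=1 TN=14 -> sen 7/9, spe 14/15
        assert msen == pytest.approx((5 / 6 + 6 / 9 + 7 / 9) / 3)
        assert mspe == pytest.approx((16 / 18 + 12 / 15 + 14 / 15) / 3)

    def test_matches_counting_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            K = rng.integers(2, 5)
            counts = rng.integers(0, 30, size=(K, K))
            if counts.sum() == 0:
                counts[0, 0] = 1
            classes = tuple(f"c{i}" for i in range(K))
            cm = ConfusionMatrix(counts, classes)
            acc, msen, mspe = ova_metrics(cm)
            assert acc == pytest.approx(np.trace(counts) / counts.sum())
            sens, spes = [], []
            for i in range(K):
                tp = counts[i, i]
                fn = counts[i].sum() - tp
                fp = counts[:, i].sum() - tp
                tn = counts.sum() - tp - fn - fp
                sens.append(tp / (tp + fn) if tp + fn else np.nan)
                spes.append(tn / (tn + fp) if tn + fp else np.nan)
            assert msen == pytest.approx(np.nanmean(sens), nan_ok=True)
            assert mspe == pytest.approx(np.nanmean(spes), nan_ok=True)


class TestFitSVM:
    def test_separable_blobs_linear(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) - 4,
                       rng.standard_normal((20, 2)) + 4])
        y = ["lo"] * 20 + ["hi"] * 20
        clf = fit_svm(X, y, KernelSpec("linear"))
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_point_per_class_bisector(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        clf = fit_svm(X, ["l", "r"], KernelSpec("linear"))
        # symmetric probes across the perpendicular bisector (the y-axis)
        probes = np.array([[-0.3, 5.0], [0.3, 5.0], [-2.0, -1.0], [2.0, -1.0]])
        pred = clf.predict(probes)
        assert list(pred) == ["l", "r", "l", "r"]

    def test_xor_needs_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.repeat(X, 5, axis=0) + 0.05 * np.random.default_rng(0).standard_normal((20, 2))
        y = ["a"] * 10 + ["b"] * 10
        rbf = fit_svm(X, y, KernelSpec("rbf", 1.0), C_svm=10.0)
        lin = fit_svm(X, y, KernelSpec("linear"), C_svm=10.0)
        assert np.mean(rbf.predict(X) == y) == 1.0
        assert np.mean(lin.predict(X) == y) <= 0.75


class TestCrossValidate:
    def test_loo_fold_count(self, small_cohort):
        r = cross_validate(small_cohort, "svm-linear", scheme="loo", repeats=1,
                           seed=0, pca_config=None)
        assert len(r.per_fold) == small_cohort.n_subjects
        assert all(cm.total == 1 for cm, *_ in r.per_fold)

    def test_kfold_record_count_and_sizes(self, default_cohort):
        r = cross_validate(default_cohort, "svm-linear", scheme="kfold10",
                           repeats=10, seed=1, pca_config={"k": 10})
        assert len(r.per_fold) == 100
        sizes = [cm.total for cm, *_ in r.per_fold]
        assert all(abs(s - 21.4) <= 1.0 for s in sizes)

    def test_default_repeat_counts(self):
        assert DEFAULT_REPEATS == {"split7030": 100, "kfold10": 10, "loo": 10}

    def test_stratified_fold_proportions(self, default_cohort):
        r = cross_validate(default_cohort, "svm-linear", scheme="kfold10",
                           repeats=1, seed=2, pca_config=None)
        y = np.array(default_cohort.labels)
        props = {c: np.mean(y == c) for c in default_cohort.classes}
        for cm, *_ in r.per_fold:
            row_totals = cm.counts.sum(axis=1)
            for i, c in enumerate(default_cohort.classes):
                # within 1 subject of proportional allocation
                assert abs(row_totals[i] - props[c] * cm.total) <= 1.0

    def test_accuracy_equals_trace_over_total(self, small_cohort):
        r = cross_validate(small_cohort, "relm", scheme="kfold10", repeats=1,
                           seed=3, pca_config=None)
        for cm, acc, _, _ in r.per_fold:
            assert acc == pytest.approx(100 * np.trace(cm.counts) / cm.total)

    def test_training_confined_to_training_folds(self, small_cohort):
        # probe classifier records every row it is fitted on; none may come
        # from its own test fold
        seen = []

        class Probe:
            def __init__(self, seed=0, classes=None):
                self.classes = classes

            def fit(self, X, y):
                seen.append(np.asarray(X).copy())
                self._lab = y[0]
                return self

            def predict(self, X):
                return np.array([self._lab] * len(X))

        register("probe", lambda seed=0, classes=None, **p: Probe(seed, classes))
        r = cross_validate(small_cohort, "probe", scheme="kfold10", repeats=1,
                           seed=4, pca_config=None)
        all_rows = {tuple(row) for row in small_cohort.values}
        for fold_X, (cm, *_) in zip(seen, r.per_fold):
            assert len(fold_X) + cm.total == small_cohort.n_subjects
            for row in fold_X:
                assert tuple(row) in all_rows

    def test_single_class_fold_rejected(self):
        t = FeatureTable(("a", "b", "c"), ("NC", "NC", "AD"), ("f",),
                         np.arange(3.0)[:, None])
        with pytest.raises(ValidationError):
            cross_validate(t, "svm-linear", scheme="loo", repeats=1,
                           pca_config=None)

    def test_binary_cohort_uses_binary_metrics(self):
        t = generate_cohort(CohortSpec(n_per_class=(25, 0, 25), effect=2.0,
                                       seed=6))
        r = cross_validate(t, "svm-linear", scheme="kfold10", repeats=1,
                           seed=0, pca_config=None)
        assert len(r.per_fold[0][0].classes) == 2
        assert 0 <= r.mean_sen <= 100 and 0 <= r.mean_spe <= 100


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all_nulls(self, small_cohort):
        res = permutation_test(small_cohort, "svm-linear", scheme="kfold10",
                               n_perm=19, seed=0, repeats=1, pca_config=None)
        # strongly separable cohort: observed should beat every null
        assert all(n < res.observed_stat for n in res.null_stats)
        assert res.p_value == pytest.approx(1 / 20)

    def test_constant_classifier_not_significant(self, small_cohort):
        class Constant:
            def fit(self, X, y):
                self._lab = sorted(set(y))[0]
                return self

            def predict(self, X):
                return np.array([self._lab] * len(X))

        register("constant", lambda seed=0, classes=None, **p: Constant())
        res = permutation_test(small_cohort, "constant", scheme="kfold10",
                               n_perm=19, seed=1, repeats=1, pca_config=None)
        assert res.p_value >= 0.5

    def test_p_value_formula(self, small_cohort):
        res = permutation_test(small_cohort, "svm-linear", scheme="split7030",
                               n_perm=10, seed=2, repeats=1, pca_config=None)
        ge = sum(1 for n in res.null_stats if n >= res.observed_stat)
        assert res.p_value == pytest.approx((1 + ge) / 11)

    def test_invalid_n_perm(self, small_cohort):
        with pytest.raises(ValidationError):
            permutation_test(small_cohort, "svm-linear", n_perm=0)

    def test_p_value_invariant_to_monotone_rescaling(self, small_cohort):
        # p depends only on the rank of the observed statistic in the null
        res = permutation_test(small_cohort, "svm-linear", scheme="split7030",
                               n_perm=15, seed=3, repeats=1, pca_config=None)
        for f in (lambda x: x / 100.0, lambda x: np.sqrt(x + 1.0),
                  lambda x: 3.0 * x - 7.0):
            obs = f(res.observed_stat)
            null = np.array([f(v) for v in res.null_stats])
            p = (1 + np.sum(null >= obs)) / (1 + len(null))
            assert p == pytest.approx(res.p_value)
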