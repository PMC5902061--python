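"""Classifier, fold-scheme and evaluation contracts."""

import numpy as np
import pytest
from scipy import stats

import eegattn as ea

SPEC_KINDS = ("mlp", "knn", "svm")


def clouds(rng, d=6.0, n_per=90, dim=3):
    """Two Gaussian clouds separated by Cohen's d along every axis."""
    x = np.vstack(
        [rng.standard_normal((n_per, dim)) + d / np.sqrt(dim),
         rng.standard_normal((n_per, dim))]
    )
    y = np.array([1] * n_per + [0] * n_per)
    perm = rng.permutation(2 * n_per)
    return x[perm], y[perm]


class TestNormalization:
    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((50, 3)) * 4 + 7
        test = rng.standard_normal((10, 3))
        tr, _ = ea.normalize_features(train, test)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_test_row_at_training_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((50, 3))
        test = train.mean(axis=0, keepdims=True)
        _, te = ea.normalize_features(train, test)
        np.testing.assert_allclose(te, 0.0, atol=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        train = rng.standard_normal((50, 3))
        test = rng.standard_normal((5, 3))
        _, a = ea.normalize_features(train, test)
        _, b = ea.normalize_features(train + 10.0, test + 10.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_variance_column_named(self):
        train = np.random.default_rng(3).standard_normal((20, 2))
        train[:, 1] = 4.0
        with pytest.raises(ValueError, match="PZ"):
            ea.normalize_features(train, train, channel_labels=["CP1", "PZ"])

    def test_transform_parameters_ignore_test_rows(self):
        rng = np.random.default_rng(4)
        train = rng.standard_normal((40, 3))
        t1 = rng.standard_normal((10, 3))
        tr1, _ = ea.normalize_features(train, t1)
        tr2, _ = ea.normalize_features(train, t1 * 100 + 5)
        np.testing.assert_array_equal(tr1, tr2)


class TestFitPredict:
    @pytest.mark.parametrize("kind", SPEC_KINDS)
    def test_separable_clouds_classified_accurately(self, kind):
        rng = np.random.default_rng(10)
        x, y = clouds(rng)
        xt, yt = clouds(np.random.default_rng(11))
        scores = ea.fit_predict(ea.ClassifierSpec(kind=kind), x, y, xt)
        assert np.mean((scores >= 0.5) == yt) >= 0.95
        assert np.all((scores >= 0) & (scores <= 1))

    @pytest.mark.parametrize("kind", SPEC_KINDS)
    def test_permuted_labels_classify_at_chance(self, kind):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = clouds(rng, d=6.0, n_per=45)
            y_perm = rng.permutation(y)
            half = len(y) // 2
            scores = ea.fit_predict(
                ea.ClassifierSpec(kind=kind, seed=seed),
                x[:half], y_perm[:half], x[half:],
            )
            accs.append(np.mean((scores >= 0.5) == y_perm[half:]))
        assert 0.4 <= float(np.mean(accs)) <= 0.6

    def test_knn_identity_neighbour(self):
        x = np.array([[0.0, 0], [5, 5], [9, 0], [0, 9]])
        y = np.array(["target", "distractor", "distractor", "target"], dtype=object)
        scores = ea.fit_predict(ea.ClassifierSpec(kind="knn", k=1), x, y, x[:2])
        assert scores[0] == 1.0 and scores[1] == 0.0

    def test_mlp_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        x, y = clouds(rng, d=1.0)
        s1 = ea.fit_predict(ea.ClassifierSpec(kind="mlp", seed=3), x, y, x[:20])
        s2 = ea.fit_predict(ea.ClassifierSpec(kind="mlp", seed=3), x, y, x[:20])
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_training_rejected(self):
        x = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            ea.fit_predict(ea.ClassifierSpec(kind="knn"), x, np.zeros(10), x)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ea.ClassifierSpec(kind="forest")
        with pytest.raises(ValueError):
            ea.ClassifierSpec(kind="knn", k=4)
        with pytest.raises(ValueError):
            ea.ClassifierSpec(kind="svm", C=-1)


class TestFolds:
    def test_stratified_random_fold_sizes(self):
        labels = np.array(["target", "distractor"] * 90, dtype=object)
        folds = ea.make_folds(labels, np.arange(180), ea.CVScheme(n_folds=10, seed=0))
        for train, test in folds:
            assert test.size == 18
            assert np.sum(labels[test] == "target") == 9

    def test_folds_disjoint_and_covering(self):
        labels = np.array(["target", "distractor"] * 45, dtype=object)
        for kind in ("random_kfold", "time_separated_kfold"):
            folds = ea.make_folds(
                labels, np.arange(90), ea.CVScheme(kind=kind, n_folds=9, seed=1)
            )
            tests = [set(te) for _, te in folds]
            assert set().union(*tests) == set(range(90))
            assert sum(len(t) for t in tests) == 90
            for tr, te in folds:
                assert set(tr) == set(range(90)) - set(te)

    def test_time_separated_assignment_by_rank_mod_k(self):
        # 18 observations of one class with time index 0..17, k = 3:
        # fold 0 tests ranks {0, 3, 6, 9, 12, 15}
        labels = np.array(["target"] * 18 + ["distractor"] * 18, dtype=object)
        time_index = np.arange(36)
        folds = ea.make_folds(
            labels, time_index, ea.CVScheme(kind="time_separated_kfold", n_folds=3)
        )
        test0 = folds[0][1]
        target_ranks = sorted(np.flatnonzero(labels == "target")[np.arange(18) % 3 == 0])
        assert sorted(i for i in test0 if labels[i] == "target") == target_ranks

    def test_excessive_fold_count_rejected(self):
        labels = np.array(["target"] * 5 + ["distractor"] * 50, dtype=object)
        with pytest.raises(ValueError, match="exceeds"):
            ea.make_folds(labels, np.arange(55), ea.CVScheme(n_folds=10))


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # TP=45 FN=5 TN=40 FP=10 -> SN 90%, SP 80%, AC 85%
        y = np.array([1] * 50 + [0] * 50)
        scores = np.concatenate(
            [np.ones(45), np.zeros(5), np.zeros(40), np.ones(10)]
        )
        rep = ea.evaluate(scores, y)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)
        assert rep.accuracy == pytest.approx(0.85)

    def test_perfect_separation(self):
        y = np.array([1] * 10 + [0] * 10)
        scores = np.concatenate([np.linspace(0.6, 1, 10), np.linspace(0, 0.4, 10)])
        rep = ea.evaluate(scores, y)
        assert rep.auc == pytest.approx(1.0)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_random_scores_have_half_auc(self):
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 2000)
        y[:2] = [0, 1]
        rep = ea.evaluate(rng.uniform(size=2000), y)
        assert 0.45 <= rep.auc <= 0.55

    def test_roc_monotone_with_anchored_endpoints(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            y = rng.integers(0, 2, 100)
            y[:2] = [0, 1]
            rep = ea.evaluate(rng.uniform(size=100), y)
            assert tuple(rep.roc[0]) == (0.0, 0.0)
            assert tuple(rep.roc[-1]) == (1.0, 1.0)
            assert np.all(np.diff(rep.roc[:, 0]) >= 0)
            assert np.all(np.diff(rep.roc[:, 1]) >= 0)

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n1, n0 = rng.integers(5, 30, 2)
            y = np.array([1] * n1 + [0] * n0)
            scores = rng.normal(size=n1 + n0)
            rep = ea.evaluate(scores, y)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:]).statistic
            assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ea.evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCompare:
    def test_planted_effect_beats_chance_and_null_does_not(self, epochs_c1, null_epochs):
        scheme = ea.CVScheme(n_folds=5, seed=0)
        specs = [ea.ClassifierSpec(kind="knn")]
        table, pooled = ea.compare_classifiers(epochs_c1, ["delta_power"], scheme, specs)
        assert table["accuracy_mean"].iloc[0] > 0.6
        assert pooled[("delta_power", "knn")].auc > 0.6
        null_table, _ = ea.compare_classifiers(null_epochs, ["delta_power"], scheme, specs)
        assert 0.35 <= null_table["accuracy_mean"].iloc[0] <= 0.65

    def test_report_shape_contract(self, epochs_c1):
        scheme = ea.CVScheme(n_folds=5, seed=0)
        specs = [ea.ClassifierSpec(kind=k) for k in SPEC_KINDS]
        table, pooled = ea.compare_classifiers(
            epochs_c1, ["delta_power", "beta_power"], scheme, specs
        )
        assert len(table) == 6  # 3 classifiers x 2 features
        for col in ("sensitivity", "specificity", "accuracy"):
            assert {f"{col}_mean", f"{col}_sd", f"{col}_max"} <= set(table.columns)
        assert len(pooled) == 6

    def test_cv_schemes_agree_without_drift(self):
        """Random and time-separated k-fold give the same accuracy to
        within 5 points on drift-free data (paired over 10 seeds)."""
        diffs = []
        specs = [ea.ClassifierSpec(kind="knn")]
        for seed in range(10):
            ep = ea.generate_epochset(ea.SyntheticConfig(seed=seed), 1)
            accs = {}
            for kind in ("random_kfold", "time_separated_kfold"):
                scheme = ea.CVScheme(kind=kind, n_folds=5, seed=seed)
                table, _ = ea.compare_classifiers(ep, ["delta_power"], scheme, specs)
                accs[kind] = table["accuracy_mean"].iloc[0]
            diffs.append(accs["random_kfold"] - accs["time_separated_kfold"])
        assert abs(float(np.mean(diffs))) < 0.05

    def test_time_separated_not_optimistic_under_drift(self):
        """With a planted linear amplitude drift, the time-separated
        estimate does not exceed the random-fold estimate by more than
        the no-drift tolerance."""
        diffs = []
        specs = [ea.ClassifierSpec(kind="knn")]
        for seed in range(10):
            cfg = ea.SyntheticConfig(seed=seed, amplitude_drift=0.6)
            ep = ea.generate_epochset(cfg, 1)
            accs = {}
            for kind in ("random_kfold", "time_separated_kfold"):
                scheme = ea.CVScheme(kind=kind, n_folds=5, seed=seed)
                table, _ = ea.compare_classifiers(ep, ["delta_power"], scheme, specs)
                accs[kind] = table["accuracy_mean"].iloc[0]
            diffs.append(accs["time_separated_kfold"] - accs["random_kfold"])
        assert float(np.mean(diffs)) < 0.05
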