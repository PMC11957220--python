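import numpy as np
import pytest

from chaostopo import (
    bfactor_regression,
    classification_metrics,
    crossval_classify,
    rs_scores,
)


class TestClassificationMetrics:
    def test_perfect_diagonal(self):
        m = classification_metrics(np.array([[50, 0], [0, 50]]))
        assert m == {"acc": 1.0, "sen": 1.0, "spec": 1.0, "ba": 1.0}

    def test_worked_contingency_table(self):
        # [[90,10],[30,70]]: ACC .80, class-0 recall .90, class-0
        # specificity .70, BA .80
        m = classification_metrics(np.array([[90, 10], [30, 70]]))
        assert m["acc"] == pytest.approx(0.80)
        assert m["ba"] == pytest.approx(0.80)
        # macro averages: recalls (0.9, 0.7); specificities (0.7, 0.9)
        assert m["sen"] == pytest.approx(0.80)
        assert m["spec"] == pytest.approx(0.80)

    def test_majority_collapse_ba_is_chance(self):
        # everything predicted as the 90-strong class
        m = classification_metrics(np.array([[90, 0], [10, 0]]))
        assert m["acc"] == pytest.approx(0.9)
        assert m["ba"] == pytest.approx(0.5)

    def test_multiclass_hand_computed(self):
        cm = np.array([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
        m = classification_metrics(cm)
        recalls = [8 / 10, 9 / 10, 8 / 10]
        assert m["ba"] == pytest.approx(np.mean(recalls))
        assert m["acc"] == pytest.approx(25 / 30)
        specs = [1 - 2 / 20, 1 - 1 / 20, 1 - 2 / 20]
        assert m["spec"] == pytest.approx(np.mean(specs))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros((0, 0)))

    def test_bruteforce_oracle_random_tables(self, rng):
        # element-by-element recomputation from TP/FP/FN/TN counts
        for _ in range(20):
            k = rng.integers(2, 5)
            cm = rng.integers(0, 40, size=(k, k))
            cm[np.diag_indices(k)] += 1  # avoid empty classes
            m = classification_metrics(cm)
            total = cm.sum()
            accs, sens, specs = 0.0, [], []
            for i in range(k):
                tp = cm[i, i]
                fn = cm[i].sum() - tp
                fp = cm[:, i].sum() - tp
                tn = total - tp - fn - fp
                sens.append(tp / (tp + fn))
                specs.append(tn / (tn + fp))
            assert m["acc"] == pytest.approx(np.trace(cm) / total)
            assert m["sen"] == pytest.approx(np.mean(sens))
            assert m["spec"] == pytest.approx(np.mean(specs))
            assert m["ba"] == pytest.approx(np.mean(sens))


class TestCrossvalClassify:
    def test_one_hot_features_are_perfect(self, rng):
        y = np.repeat([0, 1, 2], 30)
        X = np.eye(3)[y] + 0.01 * rng.normal(size=(90, 3))
        for model in ("knn", "random_forest"):
            rep = crossval_classify(X, y, model, folds=5, seeds=(0, 1))
            agg = rep.aggregate
            assert agg["acc"] == agg["ba"] == 1.0

    def test_constant_features_chance_level(self):
        y = np.repeat([0, 1], 40)
        X = np.ones((80, 3))
        rep = crossval_classify(X, y, "knn", folds=5, seeds=tuple(range(5)))
        assert abs(rep.aggregate["ba"] - 0.5) < 0.12

    def test_fold_assignments_reproducible(self, rng):
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 4))
        r1 = crossval_classify(X, y, "knn", folds=4, seeds=(7,))
        r2 = crossval_classify(X, y, "knn", folds=4, seeds=(7,))
        np.testing.assert_array_equal(r1.fold_assignments[7], r2.fold_assignments[7])
        assert r1.per_fold.equals(r2.per_fold)

    def test_small_class_rejected(self, rng):
        y = np.array([0] * 20 + [1] * 3)
        X = rng.normal(size=(23, 2))
        with pytest.raises(ValueError, match="fewer than"):
            crossval_classify(X, y, "knn", folds=5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            crossval_classify(rng.normal(size=(10, 2)), np.zeros(10), "knn")

    def test_summary_mentions_model_and_metrics(self, rng):
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 2))
        rep = crossval_classify(X, y, "knn", folds=2, seeds=(0,))
        s = rep.summary()
        assert "knn" in s and "ba" in s


class TestBfactorRegression:
    def test_target_in_design_recovers_exactly(self, rng):
        b = rng.uniform(5, 50, size=40)
        X = np.column_stack([rng.normal(size=(40, 3)), b])
        fitted, pcc = bfactor_regression(X, b)
        assert pcc == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fitted, b, atol=1e-8)

    def test_pure_noise_in_sample_pcc_modest(self):
        # in-sample OLS on k noise columns has E[R^2] ~ k/n; with
        # k=3, n=400 the in-sample PCC stays small
        rng = np.random.default_rng(5)
        pccs = []
        for _ in range(20):
            b = rng.normal(size=400)
            X = rng.normal(size=(400, 3))
            _, pcc = bfactor_regression(X, b)
            pccs.append(pcc)
        assert np.mean(pccs) < 0.2

    def test_rank_deficient_warns(self, rng):
        col = rng.normal(size=30)
        X = np.column_stack([col, col, col])
        with pytest.warns(RuntimeWarning, match="rank"):
            bfactor_regression(X, rng.normal(size=30))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            bfactor_regression(rng.normal(size=(10, 2)), np.ones(9))


class TestRSScores:
    def test_collapsed_classes_degenerate_geometry(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 3])
        y = np.array([0] * 5 + [1] * 5)
        rs = rs_scores(X, y)
        np.testing.assert_allclose(rs.similarity, 1.0)
        np.testing.assert_allclose(rs.residue[y == 0], rs.residue[0])
        np.testing.assert_allclose(rs.residue[y == 1], rs.residue[5])

    def test_scores_bounded_random_inputs(self, rng):
        for _ in range(10):
            X = rng.normal(size=(30, 4))
            y = rng.integers(0, 3, size=30)
            if len(np.unique(y)) < 2:
                continue
            rs = rs_scores(X, y)
            assert np.all(rs.residue >= 0) and np.all(rs.residue <= 1)
            assert np.all(rs.similarity >= 0) and np.all(rs.similarity <= 1)

    def test_duplicate_sample_reweights_similarity(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        rs = rs_scores(X, y)
        # append an exact duplicate of sample 0 to class 0
        X2 = np.vstack([X, X[0]])
        y2 = np.append(y, 0)
        rs2 = rs_scores(X2, y2)
        # direct recomputation: mean gains a d=0 term (the duplicate)
        D = np.linalg.norm(X[0] - X[y == 0], axis=1)
        d_max = max(
            np.linalg.norm(X2[i] - X2[j]) for i in range(13) for j in range(13)
        )
        mates = D[1:]  # classmates of sample 0 (self excluded)
        expected = np.mean(1 - np.append(mates, 0.0) / d_max)
        assert rs2.similarity[0] == pytest.approx(expected, abs=1e-12)

    def test_singleton_class_warns(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.warns(RuntimeWarning, match="singleton"):
            rs = rs_scores(X, y)
        assert rs.similarity[4] == 1.0
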