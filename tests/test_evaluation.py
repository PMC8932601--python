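"""Classifier configs, CV plans, confusion matrices and the metric formulas."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, cohen_kappa_score

from anxeeg import (ClassifierConfig, ConfusionMatrix, compute_metrics,
                    confusion_matrix, evaluate, fit_predict_cv, loio_plan,
                    loso_plan, make_classifier)

TABLE_2LEVEL_HAMA = np.array([[1145, 96], [115, 2784]])
TABLE_2LEVEL_SAM = np.array([[2300, 141], [340, 1359]])
TABLE_4LEVEL_HAMA = np.array([[330, 21, 27, 12], [7, 827, 16, 51],
                              [15, 29, 445, 39], [8, 23, 52, 2238]])


def _cm(counts, classes=None):
    k = counts.shape[0]
    classes = classes or tuple(f"c{i}" for i in range(k))
    return ConfusionMatrix(classes=classes, counts=np.asarray(counts))


class TestClassifierConfig:
    @pytest.mark.parametrize("kind,cls_name", [
        ("knn", "KNeighborsClassifier"), ("dt", "DecisionTreeClassifier"),
        ("rf", "RandomForestClassifier"), ("mlp", "MLPClassifier"),
        ("svm", "SVC")])
    def test_kinds(self, kind, cls_name):
        est = make_classifier(ClassifierConfig(kind=kind))
        assert type(est).__name__ == cls_name

    def test_study_defaults(self):
        cfg = ClassifierConfig()
        assert (cfg.knn_k, cfg.dt_max_depth, cfg.rf_n_trees,
                cfg.rf_max_depth) == (5, 32, 500, 32)
        assert cfg.svm_kernel == "rbf" and cfg.mlp_activation == "relu"

    def test_invalid(self):
        with pytest.raises(ValueError):
            make_classifier(ClassifierConfig(kind="xgb"))
        with pytest.raises(ValueError):
            make_classifier(ClassifierConfig(knn_k=0))


class TestCvPlans:
    def test_loio_fold_count_equals_instances(self):
        plan = loio_plan(37)
        assert len(plan.folds) == 37
        assert sorted(np.concatenate(plan.folds).tolist()) == list(range(37))

    def test_loso_one_fold_per_subject(self):
        subs = ["S1"] * 3 + ["S2"] * 2 + ["S3"] * 4
        plan = loso_plan(subs)
        assert len(plan.folds) == 3
        assert {len(f) for f in plan.folds} == {3, 2, 4}

    def test_coverage_validation(self):
        from anxeeg.evaluation import CvPlan
        with pytest.raises(ValueError):
            CvPlan(mode="loio", folds=[np.array([0])], n_instances=2).validate()


class TestFitPredictCv:
    def test_separable_classes_perfect_loocv(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 0.3, (20, 2)),
                            rng.normal(5, 0.3, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        for kind in ("knn", "dt", "svm"):
            preds = fit_predict_cv(X, y, ClassifierConfig(kind=kind),
                                   loio_plan(40))
            assert np.all(preds == y)

    def test_one_nn_memorizes_duplicate_point(self):
        X = np.array([[0.0], [1.0], [0.0], [1.2]])
        y = np.array(["a", "b", "a", "b"])
        preds = fit_predict_cv(X, y, ClassifierConfig(kind="knn", knn_k=1),
                               loio_plan(4))
        assert preds[2] == "a"

    def test_missing_class_in_training_fold_names_fold(self):
        X = np.zeros((4, 1))
        y = np.array(["a", "a", "a", "b"])
        plan = loso_plan(["s1", "s1", "s1", "s2"])
        with pytest.raises(ValueError, match="fold 0"):
            fit_predict_cv(X, y, ClassifierConfig(kind="dt"), plan)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = np.array(["a", "b"] * 30)
        cfg = ClassifierConfig(kind="rf", rf_n_trees=20, seed=5)
        p1 = fit_predict_cv(X, y, cfg, loio_plan(60))
        p2 = fit_predict_cv(X, y, cfg, loio_plan(60))
        assert np.array_equal(p1, p2)

    def test_accuracy_increases_with_class_separation(self):
        rng = np.random.default_rng(2)
        accs = []
        for sep in (0.0, 3.0):
            X = rng.normal(size=(80, 3))
            y01 = rng.integers(0, 2, 80)
            X[:, 0] += sep * y01
            y = np.where(y01 == 1, "a", "b")
            preds = fit_predict_cv(X, y, ClassifierConfig(kind="rf",
                                                          rf_n_trees=30),
                                   loio_plan(80))
            accs.append((preds == y).mean())
        assert accs[1] > accs[0]


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["a", "b", "a", "c"]
        cm = confusion_matrix(y, y, ("a", "b", "c"))
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_printed_table_column_sums_are_class_counts(self):
        cm = _cm(TABLE_2LEVEL_HAMA, ("Light Anxiety", "Severe Anxiety"))
        np.testing.assert_array_equal(cm.true_class_counts(), [1260, 2880])
        cm4 = _cm(TABLE_4LEVEL_HAMA)
        np.testing.assert_array_equal(cm4.true_class_counts(),
                                      [360, 900, 540, 2340])

    def test_single_row_when_one_class_predicted(self):
        cm = confusion_matrix(["a", "b", "b"], ["a", "a", "a"], ("a", "b"))
        assert np.array_equal(cm.counts, [[1, 2], [0, 0]])

    def test_unknown_label_error(self):
        with pytest.raises(ValueError, match="z"):
            confusion_matrix(["a"], ["z"], ("a", "b"))


class TestMetrics:
    def test_two_level_hama_table(self):
        rep = compute_metrics(_cm(TABLE_2LEVEL_HAMA))
        assert rep.accuracy_pct == pytest.approx(100 * 3929 / 4140)
        assert rep.accuracy_pct == pytest.approx(94.90, abs=0.005)
        assert round(rep.kappa, 2) == 0.88
        assert rep.kappa == pytest.approx(0.8791, abs=5e-4)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 3, 500).astype(str)
        p = rng.integers(0, 3, 500).astype(str)
        cm = confusion_matrix(t, p, ("0", "1", "2"))
        rep = compute_metrics(cm)
        assert rep.kappa == pytest.approx(cohen_kappa_score(t, p), abs=1e-12)
        assert rep.accuracy_pct == pytest.approx(
            100 * accuracy_score(t, p), abs=1e-12)

    def test_f_value_fixed_point(self):
        # precision = recall = 0.5 -> F = 0.5
        cm = _cm(np.array([[1, 1], [1, 1]]))
        rep = compute_metrics(cm)
        assert rep.f_value["c0"] == pytest.approx(0.5)

    def test_kappa_identities(self):
        assert compute_metrics(_cm(np.diag([5, 7, 9]))).kappa == 1.0
        # independence: counts proportional to outer(row, col) marginals
        indep = np.outer([30, 70], [40, 60]) // 1
        assert compute_metrics(_cm(indep)).kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_transpose_invariant(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 50, (3, 3))
        a = compute_metrics(_cm(counts)).kappa
        b = compute_metrics(_cm(counts.T)).kappa
        assert a == pytest.approx(b, abs=1e-12)

    def test_accuracy_is_prevalence_weighted_recall(self):
        cm = _cm(TABLE_4LEVEL_HAMA)
        rep = compute_metrics(cm)
        total = cm.total
        acc = sum(rep.recall[c] * cm.true_class_counts()[i] / total
                  for i, c in enumerate(cm.classes))
        assert rep.accuracy_pct == pytest.approx(100 * acc)

    def test_degenerate_class_flagged_zero(self):
        cm = _cm(np.array([[3, 1], [0, 0]]))
        rep = compute_metrics(cm)
        assert rep.precision["c1"] == 0.0
        assert "c1" in rep.degenerate_classes

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            compute_metrics(_cm(np.zeros((2, 2), dtype=int)))


def test_evaluate_wrapper_end_to_end():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    y01 = rng.integers(0, 2, 60)
    X["a"] += 4.0 * y01
    y = np.where(y01 == 1, "hi", "lo")
    cm, rep = evaluate(X, y, ClassifierConfig(kind="dt"), loio_plan(60))
    assert cm.total == 60
    assert rep.feature_vector_length == 3
    assert rep.accuracy_pct > 90
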