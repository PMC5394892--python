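import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from esocad import ClassifierSpec, CvPlan, cross_validate, knn_k_sweep, metrics, train_knn, train_svm, two_stage_cascade


def blobs(rng, n=40, sep=6.0, dim=2):
    y = np.array(["neg"] * n + ["pos"] * n)
    X = rng.normal(size=(2 * n, dim))
    X[n:, 0] += sep
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(dim)]), y


class TestTrainSvm:
    def test_separable_blobs_perfect_training(self, rng):
        X, y = blobs(rng)
        model = train_svm(X, y, ClassifierSpec(kind="svm_rbf", C=1.0, gamma=0.5))
        assert (model.predict(X.to_numpy()) == y).all()

    def test_xor_nonlinear_separability(self, rng):
        X = np.vstack([rng.normal(c, 0.15, size=(25, 2)) for c in [(0, 0), (1, 1), (0, 1), (1, 0)]])
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = train_svm(pd.DataFrame(X), y, ClassifierSpec(kind="svm_rbf", C=100.0, gamma=2.0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_duplication_invariance(self, rng):
        # holds when no dual coefficient sits at the box bound C (duplicating
        # samples is equivalent to doubling C, which only matters at the bound)
        X, y = blobs(rng, n=20)
        spec = ClassifierSpec(kind="svm_rbf", C=10.0, gamma=0.5)
        m1 = train_svm(X, y, spec)
        m2 = train_svm(pd.concat([X, X]), np.concatenate([y, y]), spec)
        probe = rng.normal(size=(30, 2)) * 3
        np.testing.assert_allclose(m1.decision_function(probe), m2.decision_function(probe), atol=1e-6)

    def test_single_class_fold_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            train_svm(X, ["a"] * 10, ClassifierSpec(kind="svm_rbf", C=1.0, gamma=1.0))


class TestTrainKnn:
    def test_query_at_training_point(self, rng):
        X, y = blobs(rng, n=10)
        model = train_knn(X, y, ClassifierSpec(kind="knn", K=1))
        assert model.predict(X.iloc[[0]].to_numpy())[0] == y[0]

    def test_line_vote_hand_enumerated(self):
        # 5 points on a line; query at 1.6 with K=3 -> neighbors at 2, 1, 3 -> b,a,b
        X = pd.DataFrame({"f0": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = np.array(["a", "a", "b", "b", "b"])
        model = train_knn(X, y, ClassifierSpec(kind="knn", K=3))
        scaled_query = np.array([[1.6]])
        assert model.predict(scaled_query)[0] == "b"

    def test_k_exceeding_train_size_rejected(self, rng):
        X, y = blobs(rng, n=5)
        with pytest.raises(ValueError, match="K=15"):
            train_knn(X, y, ClassifierSpec(kind="knn", K=15))

    def test_k_sweep_structure(self, rng):
        X, y = blobs(rng, n=15, sep=4.0)
        sweep = knn_k_sweep(X, y, plan=CvPlan(n_folds=5, seed=0), k_values=(1, 3, 5))
        assert list(sweep["K"]) == [1, 3, 5]
        assert (sweep["accuracy"] > 80).all()

    @pytest.mark.parametrize("bad_k", [0, 4])
    def test_even_or_nonpositive_k_rejected(self, bad_k):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="knn", K=bad_k)


class TestMetrics:
    def test_perfect_confusion(self):
        m = metrics([[50, 0], [0, 50]])
        assert m["accuracy"] == 100.0
        assert m["precision"] == 100.0
        assert m["recall"] == 100.0

    def test_hand_computed_confusion(self):
        m = metrics([[40, 10], [20, 30]])
        assert m["accuracy"] == pytest.approx(70.0)
        assert m["precision_per_class"][0] == pytest.approx(100 * 40 / 60)
        assert m["recall_per_class"][0] == pytest.approx(80.0)

    def test_label_swap_symmetry(self):
        cm = np.array([[40, 10], [20, 30]])
        m1, m2 = metrics(cm), metrics(cm[::-1, ::-1])
        assert m1["accuracy"] == m2["accuracy"]
        assert m1["precision_per_class"] == m2["precision_per_class"][::-1]
        assert m1["recall_per_class"] == m2["recall_per_class"][::-1]

    def test_empty_predicted_class_flagged(self):
        m = metrics([[10, 0], [5, 0]])
        assert m["undefined_precision"] == [1]
        assert m["precision_per_class"][1] == 0.0

    def test_accuracy_equals_complement_of_zero_one_loss(self, rng):
        cm = rng.integers(1, 30, size=(2, 2))
        m = metrics(cm)
        loss = (cm[0, 1] + cm[1, 0]) / cm.sum()
        assert m["accuracy"] == pytest.approx(100 * (1 - loss))


class TestCrossValidate:
    def test_separable_data_perfect_metrics(self, rng):
        X, y = blobs(rng, n=25, sep=10.0)
        report = cross_validate(X, y, ClassifierSpec(kind="knn", K=3), plan=CvPlan(n_folds=5, seed=0))
        assert report["mean"]["accuracy"] == 100.0
        assert report["mean"]["auc"] == 1.0
        assert report["ci95"]["accuracy"] == 0.0

    def test_fold_partition_bookkeeping(self, rng):
        X, y = blobs(rng, n=25)
        plan = CvPlan(n_folds=5, seed=0)
        report = cross_validate(X, y, ClassifierSpec(kind="knn", K=3), plan=plan)
        sizes = [(f["n_train"], f["n_val"]) for f in report["folds"]]
        assert all(tr + va == 50 and va == 10 for tr, va in sizes)

    def test_permuted_labels_chance_auc(self, rng):
        X, _ = blobs(rng, n=30, sep=5.0)
        y_perm = rng.permutation(np.array(["neg"] * 30 + ["pos"] * 30))
        report = cross_validate(X, y_perm, ClassifierSpec(kind="knn", K=5), plan=CvPlan(n_folds=5, seed=0))
        assert 0.35 <= report["mean"]["auc"] <= 0.65

    def test_too_few_samples_per_class_rejected(self, rng):
        X, y = blobs(rng, n=4)
        with pytest.raises(ValueError, match="needs"):
            cross_validate(X, y, ClassifierSpec(kind="knn", K=3), plan=CvPlan(n_folds=10))

    def test_determinism(self, rng):
        X, y = blobs(rng, n=20, sep=2.0)
        r1 = cross_validate(X, y, ClassifierSpec(kind="knn", K=5), plan=CvPlan(n_folds=5, seed=3))
        r2 = cross_validate(X, y, ClassifierSpec(kind="knn", K=5), plan=CvPlan(n_folds=5, seed=3))
        assert r1 == r2


class TestAucInvariance:
    def test_monotone_transform_preserves_auc(self, rng):
        truth = rng.integers(0, 2, 200)
        scores = rng.normal(size=200) + truth
        base = roc_auc_score(truth, scores)
        for transform in (np.exp, lambda s: 3 * s - 7, np.tanh):
            assert roc_auc_score(truth, transform(scores)) == pytest.approx(base)


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(0)
    n = 20
    labels = np.array(["normal"] * n + ["fungating"] * n + ["ulcerative"] * n)
    X = rng.normal(size=(3 * n, 4))
    # one feature carries both boundaries (fungating +8, ulcerative -8)
    # so the greedy wrapper can reach the separable structure in one step
    X[n : 2 * n, 0] += 8.0
    X[2 * n :, 0] -= 8.0
    return pd.DataFrame(X, columns=list("wxyz")), labels


class TestTwoStageCascade:

    def test_report_structure(self, cohort):
        X, labels = cohort
        report = two_stage_cascade(X, labels, ClassifierSpec(kind="knn", K=3), plan=CvPlan(n_folds=5, seed=0))
        assert set(report) == {"stage1", "stage2"}
        assert report["stage1"]["classes"] == ["abnormal", "normal"]
        assert sorted(report["stage2"]["classes"]) == ["fungating", "ulcerative"]

    def test_stage2_excludes_normals(self, cohort):
        X, labels = cohort
        report = two_stage_cascade(X, labels, ClassifierSpec(kind="knn", K=3), plan=CvPlan(n_folds=5, seed=0))
        n_stage2 = sum(f["n_train"] + f["n_val"] for f in report["stage2"]["folds"][:1])
        assert n_stage2 == (labels != "normal").sum()

    def test_unknown_label_rejected(self, cohort):
        X, labels = cohort
        bad = labels.copy()
        bad[0] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            two_stage_cascade(X, bad, ClassifierSpec(kind="knn", K=3))

    def test_sfs_does_not_destroy_separable_structure(self, cohort):
        X, labels = cohort
        spec = ClassifierSpec(kind="knn", K=3)
        plan = CvPlan(n_folds=5, seed=0)
        plain = two_stage_cascade(X, labels, spec, plan=plan, selection="none")
        selected = two_stage_cascade(X, labels, spec, plan=plan, selection="sfs")
        for stage in ("stage1", "stage2"):
            assert selected[stage]["mean"]["accuracy"] >= plain[stage]["mean"]["accuracy"] - 2.0
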