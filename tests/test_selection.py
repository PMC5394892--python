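import numpy as np
import pandas as pd
import pytest

from esocad import ClassifierSpec, pca_fit, pca_transform, sfs
from esocad.classify import wrapper_evaluator


def centroid_distance_criterion(X: pd.DataFrame, y: np.ndarray) -> float:
    """Cheap deterministic subset criterion: within-class scatter over
    between-class centroid distance (lower = better separated)."""
    Z = X.to_numpy(dtype=float)
    classes = np.unique(y)
    centroids = {c: Z[y == c].mean(axis=0) for c in classes}
    within = sum(np.sum((Z[y == c] - centroids[c]) ** 2) for c in classes)
    between = np.sum((centroids[classes[0]] - centroids[classes[1]]) ** 2)
    return within / (between + 1e-12)


def exhaustive_greedy(X, y, evaluator):
    """Independently coded greedy forward search with the same tie rule."""
    selected, trace = [], []
    best = np.inf
    remaining = list(X.columns)
    while remaining:
        scored = [(evaluator(X[selected + [f]], y), i) for i, f in enumerate(remaining)]
        score, idx = min(scored, key=lambda t: (t[0], t[1]))
        if score >= best:
            break
        best = score
        selected.append(remaining.pop(idx))
        trace.append(score)
    return selected, trace


@pytest.fixture
def toy_table(rng):
    n = 40
    y = np.array(["a"] * 20 + ["b"] * 20)
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("pqrstu"))
    X.loc[y == "b", "r"] += 4.0
    X.loc[y == "b", "u"] += 1.0
    return X, y


class TestSfs:
    def test_perfect_single_discriminator_first(self, rng):
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["f0", "f1", "f2"])
        X["f1"] = np.where(y == "b", 10.0, -10.0) + rng.normal(0, 0.1, 20)
        res = sfs(X, y, wrapper_evaluator(ClassifierSpec(kind="knn", K=3), seed=0))
        assert res.selected[0] == "f1"
        assert res.criterion_trace[0] == 0.0

    def test_matches_exhaustive_greedy(self, toy_table):
        X, y = toy_table
        res = sfs(X, y, centroid_distance_criterion, stop="no_improvement")
        selected, trace = exhaustive_greedy(X, y, centroid_distance_criterion)
        assert res.selected == selected
        assert res.criterion_trace == pytest.approx(trace)

    def test_fixed_k_returns_exactly_k(self, toy_table):
        X, y = toy_table
        res = sfs(X, y, centroid_distance_criterion, stop="fixed_k", fixed_k=4)
        assert len(res.selected) == 4
        assert len(set(res.selected)) == 4

    def test_no_improvement_never_worsens(self, toy_table):
        X, y = toy_table
        res = sfs(X, y, centroid_distance_criterion, stop="no_improvement")
        trace = res.criterion_trace
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sfs(pd.DataFrame(), [], centroid_distance_criterion)


class TestPca:
    def test_rank_one_data_single_component(self, rng):
        t = rng.normal(size=50)
        X = pd.DataFrame(np.outer(t, [1.0, -2.0, 0.5, 3.0, 1.5]), columns=list("abcde"))
        model = pca_fit(X, threshold=0.9)
        assert model.k_retained == 1
        assert model.cumulative_variance[0] == pytest.approx(1.0)

    def test_retention_rule_minimality(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 10)) * np.arange(1, 11))
        X.columns = [f"f{i}" for i in range(10)]
        model = pca_fit(X, threshold=0.9)
        k = model.k_retained
        assert model.cumulative_variance[k - 1] >= 0.9
        if k > 1:
            assert model.cumulative_variance[k - 2] < 0.9

    def test_eigendecomposition_matches_brute_force(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 10)), columns=[f"f{i}" for i in range(10)])
        model = pca_fit(X, threshold=1.0)
        Z = (X.to_numpy() - model.center) / model.scale
        cov = np.cov(Z, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.eigenvalues, eigvals, rtol=1e-8)
        # full reconstruction through all components is exact
        scores = Z @ model.eigenvectors.T
        np.testing.assert_allclose(scores @ model.eigenvectors, Z, atol=1e-8)

    def test_training_scores_centered_and_diagonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)])
        model = pca_fit(X, threshold=0.9)
        scores = pca_transform(model, X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(scores.to_numpy(), rowvar=False)
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues[: model.k_retained]), atol=1e-8)

    def test_mean_sample_maps_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        model = pca_fit(X)
        mean_row = pd.DataFrame([X.mean()], columns=X.columns)
        np.testing.assert_allclose(pca_transform(model, mean_row).to_numpy(), 0.0, atol=1e-10)

    def test_schema_mismatch_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        model = pca_fit(X)
        bad = X.rename(columns={"c": "z"})
        with pytest.raises(ValueError, match="missing=\\['c'\\]"):
            pca_transform(model, bad)

    def test_cumulative_variance_monotone(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 7)), columns=[f"f{i}" for i in range(7)])
        model = pca_fit(X)
        assert (np.diff(model.cumulative_variance) >= -1e-12).all()
        assert model.cumulative_variance[-1] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(pd.DataFrame([[1.0, 2.0]], columns=["a", "b"]))
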