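"""Feature selection: wrapper sequential forward selection and PCA.

Two complementary reducers for the 37-column feature table:

* :func:`sfs` — greedy wrapper search. Starting from the empty set, each
  step adds the single feature whose inclusion minimizes a scalar criterion
  (by default the cross-validated misclassification rate of the downstream
  classifier); the search stops when no addition improves the criterion, or
  after a fixed number of features.
* :func:`pca_fit` / :func:`pca_transform` — standardize to zero mean / unit
  variance, eigendecompose the covariance (= correlation) matrix, and retain
  the minimal number of leading components whose cumulative explained
  variance reaches the threshold (default 0.9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = ["SfsResult", "PcaModel", "sfs", "pca_fit", "pca_transform"]


@dataclass
class SfsResult:
    """Outcome of a greedy forward search: features in selection order."""

    selected: list[str]
    criterion_trace: list[float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"selected": self.selected, "criterion_trace": self.criterion_trace}, indent=2)
        )


@dataclass
class PcaModel:
    """Fitted standardize-then-rotate model with the retention rule applied."""

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # rows are components, sorted by eigenvalue desc
    cumulative_variance: np.ndarray
    k_retained: int
    threshold: float

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "cumulative_variance": self.cumulative_variance.tolist(),
            "k_retained": self.k_retained,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def sfs(
    X: pd.DataFrame,
    y: Sequence,
    evaluator: Callable[[pd.DataFrame, np.ndarray], float],
    stop: str = "no_improvement",
    fixed_k: int | None = None,
) -> SfsResult:
    """Greedy forward feature selection minimizing ``evaluator``.

    Parameters
    ----------
    X
        Feature table (columns are candidate features).
    y
        Class labels, one per row.
    evaluator
        Maps a candidate column subset (and labels) to a scalar criterion;
        lower is better.
    stop
        ``"no_improvement"`` stops when the best candidate addition fails to
        strictly improve the criterion; ``"fixed_k"`` always selects exactly
        ``fixed_k`` features.

    Ties between candidate features are broken toward the lowest column
    index, so the greedy trace is deterministic.
    """
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("feature table is empty")
    if stop not in ("no_improvement", "fixed_k"):
        raise ValueError(f"unknown stop rule {stop!r}")
    if stop == "fixed_k":
        if fixed_k is None or not (1 <= fixed_k <= X.shape[1]):
            raise ValueError(f"fixed_k must be in [1, {X.shape[1]}], got {fixed_k}")
    y = np.asarray(y)

    selected: list[str] = []
    trace: list[float] = []
    best = np.inf
    remaining = list(X.columns)
    max_k = fixed_k if stop == "fixed_k" else X.shape[1]
    while remaining and len(selected) < max_k:
        scores = [evaluator(X[selected + [name]], y) for name in remaining]
        idx = int(np.argmin(scores))  # argmin keeps the lowest index on ties
        cand_best = scores[idx]
        if stop == "no_improvement" and cand_best >= best:
            break
        best = cand_best if cand_best < best else best
        selected.append(remaining.pop(idx))
        trace.append(cand_best)
    return SfsResult(selected=selected, criterion_trace=trace)


def pca_fit(X: pd.DataFrame, threshold: float = 0.9) -> PcaModel:
    """Standardize, eigendecompose, and apply the cumulative-variance rule.

    Zero-variance columns cannot be standardized and are dropped with a
    logged warning. ``k_retained`` is the smallest k whose leading
    components explain at least ``threshold`` of the total variance. Each
    eigenvector's largest-magnitude entry is made positive so serialized
    models are reproducible across runs.
    """
    if X.shape[0] < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {X.shape[0]}")
    variances = X.var(axis=0, ddof=0)
    keep = variances > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        logger.warning("dropping zero-variance features before PCA: %s", dropped)
        X = X.loc[:, keep]
    scaler = StandardScaler().fit(X.to_numpy(dtype=float))
    Z = scaler.transform(X.to_numpy(dtype=float))
    pca = PCA(n_components=min(X.shape)).fit(Z)

    vectors = pca.components_.copy()
    # sign convention: dominant loading positive
    for row in vectors:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0

    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    k_retained = int(np.searchsorted(cumulative, threshold) + 1)
    k_retained = min(k_retained, len(cumulative))
    return PcaModel(
        feature_names=list(X.columns),
        center=scaler.mean_,
        scale=scaler.scale_,
        eigenvalues=pca.explained_variance_,
        eigenvectors=vectors,
        cumulative_variance=cumulative,
        k_retained=k_retained,
        threshold=threshold,
    )


def pca_transform(model: PcaModel, X: pd.DataFrame) -> pd.DataFrame:
    """Project a feature table onto the retained principal components.

    The table must contain exactly the features the model was fitted on
    (extra or missing columns raise, naming the offenders); column order is
    realigned automatically.
    """
    missing = [c for c in model.feature_names if c not in X.columns]
    extra = [c for c in X.columns if c not in model.feature_names]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing}, extra={extra}")
    Z = (X[model.feature_names].to_numpy(dtype=float) - model.center) / model.scale
    scores = Z @ model.eigenvectors[: model.k_retained].T
    cols = [f"PC{i + 1}" for i in range(model.k_retained)]
    return pd.DataFrame(scores, columns=cols, index=X.index)
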