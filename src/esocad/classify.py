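"""Classifier training and cross-validated evaluation.

Two classifiers are supported: an RBF-kernel support vector machine and a
K-nearest-neighbors voter with Euclidean distance. Evaluation follows the
two-stage cascade protocol: stage 1 separates normal from abnormal images,
stage 2 separates the abnormal subset into fungating and ulcerative types.
Each stage runs stratified 10-fold cross-validation (90% train / 10%
validation per fold) and reports AUC, accuracy, precision and recall with
95% Student-t confidence intervals over the fold values.

Feature selection (SFS or PCA), when requested, is fitted on each training
partition only, so no validation information leaks into the selected
subspace; ``global_selection=True`` instead fits selection once on the full
table before the folds are formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import pca_fit, pca_transform, sfs

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CvPlan",
    "train_svm",
    "train_knn",
    "train_classifier",
    "metrics",
    "cross_validate",
    "knn_k_sweep",
    "two_stage_cascade",
    "wrapper_evaluator",
]

SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA_GRID = tuple(2.0**p for p in range(-4, 3))


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier.

    ``C``/``gamma`` left as ``None`` triggers a nested 5-fold grid search on
    each training partition (the values are never printed in stone for this
    problem, so they are re-tuned per fold by default). ``K`` must be odd so
    binary votes cannot tie.
    """

    kind: str = "svm_rbf"  # or "knn"
    C: float | None = None
    gamma: float | None = None
    K: int = 15
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kind == "knn" and (self.K < 1 or self.K % 2 == 0):
            raise ValueError(f"K must be an odd positive integer, got {self.K}")
        if self.distance != "euclidean":
            raise ValueError(f"only euclidean distance is supported, got {self.distance!r}")


@dataclass(frozen=True)
class CvPlan:
    """Cross-validation layout: stratified folds with a fixed shuffle seed."""

    n_folds: int = 10
    seed: int = 0
    stratified: bool = True


def _check_binary(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"degenerate training fold: single class {classes!r}")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {classes!r}")
    return classes


def train_svm(X: pd.DataFrame | np.ndarray, y: Sequence, spec: ClassifierSpec, seed: int = 0) -> Pipeline:
    """Fit a standardize + RBF-SVM pipeline.

    With unspecified hyperparameters, ``C`` and ``gamma`` are chosen by an
    internal stratified 5-fold grid search on the training data.
    """
    if spec.kind != "svm_rbf":
        raise ValueError(f"train_svm called with spec.kind={spec.kind!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_binary(y)
    if spec.C is not None and spec.gamma is not None:
        model = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=spec.C, gamma=spec.gamma))]
        )
        return model.fit(X, y)
    inner = StratifiedKFold(n_splits=min(5, int(np.bincount(pd.factorize(y)[0]).min())), shuffle=True, random_state=seed)
    search = GridSearchCV(
        Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))]),
        param_grid={
            "svc__C": list(SVM_C_GRID) if spec.C is None else [spec.C],
            "svc__gamma": list(SVM_GAMMA_GRID) if spec.gamma is None else [spec.gamma],
        },
        cv=inner,
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def train_knn(X: pd.DataFrame | np.ndarray, y: Sequence, spec: ClassifierSpec, seed: int = 0) -> Pipeline:
    """Fit a standardize + K-nearest-neighbors pipeline (majority vote).

    The decision score for ROC analysis is the fraction of the K Euclidean
    neighbors belonging to the positive class.
    """
    if spec.kind != "knn":
        raise ValueError(f"train_knn called with spec.kind={spec.kind!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_binary(y)
    if spec.K > len(y):
        raise ValueError(f"K={spec.K} exceeds the {len(y)} training samples")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=spec.K, metric="euclidean")),
        ]
    )
    return model.fit(X, y)


def train_classifier(X, y, spec: ClassifierSpec, seed: int = 0) -> Pipeline:
    if spec.kind == "svm_rbf":
        return train_svm(X, y, spec, seed=seed)
    return train_knn(X, y, spec, seed=seed)


def decision_scores(model: Pipeline, X, pos_label) -> np.ndarray:
    """Real-valued score increasing with confidence in ``pos_label``."""
    X = np.asarray(X, dtype=float)
    if hasattr(model[-1], "decision_function"):
        raw = model.decision_function(X)
        return raw if model.classes_[1] == pos_label else -raw
    proba = model.predict_proba(X)
    col = int(np.where(model.classes_ == pos_label)[0][0])
    return proba[:, col]


def metrics(confusion: np.ndarray | Sequence[Sequence[int]]) -> dict:
    """Accuracy, per-class and macro precision/recall from a 2x2 confusion matrix.

    Convention: ``confusion[i, j]`` counts samples of true class ``i``
    predicted as class ``j``. All values are percentages. A class never
    predicted has undefined precision, reported as 0 with
    ``undefined_precision`` flagging the class index.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("expected a non-negative 2x2 confusion matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * np.trace(cm) / total
    precision, recall, undefined = [], [], []
    for c in (0, 1):
        pred_c = cm[:, c].sum()
        true_c = cm[c, :].sum()
        if pred_c == 0:
            undefined.append(c)
            precision.append(0.0)
        else:
            precision.append(100.0 * cm[c, c] / pred_c)
        recall.append(100.0 * cm[c, c] / true_c if true_c > 0 else 0.0)
    return {
        "accuracy": float(accuracy),
        "precision_per_class": [float(p) for p in precision],
        "recall_per_class": [float(r) for r in recall],
        "precision": float(np.mean(precision)),
        "recall": float(np.mean(recall)),
        "undefined_precision": undefined,
    }


def _t_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    """Half-width of the Student-t confidence interval over fold values."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return 0.0
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n))


def _fit_fold_selection(
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    X_va: pd.DataFrame,
    selection: str,
    spec: ClassifierSpec,
    seed: int,
    sfs_stop: str,
    sfs_fixed_k: int | None,
    pca_threshold: float,
):
    """Fit the requested reducer on the training part and apply to both parts."""
    if selection == "none":
        return X_tr, X_va, None
    if selection == "sfs":
        result = sfs(X_tr, y_tr, wrapper_evaluator(spec, seed=seed), stop=sfs_stop, fixed_k=sfs_fixed_k)
        return X_tr[result.selected], X_va[result.selected], result
    if selection == "pca":
        model = pca_fit(X_tr, threshold=pca_threshold)
        return pca_transform(model, X_tr), pca_transform(model, X_va), model
    raise ValueError(f"unknown selection mode {selection!r}")


def wrapper_evaluator(spec: ClassifierSpec, n_splits: int = 5, seed: int = 0):
    """SFS criterion: cross-validated misclassification rate of the classifier.

    The mean 0/1 error equals the mean squared error of one-hot class
    predictions, computed under internal stratified CV on the training
    partition. The SVM is evaluated at fixed mid-grid hyperparameters here
    (C=1, gamma=1/p) to keep the wrapper search tractable; the final
    per-fold model is still tuned after selection.
    """
    if spec.kind == "svm_rbf":
        eval_spec = replace(spec, C=spec.C or 1.0, gamma=spec.gamma)

        def make_model(n_features):
            g = eval_spec.gamma if eval_spec.gamma is not None else 1.0 / max(n_features, 1)
            return Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=eval_spec.C, gamma=g))])
    else:

        def make_model(n_features, _spec=spec):
            return Pipeline(
                [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=_spec.K, metric="euclidean"))]
            )

    def evaluate(X: pd.DataFrame, y: np.ndarray) -> float:
        y = np.asarray(y)
        counts = np.bincount(pd.factorize(y)[0])
        splits = min(n_splits, int(counts.min()))
        if splits < 2:
            raise ValueError("need at least 2 samples per class for the wrapper criterion")
        skf = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        errors = []
        Xa = X.to_numpy(dtype=float)
        for tr, va in skf.split(Xa, y):
            model = make_model(X.shape[1])
            if "knn" in model.named_steps and model.named_steps["knn"].n_neighbors > len(tr):
                model.set_params(knn__n_neighbors=len(tr) if len(tr) % 2 else len(tr) - 1)
            model.fit(Xa[tr], y[tr])
            errors.append(np.mean(model.predict(Xa[va]) != y[va]))
        return float(np.mean(errors))

    return evaluate


def cross_validate(
    X: pd.DataFrame,
    y: Sequence,
    spec: ClassifierSpec,
    plan: CvPlan = CvPlan(),
    selection: str = "none",
    pos_label=None,
    sfs_stop: str = "no_improvement",
    sfs_fixed_k: int | None = None,
    pca_threshold: float = 0.9,
    global_selection: bool = False,
) -> dict:
    """Stratified k-fold evaluation of one binary problem.

    Returns a report dict with fold-wise AUC / accuracy / precision /
    recall, their means and 95% CI half-widths, the pooled-score AUC and
    ROC points, and the aggregate confusion matrix.
    """
    y = np.asarray(y)
    classes = _check_binary(y)
    if pos_label is None:
        pos_label = classes[1]
    counts = {c: int((y == c).sum()) for c in classes}
    if plan.stratified and min(counts.values()) < plan.n_folds:
        raise ValueError(
            f"stratified {plan.n_folds}-fold CV needs >= {plan.n_folds} samples per class, got {counts}"
        )
    if global_selection and selection != "none":
        X_sel, _, sel_obj = _fit_fold_selection(
            X, y, X.iloc[:0], selection, spec, plan.seed, sfs_stop, sfs_fixed_k, pca_threshold
        )
        X = X_sel
        selection_for_folds = "none"
    else:
        sel_obj = None
        selection_for_folds = selection

    skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    fold_rows = []
    pooled_scores, pooled_truth = [], []
    cm_total = np.zeros((2, 2), dtype=int)
    label_order = list(classes)
    selections = []
    for fold_id, (tr, va) in enumerate(skf.split(X.to_numpy(dtype=float), y)):
        X_tr, X_va = X.iloc[tr], X.iloc[va]
        y_tr, y_va = y[tr], y[va]
        X_tr_s, X_va_s, fold_sel = _fit_fold_selection(
            X_tr, y_tr, X_va, selection_for_folds, spec, plan.seed, sfs_stop, sfs_fixed_k, pca_threshold
        )
        if fold_sel is not None:
            selections.append(fold_sel)
        model = train_classifier(X_tr_s, y_tr, spec, seed=plan.seed)
        pred = model.predict(np.asarray(X_va_s, dtype=float))
        score = decision_scores(model, X_va_s, pos_label)
        cm = confusion_matrix(y_va, pred, labels=label_order)
        cm_total += cm
        fold_metrics = metrics(cm)
        both_present = len(np.unique(y_va)) == 2
        auc = float(roc_auc_score((y_va == pos_label).astype(int), score)) if both_present else np.nan
        fold_rows.append(
            {
                "fold": fold_id,
                "n_train": int(len(tr)),
                "n_val": int(len(va)),
                "auc": auc,
                "accuracy": fold_metrics["accuracy"],
                "precision": fold_metrics["precision"],
                "recall": fold_metrics["recall"],
            }
        )
        pooled_scores.append(score)
        pooled_truth.append((y_va == pos_label).astype(int))

    folds = pd.DataFrame(fold_rows)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_truth = np.concatenate(pooled_truth)
    fpr, tpr, _ = roc_curve(pooled_truth, pooled_scores)
    report = {
        "classifier": spec.kind,
        "selection": selection,
        "n_folds": plan.n_folds,
        "classes": [str(c) for c in label_order],
        "pos_label": str(pos_label),
        "folds": fold_rows,
        "mean": {m: float(np.nanmean(folds[m])) for m in ("auc", "accuracy", "precision", "recall")},
        "ci95": {m: _t_halfwidth(folds[m].dropna().to_numpy()) for m in ("auc", "accuracy", "precision", "recall")},
        "pooled_auc": float(roc_auc_score(pooled_truth, pooled_scores)),
        "roc_points": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "confusion": cm_total.tolist(),
    }
    if selection == "sfs" and selections:
        report["selected_features"] = [s.selected for s in selections]
    if selection == "pca" and selections:
        report["k_retained"] = [s.k_retained for s in selections]
    if global_selection and sel_obj is not None:
        if selection == "sfs":
            report["selected_features"] = [sel_obj.selected]
        else:
            report["k_retained"] = [sel_obj.k_retained]
    return report


def knn_k_sweep(
    X: pd.DataFrame,
    y: Sequence,
    plan: CvPlan = CvPlan(),
    k_values: Sequence[int] = tuple(range(1, 22, 2)),
) -> pd.DataFrame:
    """Mean CV accuracy of KNN for each neighbor count K.

    Sweeps odd K from 1 to 21 by default and returns a table of
    (K, mean_accuracy, ci95) so the best K can be located empirically.
    """
    rows = []
    for k in k_values:
        report = cross_validate(X, y, ClassifierSpec(kind="knn", K=k), plan=plan, selection="none")
        rows.append({"K": k, "accuracy": report["mean"]["accuracy"], "ci95": report["ci95"]["accuracy"]})
    return pd.DataFrame(rows)


def two_stage_cascade(
    X: pd.DataFrame,
    labels: Sequence,
    spec: ClassifierSpec,
    plan: CvPlan = CvPlan(),
    selection: str = "none",
    normal_label: str = "normal",
    stage2_labels: tuple[str, str] = ("fungating", "ulcerative"),
    **kwargs,
) -> dict:
    """Evaluate the two-stage protocol on a three-class feature table.

    Stage 1: all samples, ``normal`` versus the pooled abnormal classes.
    Stage 2: abnormal samples only, first versus second abnormal type.
    Both stages use the same CV plan and selection mode and are reported
    independently.
    """
    labels = np.asarray(labels, dtype=object)
    known = {normal_label, *stage2_labels}
    unknown = set(labels) - known
    if unknown:
        raise ValueError(f"unexpected labels {sorted(unknown)}; expected {sorted(known)}")

    y_stage1 = np.where(labels == normal_label, "normal", "abnormal")
    stage1 = cross_validate(X, y_stage1, spec, plan=plan, selection=selection, pos_label="abnormal", **kwargs)

    mask = labels != normal_label
    if mask.sum() == 0:
        raise ValueError("no abnormal samples for stage 2")
    stage2 = cross_validate(
        X.loc[mask].reset_index(drop=True),
        labels[mask],
        spec,
        plan=plan,
        selection=selection,
        pos_label=stage2_labels[1],
        **kwargs,
    )
    return {"stage1": stage1, "stage2": stage2}
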