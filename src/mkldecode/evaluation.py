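"""Nested cross-validation, performance metrics and permutation inference.

Folding is always at the subject level (both condition images of a
subject stay on the same side of every split) under one of two schemes:
leave-one-subject-out (LOSO) or k-fold with k = 10.  Hyperparameters are
selected by an inner cross-validation that mirrors the outer scheme on
the outer-training subjects only; kernel centring/normalisation
statistics and regression target means are likewise computed from
training data only, so held-out subjects never leak into model fitting.

Test predictions are pooled across outer folds before computing metrics
(per-class accuracy, balanced accuracy, ROC/AUC for classification;
Pearson r, R^2 = r^2, MSE for regression), which makes every LOSO
accuracy an integer multiple of 100/n_subjects.  Significance comes from
permutation tests: the full pipeline is re-run with permuted labels and
p = (1 + #{permuted metric at least as good}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .kernels import KernelSet, process_kernelset
from .mkl import MKLModel, predict, train_mkl

__all__ = [
    "FoldPlan",
    "CVReport",
    "PermutationReport",
    "make_fold_plan",
    "run_nested_cv",
    "classification_metrics",
    "regression_metrics",
    "permutation_test",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

#: metrics where smaller permuted values count as "at least as good"
LOWER_IS_BETTER = {"mse"}


@dataclass
class FoldPlan:
    """Subject-level cross-validation folds with nested inner plans."""

    scheme: str                                  # "loso" | "kfold"
    folds: list[tuple[list[str], list[str]]]     # (train_ids, test_ids)
    inner: list["FoldPlan | None"] = field(default_factory=list)

    def __post_init__(self) -> None:
        all_test = [s for _, te in self.folds for s in te]
        if len(all_test) != len(set(all_test)):
            raise ValueError("outer test sets overlap")
        for (tr, te), inner in zip(self.folds, self.inner or [None] * len(self.folds)):
            if set(tr) & set(te):
                raise ValueError("train and test subjects overlap")
            if inner is not None:
                inner_subjects = {s for f in inner.folds for s in f[0] + f[1]}
                if inner_subjects - set(tr):
                    raise ValueError("inner folds touch outer test subjects")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_fold_plan(subject_ids: list[str], scheme: str = "loso",
                   k: int = 10, seed: int = 0, nested: bool = True) -> FoldPlan:
    """Build a (nested) subject-level fold plan.

    LOSO yields one fold per subject; k-fold shuffles subjects with the
    seed and splits them into k groups whose sizes differ by at most
    one.  With ``nested`` each outer fold carries an inner plan of the
    same scheme over its training subjects.
    """
    subjects = list(subject_ids)
    if scheme == "loso":
        if len(subjects) < 3:
            raise ValueError("LOSO needs at least 3 subjects")
        groups = [[s] for s in subjects]
    elif scheme == "kfold":
        if len(subjects) < k:
            raise ValueError(f"k-fold needs at least k={k} subjects")
        rng = np.random.default_rng(seed)
        shuffled = [subjects[i] for i in rng.permutation(len(subjects))]
        groups = [list(g) for g in np.array_split(np.array(shuffled), k)]
    else:
        raise ValueError("scheme must be 'loso' or 'kfold'")
    folds = [([s for s in subjects if s not in set(te)], list(te))
             for te in groups]
    inner: list[FoldPlan | None] = []
    for i, (tr, _) in enumerate(folds):
        if nested:
            inner_k = min(k, len(tr)) if scheme == "kfold" else k
            inner.append(make_fold_plan(tr, scheme, k=inner_k,
                                        seed=seed * 1000 + i + 1, nested=False))
        else:
            inner.append(None)
    return FoldPlan(scheme=scheme, folds=folds, inner=inner)


@dataclass
class CVReport:
    """Pooled predictions, metrics and per-fold models of one CV run."""

    task: str
    predictions: pd.DataFrame     # subject, fold, y_true, y_pred
    metrics: dict[str, float]
    chosen_C: list[float]
    fold_weights: pd.DataFrame    # index region_id, one column per fold
    models: list[MKLModel]
    roc: tuple[np.ndarray, np.ndarray] | None = None

    def recompute_metrics(self) -> dict[str, float]:
        y = self.predictions["y_true"].to_numpy()
        f = self.predictions["y_pred"].to_numpy()
        if self.task == "classification":
            return classification_metrics(y, f)[0]
        return regression_metrics(y, f)


def _rows_for(subjects_per_sample: np.ndarray, subject_set: list[str]) -> np.ndarray:
    return np.flatnonzero(np.isin(subjects_per_sample, subject_set))


def _slice_kernelset(ks: KernelSet, rows: np.ndarray) -> KernelSet:
    return KernelSet(
        region_ids=list(ks.region_ids),
        matrices=[K[np.ix_(rows, rows)] for K in ks.matrices],
        sample_subjects=[ks.sample_subjects[i] for i in rows],
        sample_conditions=[ks.sample_conditions[i] for i in rows],
        centered=ks.centered, normalized=ks.normalized,
        training_rows=np.arange(len(rows)))


def _fit_and_score(raw: KernelSet, y: np.ndarray, task: str,
                   train_rows: np.ndarray, test_rows: np.ndarray,
                   C: float, **mkl_kwargs) -> tuple[np.ndarray, MKLModel]:
    """Process kernels on train rows, fit, return test predictions."""
    processed = process_kernelset(raw, train_rows)
    model = train_mkl(_slice_kernelset(processed, train_rows), y[train_rows],
                      task, C=C, **mkl_kwargs)
    id_to_mat = dict(zip(processed.region_ids, processed.matrices))
    blocks = [id_to_mat[rid][np.ix_(test_rows, train_rows)]
              for rid in model.region_ids]
    return predict(model, blocks), model


def run_nested_cv(kernels: KernelSet, targets: np.ndarray, task: str,
                  plan: FoldPlan, C_grid: tuple[float, ...] = DEFAULT_C_GRID,
                  fixed_C: float | None = None, **mkl_kwargs) -> CVReport:
    """Nested cross-validation over a raw (unprocessed) kernel set.

    Per outer fold: the inner plan scores every C on pooled inner-fold
    predictions (balanced accuracy for classification, MSE for
    regression; ties go to the smallest C), the model is refit on the
    full outer-training set with the winner, and test predictions are
    pooled across folds.  ``fixed_C`` skips the inner loop (fast mode
    for permutations).  All kernel statistics come from training rows
    of the split at hand.
    """
    y = np.asarray(targets, dtype=float)
    subjects = np.array(kernels.sample_subjects)
    if len(y) != len(subjects):
        raise ValueError("targets length does not match kernel sample count")
    records = []
    chosen: list[float] = []
    models: list[MKLModel] = []
    for fold_i, (train_subj, test_subj) in enumerate(plan.folds):
        train_rows = _rows_for(subjects, train_subj)
        test_rows = _rows_for(subjects, test_subj)
        if fixed_C is not None:
            C_sel = fixed_C
        else:
            inner = plan.inner[fold_i]
            if inner is None:
                raise ValueError("nested CV requires inner fold plans "
                                 "(or pass fixed_C)")
            C_sel = _select_C(kernels, y, task, subjects, inner, C_grid,
                              **mkl_kwargs)
        preds, model = _fit_and_score(kernels, y, task, train_rows, test_rows,
                                      C_sel, **mkl_kwargs)
        chosen.append(C_sel)
        models.append(model)
        for row, p in zip(test_rows, preds):
            records.append({"subject": subjects[row], "fold": fold_i,
                            "y_true": y[row], "y_pred": p})
    pred_df = pd.DataFrame(records)
    roc = None
    if task == "classification":
        metrics, roc = classification_metrics(pred_df["y_true"].to_numpy(),
                                              pred_df["y_pred"].to_numpy())
    else:
        metrics = regression_metrics(pred_df["y_true"].to_numpy(),
                                     pred_df["y_pred"].to_numpy())
    weights = pd.DataFrame(
        {f"fold_{i}": pd.Series(dict(zip(m.region_ids, m.kernel_weights)))
         for i, m in enumerate(models)}).fillna(0.0)
    weights.index.name = "region_id"
    return CVReport(task=task, predictions=pred_df, metrics=metrics,
                    chosen_C=chosen, fold_weights=weights, models=models,
                    roc=roc)


def _select_C(raw: KernelSet, y: np.ndarray, task: str,
              subjects: np.ndarray, inner: FoldPlan,
              C_grid: tuple[float, ...], **mkl_kwargs) -> float:
    """Pooled inner-CV score per C; best score, ties to the smallest C."""
    pooled: dict[float, list[tuple[float, float]]] = {C: [] for C in C_grid}
    for itrain_subj, itest_subj in inner.folds:
        itrain = _rows_for(subjects, itrain_subj)
        itest = _rows_for(subjects, itest_subj)
        if task == "classification" and len(np.unique(y[itrain])) < 2:
            warnings.warn("inner fold skipped: single-class training labels",
                          stacklevel=2)
            continue
        for C in C_grid:
            preds, _ = _fit_and_score(raw, y, task, itrain, itest, C,
                                      **mkl_kwargs)
            pooled[C].extend(zip(y[itest], preds))
    scores: dict[float, float] = {}
    for C, pairs in pooled.items():
        if not pairs:
            raise ValueError("no usable inner folds for hyperparameter search")
        yt = np.array([p[0] for p in pairs])
        yp = np.array([p[1] for p in pairs])
        if task == "classification":
            scores[C] = classification_metrics(yt, yp)[0]["balanced_accuracy"]
        else:
            scores[C] = -float(np.mean((yt - yp) ** 2))
    best = max(scores.values())
    return min(C for C, s in scores.items() if s == best)


def classification_metrics(y_true: np.ndarray, decision_values: np.ndarray
                           ) -> tuple[dict[str, float],
                                      tuple[np.ndarray, np.ndarray]]:
    """Pooled per-class accuracies (percent), balanced accuracy and AUC.

    Class 1 is the positive label (+1), class 2 the negative (-1);
    balanced accuracy is the arithmetic mean of the two per-class
    accuracies.  The ROC curve pools decision values over all
    predictions; AUC is its trapezoidal area (midrank tie handling).
    """
    y = np.asarray(y_true, dtype=float)
    f = np.asarray(decision_values, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pred = np.where(f >= 0, 1.0, -1.0)
    acc1 = 100.0 * float(np.mean(pred[y > 0] == 1.0))
    acc2 = 100.0 * float(np.mean(pred[y < 0] == -1.0))
    fpr, tpr, _ = roc_curve(y, f)
    metrics = {
        "accuracy_class1": acc1,
        "accuracy_class2": acc2,
        "balanced_accuracy": (acc1 + acc2) / 2.0,
        "auc": float(roc_auc_score(y, f)),
    }
    return metrics, (fpr, tpr)


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray
                       ) -> dict[str, float]:
    """Pearson r, R^2 = r^2, and mean squared error of pooled predictions."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 pooled predictions")
    mse = float(np.mean((y - p) ** 2))
    if y.std(ddof=0) == 0 or p.std(ddof=0) == 0:
        warnings.warn("zero variance: Pearson r undefined", stacklevel=2)
        return {"r": np.nan, "r2": np.nan, "mse": mse}
    r = float(stats.pearsonr(y, p).statistic)
    return {"r": r, "r2": r ** 2, "mse": mse}


@dataclass
class PermutationReport:
    """Null distributions and p-values from label-permutation reruns."""

    n_permutations: int
    seed: int
    observed: dict[str, float]
    permuted: pd.DataFrame          # one row per permutation, metric columns
    p_values: dict[str, float]


def permute_classification_labels(y: np.ndarray, subjects: np.ndarray,
                                  rng: np.random.Generator,
                                  scheme: str = "within_subject") -> np.ndarray:
    """Permute class labels; default swaps within each subject's pair,
    preserving the paired design.  ``scheme='free'`` permutes labels
    across all samples."""
    y = np.asarray(y, dtype=float)
    if scheme == "free":
        return y[rng.permutation(len(y))]
    out = y.copy()
    for s in np.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        if rng.random() < 0.5:
            out[rows] = out[rows][::-1]
    return out


def permutation_test(pipeline_closure: Callable[[np.ndarray], dict[str, float]],
                     targets: np.ndarray, task: str,
                     observed_metrics: dict[str, float] | None = None,
                     n_perm: int = 100, seed: int = 0,
                     subjects: np.ndarray | None = None,
                     scheme: str = "within_subject") -> PermutationReport:
    """Permutation p-values for every metric the closure reports.

    The closure maps a target vector to a metric dict and must be
    deterministic given the targets (folds and hyperparameter grids held
    fixed).  Classification permutes class labels within each subject's
    image pair; regression permutes the targets across subjects.  For
    each metric, p = (1 + #{|permuted| >= |observed|}) / (n_perm + 1),
    with the comparison reversed (<=) for MSE, so p is never below
    1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(targets, dtype=float)
    if observed_metrics is None:
        observed_metrics = pipeline_closure(y)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        if task == "classification":
            if subjects is None:
                raise ValueError("classification permutation needs subjects")
            y_perm = permute_classification_labels(y, np.asarray(subjects), rng,
                                                   scheme)
        else:
            y_perm = y[rng.permutation(len(y))]
        rows.append(pipeline_closure(y_perm))
    permuted = pd.DataFrame(rows)
    p_values = {}
    for metric, obs in observed_metrics.items():
        if metric not in permuted.columns:
            continue
        vals = permuted[metric].to_numpy(dtype=float)
        if metric in LOWER_IS_BETTER:
            count = int(np.sum(vals <= obs))
        else:
            count = int(np.sum(np.abs(vals) >= abs(obs)))
        p_values[metric] = (1 + count) / (n_perm + 1)
    return PermutationReport(n_permutations=n_perm, seed=seed,
                             observed=observed_metrics, permuted=permuted,
                             p_values=p_values)
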