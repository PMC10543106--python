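"""Repeated cross-validated prediction with permutation testing and
stability-based feature extraction.

The protocol: within each of ``n_iterations`` random 10-fold partitions,
every training fold standardizes its own rows, ranks features by Spearman
correlation with the label, retains those above the threshold, fits a
linear SVM and predicts the held-out fold — no held-out information ever
touches selection, standardization or fitting.  Classification performance
is accuracy / sensitivity / specificity / AUC; regression performance is
R-squared / MSE on pooled out-of-fold predictions.  Significance comes from
a label-permutation test; stability from "consensus" features retained in
every fold of every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sklearn
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import subseed as _subseed
from .connectome import FeatureMatrix, standardize_array
from .selection_model import (LinearModel, ThresholdGrid, decision_values,
                              spearman_rho, train_svc, train_svr)

__all__ = [
    "LabelSet", "CVReport", "PermutationResult", "ConsensusSet", "FoldFit",
    "assign_labels", "labels_from_improvement", "run_repeated_cv",
    "compute_classification_metrics", "compute_regression_metrics",
    "permutation_test", "select_operating_threshold", "extract_consensus",
    "validate_external", "fit_fold",
]

RESPONDER_IMPROVEMENT = 2.0  # SID points


@dataclass
class LabelSet:
    """Responder labels (+1/-1) and the continuous improvement they
    dichotomize (SID_baseline - SID_post)."""
    responder: np.ndarray
    improvement: np.ndarray

    def __post_init__(self) -> None:
        self.responder = np.asarray(self.responder)
        self.improvement = np.asarray(self.improvement, dtype=float)
        if self.responder.shape != self.improvement.shape:
            raise ValueError("responder and improvement differ in length")
        if not np.all(np.isin(self.responder, (-1, 1))):
            raise ValueError("responder labels must be +/-1")
        expect = np.where(self.improvement >= RESPONDER_IMPROVEMENT, 1, -1)
        if not np.array_equal(self.responder, expect):
            raise ValueError("responder labels inconsistent with the >= 2-point rule")


def labels_from_improvement(improvement: np.ndarray) -> LabelSet:
    improvement = np.asarray(improvement, dtype=float)
    return LabelSet(np.where(improvement >= RESPONDER_IMPROVEMENT, 1, -1),
                    improvement)


def assign_labels(sid_baseline: np.ndarray, sid_post: np.ndarray) -> LabelSet:
    """Label rule on observed scores: responder iff the SID score improved
    by at least two points after treatment."""
    base = np.asarray(sid_baseline, dtype=float)
    post = np.asarray(sid_post, dtype=float)
    if base.shape != post.shape:
        raise ValueError("baseline and post score vectors differ in length")
    for name, v in (("baseline", base), ("post", post)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"missing or non-finite {name} SID score")
        if np.any(v < 0):
            raise ValueError(f"{name} SID scores must be nonnegative")
    return labels_from_improvement(base - post)


# --------------------------------------------------------------------------
# metrics

def compute_classification_metrics(y_true: np.ndarray,
                                   decision: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity (responder recall), specificity (nonresponder
    recall) and rank-based AUC from decision values.

    AUC is the Mann-Whitney statistic with average-rank tie correction;
    sensitivity/specificity/AUC are NaN when a class is absent.
    """
    y = np.asarray(y_true).ravel()
    d = np.asarray(decision, dtype=float).ravel()
    if y.size == 0 or y.size != d.size:
        raise ValueError("need matching, nonempty truth and decision vectors")
    pred = np.where(d >= 0, 1, -1)
    acc = float(np.mean(pred == y))
    pos, neg = y == 1, y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    sens = float(np.mean(pred[pos] == 1)) if n_pos else np.nan
    spec = float(np.mean(pred[neg] == -1)) if n_neg else np.nan
    if n_pos and n_neg:
        ranks = rankdata(d)
        auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    else:
        auc = np.nan
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


def compute_regression_metrics(y_true: np.ndarray,
                               y_pred: np.ndarray) -> dict[str, float]:
    """R-squared (1 - SS_res/SS_tot; NaN for constant truths) and MSE."""
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size < 2 or y.size != p.size:
        raise ValueError("need matching vectors of length >= 2")
    mse = float(np.mean((y - p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - p) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return {"r2": r2, "mse": mse}


# --------------------------------------------------------------------------
# fold fitting

@dataclass
class FoldFit:
    """Everything fitted from one training fold: standardization
    parameters, per-feature |rho|, and a (selection, model) pair per
    threshold.  Depends only on the training rows."""
    center: np.ndarray
    scale: np.ndarray
    rho: np.ndarray
    selections: list[np.ndarray]      # per threshold, ascending column idx
    models: list[LinearModel]

    def decide(self, X: np.ndarray, thr_idx: int) -> np.ndarray:
        Xs = (X - self.center) / self.scale
        sel = self.selections[thr_idx]
        return decision_values(self.models[thr_idx], Xs[:, sel])


def _fallback_model(task: str, y_train: np.ndarray, epsilon: float) -> LinearModel:
    # no feature survived the filter: intercept-only (majority / mean)
    if task == "svc":
        bias = 1.0 if (y_train == 1).sum() >= (y_train == -1).sum() else -1.0
        return LinearModel("svc", np.zeros(0), bias)
    return LinearModel("svr", np.zeros(0), float(np.mean(y_train)), epsilon=epsilon)


def fit_fold(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
             thresholds: Sequence[float] | None, task: str = "svc",
             C: float = 1.0, epsilon: float = 0.1) -> FoldFit:
    """Standardize, filter and fit on training rows only.

    ``thresholds=None`` skips selection (all columns retained at a single
    pseudo-threshold).  Held-out rows are never read, which is the
    leakage-ban contract the test suite asserts by mutating them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    train_idx = np.asarray(train_idx)
    Xtr = X[train_idx]
    ytr = y[train_idx]
    _, center, scale = standardize_array(Xtr, np.arange(len(train_idx)))
    Xtr_s = (Xtr - center) / scale

    if thresholds is None:
        sel_all = np.arange(X.shape[1])
        model = (train_svc(Xtr_s, ytr, C=C) if task == "svc"
                 else train_svr(Xtr_s, ytr, C=C, epsilon=epsilon))
        return FoldFit(center, scale, np.full(X.shape[1], np.nan),
                       [sel_all], [model])

    rho = spearman_rho(Xtr, ytr)  # rank-based: standardization-invariant
    abs_rho = np.abs(rho)
    selections, models = [], []
    for thr in thresholds:
        sel = np.flatnonzero(abs_rho >= thr)
        selections.append(sel)
        if sel.size == 0:
            models.append(_fallback_model(task, ytr, epsilon))
        elif task == "svc":
            models.append(train_svc(Xtr_s[:, sel], ytr, C=C))
        else:
            models.append(train_svr(Xtr_s[:, sel], ytr, C=C, epsilon=epsilon))
    return FoldFit(center, scale, rho, selections, models)


# --------------------------------------------------------------------------
# repeated CV

@dataclass
class CVReport:
    """Per-iteration, per-threshold performance plus (optionally) the
    retained-feature sets and fold weights needed for consensus extraction."""
    task: str
    thresholds: np.ndarray
    metrics: dict[str, np.ndarray]            # name -> (n_iterations, n_thresholds)
    n_folds: int
    master_seed: int
    feature_ids: list[str] | None = None
    selections: list[list[list[np.ndarray]]] | None = None   # [it][fold][thr]
    weights: list[list[list[np.ndarray]]] | None = None      # aligned with selections

    @property
    def n_iterations(self) -> int:
        return next(iter(self.metrics.values())).shape[0]

    def summary(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Mean and SD over iterations, per threshold."""
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for name, arr in self.metrics.items():
                out[name] = (np.nanmean(arr, axis=0), np.nanstd(arr, axis=0, ddof=0))
        return out

    def mean_metric(self, name: str, thr_idx: int = 0) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(self.metrics[name][:, thr_idx]))

    def threshold_index(self, threshold: float) -> int:
        idx = np.flatnonzero(np.isclose(self.thresholds, threshold, atol=1e-9))
        if idx.size != 1:
            raise ValueError(f"threshold {threshold} not in the report grid")
        return int(idx[0])


def _labels_for(task: str, labels) -> np.ndarray:
    if isinstance(labels, LabelSet):
        return labels.responder.astype(float) if task == "svc" else labels.improvement
    return np.asarray(labels, dtype=float).ravel()


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _feature_ids(X) -> list[str] | None:
    return X.feature_ids if isinstance(X, FeatureMatrix) else None


def _fold_iterator(y: np.ndarray, n_folds: int, task: str, stratified: bool,
                   seed: int):
    n = y.shape[0]
    if task == "svc" and stratified:
        counts = np.bincount((y == 1).astype(int), minlength=2)
        if counts.min() >= n_folds:
            kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            return kf.split(np.zeros(n), y)
        warnings.warn("too few subjects in a class for stratified folds; "
                      "falling back to unstratified", stacklevel=3)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return kf.split(np.zeros(n))


def run_repeated_cv(X, labels, grid: ThresholdGrid | Sequence[float] | None,
                    n_folds: int = 10, n_iterations: int = 100,
                    task: str = "svc", C: float = 1.0, epsilon: float = 0.1,
                    master_seed: int = 0, stratified: bool = True,
                    pooled: bool | None = None,
                    store_selection: bool = False,
                    store_weights: bool = False) -> CVReport:
    """Repeat ``n_iterations`` random k-fold partitions of the full
    selection + training + prediction pipeline over a threshold grid.

    ``pooled=None`` uses the task default: classification metrics are
    averaged over folds within an iteration, regression metrics are
    computed on the iteration's pooled out-of-fold predictions.
    ``grid=None`` disables feature selection (external-validation mode).
    Deterministic given ``master_seed``.
    """
    if task not in ("svc", "svr"):
        raise ValueError("task must be 'svc' or 'svr'")
    Xv = _values(X)
    y = _labels_for(task, labels)
    n = Xv.shape[0]
    if y.shape[0] != n:
        raise ValueError("labels and features disagree on subject count")
    if n < 2 * n_folds:
        warnings.warn(f"only {n} subjects for {n_folds} folds", stacklevel=2)
    if pooled is None:
        pooled = task == "svr"
    thresholds = None if grid is None else np.asarray(list(grid), dtype=float)
    n_thr = 1 if thresholds is None else thresholds.size
    metric_names = (("accuracy", "sensitivity", "specificity", "auc")
                    if task == "svc" else ("r2", "mse"))
    metrics = {m: np.full((n_iterations, n_thr), np.nan) for m in metric_names}
    all_selections = [] if store_selection else None
    all_weights = [] if store_weights else None

    # inputs are validated once up front; skip sklearn's per-fit validation
    # inside the hot loop (thousands of small SVM fits per analysis)
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        _run_iterations(Xv, y, thresholds, n_folds, n_iterations, task, C,
                        epsilon, master_seed, stratified, pooled, metric_names,
                        metrics, all_selections, all_weights)

    return CVReport(task=task,
                    thresholds=np.zeros(1) if thresholds is None else thresholds,
                    metrics=metrics, n_folds=n_folds, master_seed=master_seed,
                    feature_ids=_feature_ids(X),
                    selections=all_selections, weights=all_weights)


def _run_iterations(Xv, y, thresholds, n_folds, n_iterations, task, C, epsilon,
                    master_seed, stratified, pooled, metric_names, metrics,
                    all_selections, all_weights) -> None:
    n_thr = 1 if thresholds is None else thresholds.size
    for it in range(n_iterations):
        it_seed = _subseed(master_seed, it)
        folds = list(_fold_iterator(y, n_folds, task, stratified, it_seed))
        fold_metrics = {m: np.full((n_folds, n_thr), np.nan) for m in metric_names}
        pooled_truth: list[np.ndarray] = []
        pooled_dec: list[list[np.ndarray]] = [[] for _ in range(n_thr)]
        it_sel, it_wts = [], []
        for f, (train_idx, test_idx) in enumerate(folds):
            fit = fit_fold(Xv, y, train_idx,
                           None if thresholds is None else thresholds,
                           task=task, C=C, epsilon=epsilon)
            y_test = y[test_idx]
            pooled_truth.append(y_test)
            for t in range(n_thr):
                dec = fit.decide(Xv[test_idx], t)
                if pooled:
                    pooled_dec[t].append(dec)
                else:
                    fm = (compute_classification_metrics(y_test, dec)
                          if task == "svc"
                          else compute_regression_metrics(y_test, dec))
                    for m in metric_names:
                        fold_metrics[m][f, t] = fm[m]
            if all_selections is not None:
                it_sel.append([s.copy() for s in fit.selections])
            if all_weights is not None:
                it_wts.append([m.weights.copy() for m in fit.models])
        if pooled:
            y_all = np.concatenate(pooled_truth)
            for t in range(n_thr):
                d_all = np.concatenate(pooled_dec[t])
                fm = (compute_classification_metrics(y_all, d_all)
                      if task == "svc" else compute_regression_metrics(y_all, d_all))
                for m in metric_names:
                    metrics[m][it, t] = fm[m]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for m in metric_names:
                    metrics[m][it] = np.nanmean(fold_metrics[m], axis=0)
        if all_selections is not None:
            all_selections.append(it_sel)
        if all_weights is not None:
            all_weights.append(it_wts)


# --------------------------------------------------------------------------
# permutation testing

@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    p_value: float
    significant: bool
    statistic: str
    better: str  # "higher" | "lower"


_METRIC_BETTER = {"accuracy": "higher", "auc": "higher", "r2": "higher",
                  "mse": "lower"}


def permutation_test(X, labels, threshold: float | None = None,
                     statistic: str = "accuracy", B: int = 1000,
                     n_folds: int = 10, n_iterations: int = 1,
                     task: str = "svc", C: float = 1.0, epsilon: float = 0.1,
                     master_seed: int = 0, stratified: bool = True,
                     better: str | None = None) -> PermutationResult:
    """Label-permutation significance test of the full pipeline.

    Each of the B null replicates permutes the labels, then reruns
    selection + repeated CV from scratch with a fresh fold plan; the
    add-one p-value is (1 + #{null at least as good}) / (1 + B), and the
    model is called significant when the observed statistic beats the 95th
    percentile of the null (5th for lower-is-better statistics).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if better is None:
        better = _METRIC_BETTER.get(statistic)
        if better is None:
            raise ValueError(f"unknown statistic '{statistic}'")
    grid = None if threshold is None else ThresholdGrid((float(threshold),))
    y = _labels_for(task, labels)
    Xv = _values(X)

    def stat_of(y_run: np.ndarray, seed: int) -> float:
        rep = run_repeated_cv(Xv, y_run, grid, n_folds=n_folds,
                              n_iterations=n_iterations, task=task, C=C,
                              epsilon=epsilon, master_seed=seed,
                              stratified=stratified)
        return rep.mean_metric(statistic, 0)

    observed = stat_of(y, _subseed(master_seed, 0))
    rng = np.random.default_rng(_subseed(master_seed, 777_000))
    nulls = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        nulls[b] = stat_of(y_perm, _subseed(master_seed, 1 + b))

    if better == "higher":
        as_good = int(np.sum(nulls >= observed))
        significant = bool(observed > np.percentile(nulls, 95))
    else:
        as_good = int(np.sum(nulls <= observed))
        significant = bool(observed < np.percentile(nulls, 5))
    p = (1 + as_good) / (1 + B)
    return PermutationResult(observed, nulls, p, significant, statistic, better)


# --------------------------------------------------------------------------
# operating threshold and consensus features

def select_operating_threshold(report: CVReport, rule: str = "fixed",
                               value: float = 0.15, metric: str | None = None,
                               tol: float = 0.02, window: int = 5) -> float:
    """Pick the filter threshold the final model operates at.

    Rules: ``fixed`` returns ``value`` (0.15 reproduces the published
    choice); ``max_mean_accuracy`` the metric-maximizing grid point (ties
    to the larger threshold); ``plateau`` the smallest grid point from
    which the mean metric varies by at most ``tol`` over ``window``
    consecutive grid points.
    """
    if rule == "fixed":
        return float(value)
    if metric is None:
        metric = "accuracy" if report.task == "svc" else "r2"
    means = report.summary()[metric][0]
    if rule == "max_mean_accuracy":
        best = np.nanmax(means)
        idx = int(np.flatnonzero(means == best)[-1])
        return float(report.thresholds[idx])
    if rule == "plateau":
        window = min(window, means.size)
        for k in range(means.size - window + 1):
            seg = means[k:k + window]
            if np.all(np.isfinite(seg)) and (seg.max() - seg.min()) <= tol:
                return float(report.thresholds[k])
        raise ValueError("no plateau found at the given tolerance/window")
    raise ValueError(f"unknown threshold rule '{rule}'")


@dataclass
class ConsensusSet:
    """Features retained in every fold of every iteration, with their
    per-iteration signed weight traces (fold weights averaged first)."""
    feature_indices: np.ndarray
    feature_ids: list[str] | None
    per_iteration: list[np.ndarray]
    weight_trace: np.ndarray          # (n_iterations, n_consensus), signed

    @property
    def size(self) -> int:
        return self.feature_indices.size


def extract_consensus(report: CVReport, threshold: float) -> ConsensusSet:
    """Intersect retained-feature sets across folds, then across iterations.

    A feature missing from a single fold of a single iteration is out.
    Requires a report run with ``store_selection=True`` and
    ``store_weights=True`` at a grid containing ``threshold``.
    """
    if report.selections is None or report.weights is None:
        raise ValueError("report must store selections and weights "
                         "(store_selection=True, store_weights=True)")
    t = report.threshold_index(threshold)
    per_iteration = []
    for it_sel in report.selections:
        sets = [set(fold_sel[t].tolist()) for fold_sel in it_sel]
        per_iteration.append(np.array(sorted(set.intersection(*sets)), dtype=int))
    final: set[int] = set(per_iteration[0].tolist())
    for s in per_iteration[1:]:
        final &= set(s.tolist())
    final_idx = np.array(sorted(final), dtype=int)
    if final_idx.size == 0:
        warnings.warn("consensus feature set is empty", stacklevel=2)

    n_it = len(report.selections)
    trace = np.zeros((n_it, final_idx.size))
    for it in range(n_it):
        fold_w = np.zeros((len(report.selections[it]), final_idx.size))
        for f, (sel, wts) in enumerate(zip(report.selections[it],
                                           report.weights[it])):
            pos = {int(c): k for k, c in enumerate(sel[t])}
            for k, feat in enumerate(final_idx):
                fold_w[f, k] = wts[t][pos[int(feat)]]
        trace[it] = fold_w.mean(axis=0) if final_idx.size else fold_w.sum(axis=0)
    ids = ([report.feature_ids[k] for k in final_idx]
           if report.feature_ids is not None else None)
    return ConsensusSet(final_idx, ids, per_iteration, trace)


def validate_external(consensus: ConsensusSet | Sequence[int], X_val, labels_val,
                      task: str = "svc", n_folds: int = 10,
                      n_iterations: int = 100, C: float = 1.0,
                      epsilon: float = 0.1, master_seed: int = 0,
                      B: int = 1000, statistic: str | None = None,
                      ) -> tuple[CVReport, PermutationResult]:
    """Re-evaluate the predictive features on an independent cohort.

    Columns are restricted to the consensus set and repeated CV runs with
    no further selection; the permutation test re-permutes labels within
    the validation cohort only.  Fails on an empty predictive set or on
    missing columns.
    """
    if isinstance(consensus, ConsensusSet):
        idx = consensus.feature_indices
        ids = consensus.feature_ids
    else:
        idx = np.asarray(list(consensus), dtype=int)
        ids = None
    if idx.size == 0:
        raise ValueError("predictive feature set is empty")
    if isinstance(X_val, FeatureMatrix):
        if ids is not None:
            Xr = X_val.restrict(ids).values  # raises on missing columns
        else:
            Xr = X_val.values[:, idx]
    else:
        Xv = np.asarray(X_val, dtype=float)
        if idx.max() >= Xv.shape[1]:
            missing = [int(k) for k in idx if k >= Xv.shape[1]]
            raise ValueError(f"validation features missing columns {missing}")
        Xr = Xv[:, idx]
    if statistic is None:
        statistic = "accuracy" if task == "svc" else "r2"
    report = run_repeated_cv(Xr, labels_val, None, n_folds=n_folds,
                             n_iterations=n_iterations, task=task, C=C,
                             epsilon=epsilon, master_seed=master_seed)
    perm = permutation_test(Xr, labels_val, None, statistic=statistic, B=B,
                            n_folds=n_folds, n_iterations=min(n_iterations, 5),
                            task=task, C=C, epsilon=epsilon,
                            master_seed=_subseed(master_seed, 31),)
    return report, perm
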