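"""SVM patient-stratification harness with cross-validated evaluation.

Two binary tasks are supported on the 12-feature bioenergetic matrix:
control vs. disease (sALS + PLS + C9orf72 combined; disease is the
positive class) and sALS vs. PLS (C9orf72 lines excluded; sALS is the
positive class).

Model selection is a grid search over 1120 hyperparameter sets —
4 kernels x 7 penalties x 8 gamma values x 5 class-weight settings —
scored by the mean validation accuracy over stratified 10-fold
cross-validation with folds fixed by seed and shared across grid points.
Features are z-scored with training-fold statistics only (the raw
feature scales span four orders of magnitude, which distance-based
kernels cannot tolerate). Ties in mean accuracy break by enumeration
order, which is kernel-major and deterministic.

Evaluation of the selected model reports per-fold ROC curves from the
continuous decision score, their vertical average on a fixed 101-point
FPR grid with the trapezoidal AUC, and a confusion panel (sensitivity,
specificity, PPV, NPV, FPR, FNR, FDR) from confusion counts pooled
across validation folds, with across-fold normal-approximation 95% CIs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "GridPoint",
    "build_default_grid",
    "make_task",
    "cross_validate_grid",
    "GridSearchResult",
    "evaluate_best",
    "CVReport",
    "mean_roc",
    "TASKS",
]

KERNELS = ("linear", "rbf", "poly", "sigmoid")
C_VALUES = tuple(np.logspace(-2, 4, 7))          # 0.01 ... 10000
GAMMA_VALUES = tuple(np.logspace(np.log10(1e-4), np.log10(30.0), 8))
CLASS_WEIGHTS = ("none", "balanced", "pos2", "pos5", "pos10")

#: task name -> (positive groups, negative groups)
TASKS = {
    "control-vs-disease": (("sALS", "PLS", "C9orf72"), ("control",)),
    "sals-vs-pls": (("sALS",), ("PLS",)),
}

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class GridPoint:
    """One hyperparameter set. gamma is enumerated (and ignored) for the
    linear kernel so the grid cardinality is uniform across kernels."""

    kernel: str
    C: float
    gamma: float
    class_weight: str  # one of CLASS_WEIGHTS

    def sklearn_class_weight(self):
        if self.class_weight == "none":
            return None
        if self.class_weight == "balanced":
            return "balanced"
        return {1: int(self.class_weight[3:])}

    def make_svc(self) -> SVC:
        # iteration cap keeps pathological large-C points from stalling the
        # grid; a truncated fit simply scores what it earned
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                   class_weight=self.sklearn_class_weight(),
                   cache_size=64, max_iter=5000)

    def fit_key(self) -> tuple:
        """Grid points indistinguishable to the solver share a key
        (the linear kernel ignores gamma)."""
        gamma = None if self.kernel == "linear" else self.gamma
        return (self.kernel, self.C, gamma, self.class_weight)


def build_default_grid() -> list[GridPoint]:
    """The default 4 x 7 x 8 x 5 = 1120-point grid, kernel-major order."""
    return [GridPoint(k, c, g, w)
            for k, c, g, w in itertools.product(KERNELS, C_VALUES,
                                                GAMMA_VALUES, CLASS_WEIGHTS)]


def make_task(y_groups: pd.Series | np.ndarray, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for a named task.

    Returns ``(mask, y)``: a boolean mask over the input selecting the
    lines that participate, and 0/1 labels (1 = positive class) for the
    selected lines.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task '{task}'; available: {sorted(TASKS)}")
    pos, neg = TASKS[task]
    groups = np.asarray(y_groups)
    mask = np.isin(groups, pos + neg)
    y = np.isin(groups[mask], pos).astype(int)
    return mask, y


def _prepare_folds(X: np.ndarray, y: np.ndarray, k: int, seed: int):
    """Stratified folds with per-fold train-statistics z-scoring.

    Returns a list of (X_train, y_train, X_val, y_val, val_idx) with the
    scaling already applied, so grid points can reuse them.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff}: smallest class has "
                      f"{counts.min()} members", stacklevel=3)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in skf.split(X, y):
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        folds.append(((X[train_idx] - mu) / sd, y[train_idx],
                      (X[val_idx] - mu) / sd, y[val_idx], val_idx))
    return folds


@dataclass
class GridSearchResult:
    accuracy_table: pd.DataFrame   # one row per grid point + fold accuracies
    best_index: int
    best_point: GridPoint
    best_mean_accuracy: float
    k: int


def cross_validate_grid(X, y, grid: list[GridPoint] | None = None,
                        k: int = 10, seed: int = 0) -> GridSearchResult:
    """Mean validation accuracy per grid point; best point by accuracy.

    Folds are stratified, fixed by ``seed``, and identical across grid
    points. Returns the full accuracy table for audit; the best point is
    the first (enumeration order) with maximal mean accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    grid = build_default_grid() if grid is None else grid
    folds = _prepare_folds(X, y, k, seed)
    acc = np.empty((len(grid), len(folds)))
    cache: dict[tuple, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for gi, point in enumerate(grid):
            key = point.fit_key()
            if key not in cache:
                svc = point.make_svc()
                row = np.empty(len(folds))
                for fi, (Xtr, ytr, Xva, yva, _) in enumerate(folds):
                    svc.fit(Xtr, ytr)
                    row[fi] = (svc.predict(Xva) == yva).mean()
                cache[key] = row
            acc[gi] = cache[key]
    mean_acc = acc.mean(axis=1)
    best = int(np.argmax(mean_acc))  # argmax returns the first maximum
    table = pd.DataFrame({
        "kernel": [p.kernel for p in grid],
        "C": [p.C for p in grid],
        "gamma": [p.gamma for p in grid],
        "class_weight": [p.class_weight for p in grid],
        "mean_accuracy": mean_acc,
    })
    for fi in range(len(folds)):
        table[f"fold_{fi}"] = acc[:, fi]
    return GridSearchResult(accuracy_table=table, best_index=best,
                            best_point=grid[best],
                            best_mean_accuracy=float(mean_acc[best]),
                            k=len(folds))


def mean_roc(curves: list[tuple[np.ndarray, np.ndarray]]
             ) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Vertical (pointwise) average of per-fold ROC curves.

    Each fold's curve is linearly interpolated onto the fixed 101-point
    FPR grid and TPR is averaged pointwise; the summary AUC is the
    trapezoid rule on the mean curve. Per-fold AUCs (same grid) are also
    returned. Requires at least one curve.
    """
    if not curves:
        raise ValueError("mean_roc requires at least one curve")
    tprs = []
    fold_aucs = []
    for fpr, tpr in curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        # collapse vertical segments: keep the top TPR at each distinct FPR,
        # so a perfect fold averages to AUC exactly 1
        last = np.r_[np.diff(fpr) > 0, True]
        interp = np.interp(FPR_GRID, fpr[last], tpr[last])
        tprs.append(interp)
        fold_aucs.append(float(np.trapezoid(interp, FPR_GRID)))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    return FPR_GRID.copy(), mean_tpr, auc, fold_aucs


_PANEL_METRICS = ("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr", "fdr")


def _panel_from_counts(tp: float, fn: float, tn: float, fp: float) -> dict[str, float]:
    """Confusion panel in percent; undefined ratios (0/0) become NaN."""
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": ratio(tn, tn + fn),
        "fpr": 100.0 - spec if not np.isnan(spec) else np.nan,
        "fnr": 100.0 - sens if not np.isnan(sens) else np.nan,
        "fdr": 100.0 - ppv if not np.isnan(ppv) else np.nan,
    }


@dataclass
class CVReport:
    """Cross-validated evaluation of one selected model on one task."""

    task: str
    best_point: GridPoint
    fold_accuracies: list[float]
    mean_accuracy: float
    fold_curves: list[tuple[np.ndarray, np.ndarray]]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc_mean_curve: float
    fold_aucs: list[float]
    pooled_confusion: dict[str, float]          # tp, fn, tn, fp over all folds
    panel: pd.DataFrame                         # metric, value, ci_low, ci_high
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out = {"task": self.task, "mean_accuracy": self.mean_accuracy,
               "auc_mean_curve": self.auc_mean_curve,
               "best_point": {"kernel": self.best_point.kernel,
                              "C": self.best_point.C,
                              "gamma": self.best_point.gamma,
                              "class_weight": self.best_point.class_weight}}
        for _, row in self.panel.iterrows():
            out[row["metric"]] = row["value"]
        return out


def evaluate_best(X, y, best: GridPoint, k: int = 10, seed: int = 0,
                  task: str = "", panel_from: str = "pooled") -> CVReport:
    """Refit the selected model per fold and assemble the full report.

    Confusion counts are taken on each validation fold at the decision
    threshold (SVC ``predict``); panel metrics come from counts pooled
    across folds by default (``panel_from='fold_mean'`` averages per-fold
    metrics instead). CIs are mean +/- 1.96 * SD / sqrt(k) over the folds
    with defined values, truncated to [0, 100]. ROC curves use the
    continuous ``decision_function`` score.
    """
    if panel_from not in ("pooled", "fold_mean"):
        raise ValueError("panel_from must be 'pooled' or 'fold_mean'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = _prepare_folds(X, y, k, seed)
    warnings_: list[str] = []
    fold_acc, curves, fold_panels = [], [], []
    counts = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
    for fi, (Xtr, ytr, Xva, yva, _) in enumerate(folds):
        svc = best.make_svc()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svc.fit(Xtr, ytr)
        pred = svc.predict(Xva)
        fold_acc.append(float((pred == yva).mean()))
        tp = int(((pred == 1) & (yva == 1)).sum())
        fn = int(((pred == 0) & (yva == 1)).sum())
        tn = int(((pred == 0) & (yva == 0)).sum())
        fp = int(((pred == 1) & (yva == 0)).sum())
        for key, val in zip(("tp", "fn", "tn", "fp"), (tp, fn, tn, fp)):
            counts[key] += val
        if yva.sum() == 0 or (1 - yva).sum() == 0:
            warnings_.append(f"fold {fi}: single-class validation set; "
                             "undefined metrics excluded from CI")
        fold_panels.append(_panel_from_counts(tp, fn, tn, fp))
        score = svc.decision_function(Xva)
        if len(np.unique(yva)) == 2:
            fpr, tpr, _ = roc_curve(yva, score)
            curves.append((fpr, tpr))
        else:
            warnings_.append(f"fold {fi}: ROC undefined (single-class), skipped")
    fpr_grid, mean_tpr, auc, fold_aucs = mean_roc(curves)

    pooled = _panel_from_counts(**counts)
    rows = []
    for metric in _PANEL_METRICS:
        per_fold = np.array([p[metric] for p in fold_panels], dtype=float)
        defined = per_fold[~np.isnan(per_fold)]
        if len(defined):
            half = 1.96 * defined.std(ddof=1) / np.sqrt(len(defined)) if len(defined) > 1 else np.nan
            center = defined.mean()
        else:
            half, center = np.nan, np.nan
        value = pooled[metric] if panel_from == "pooled" else center
        rows.append({"metric": metric, "value": value,
                     "ci_low": max(0.0, center - half) if not np.isnan(half) else np.nan,
                     "ci_high": min(100.0, center + half) if not np.isnan(half) else np.nan})
    panel = pd.DataFrame(rows)
    return CVReport(task=task, best_point=best, fold_accuracies=fold_acc,
                    mean_accuracy=float(np.mean(fold_acc)), fold_curves=curves,
                    fpr_grid=fpr_grid, mean_tpr=mean_tpr, auc_mean_curve=auc,
                    fold_aucs=fold_aucs, pooled_confusion=dict(counts),
                    panel=panel, warnings=warnings_)
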