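"""Connectome-based prediction (SVR) and two-group classification (RBF SVM).

The kernel learners themselves come from scikit-learn; this module owns the
nested-cross-validation harness (hyperparameter grids selected strictly inside
outer-training data), repetition averaging, metrics, and label-permutation
significance. Feature scaling is fitted on outer-training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

__all__ = [
    "FeatureMask",
    "PredictionReport",
    "ClassificationReport",
    "svr_predict_cv",
    "svm_classify_cv",
    "compare_feature_sets",
]

DEFAULT_SVR_C_GRID = np.round(np.arange(0.1, 1.01, 0.1), 10)
DEFAULT_SVM_C_GRID = 2.0 ** np.arange(-5, 16, 2)
DEFAULT_SVM_GAMMA_GRID = 2.0 ** np.arange(-15, 4, 2)


@dataclass
class FeatureMask:
    """Boolean edge selector; ``whole_brain`` marks an all-true mask."""

    selected: np.ndarray
    data_derived: bool = False  # True when the mask came from the same sample

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool).ravel()
        if self.selected.sum() < 1:
            raise ValueError("feature mask selects no edges")

    @classmethod
    def whole_brain(cls, n_edges: int) -> "FeatureMask":
        return cls(selected=np.ones(n_edges, dtype=bool))

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class PredictionReport:
    predictions: np.ndarray  # per-subject, averaged over repetitions
    r: float
    mae: float
    baseline_mae: float  # MAE of always predicting mean(y)
    permutation_p: float | None
    c_grid: np.ndarray
    outer_folds: int
    inner_folds: int
    repetitions: int
    n_perm: int
    seed: int
    mask_n_selected: int
    mask_data_derived: bool
    settings: dict = field(default_factory=dict)


@dataclass
class ClassificationReport:
    accuracy: float  # mean over repetitions
    sensitivity: float
    specificity: float
    auc: float  # from mean decision values
    auc_per_repetition: float  # alternative: per-repetition AUC averaged
    decision_values: np.ndarray  # per-subject means
    meaningful: bool  # accuracy > 0.70 per the reporting convention
    permutation_p: float | None
    c_grid: np.ndarray
    gamma_grid: np.ndarray
    outer_folds: int
    inner_folds: int
    repetitions: int
    n_perm: int
    seed: int
    mask_n_selected: int
    mask_data_derived: bool
    settings: dict = field(default_factory=dict)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a @ b) / den) if den > 0 else float("nan")


def _scale_train_test(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _svr_one_repetition(
    x: np.ndarray, y: np.ndarray, c_grid, outer_folds, inner_folds, rng
) -> np.ndarray:
    n = x.shape[0]
    preds = np.empty(n)
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    for train_idx, test_idx in outer.split(x):
        xtr_raw, xte_raw = x[train_idx], x[test_idx]
        ytr = y[train_idx]
        inner = KFold(
            n_splits=inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        splits = list(inner.split(xtr_raw))
        best_c, best_score = c_grid[0], -np.inf
        for c in c_grid:
            inner_pred = np.empty(xtr_raw.shape[0])
            for itr, ite in splits:
                xi, xv = _scale_train_test(xtr_raw[itr], xtr_raw[ite])
                m = SVR(C=c)
                m.fit(xi, ytr[itr])
                inner_pred[ite] = m.predict(xv)
            score = _pearson(inner_pred, ytr)
            if np.isnan(score):
                score = -np.inf
            if score > best_score:
                best_c, best_score = c, score
        xtr, xte = _scale_train_test(xtr_raw, xte_raw)
        m = SVR(C=best_c)
        m.fit(xtr, ytr)
        preds[test_idx] = m.predict(xte)
    return preds


def svr_predict_cv(
    X: np.ndarray,
    y: np.ndarray,
    mask: FeatureMask | None = None,
    c_grid=DEFAULT_SVR_C_GRID,
    outer_folds: int = 10,
    inner_folds: int = 10,
    repetitions: int = 100,
    n_perm: int = 1000,
    perm_repetitions: int = 1,
    seed: int = 0,
) -> PredictionReport:
    """Repeated nested-CV support-vector regression of ``y`` on masked edges.

    Per repetition: outer k-fold; inside each outer-training set an inner
    k-fold picks C from the grid by inner Pearson r; the refit model predicts
    the outer test fold. Predictions are averaged per subject over
    repetitions before computing the final r and MAE. Significance shuffles
    ``y`` and reruns the pipeline (``perm_repetitions`` repetitions per
    permutation as a cost trade-off).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("target is constant; prediction is undefined")
    if mask is None:
        mask = FeatureMask.whole_brain(X.shape[1])
    xm = X[:, mask.selected]
    c_grid = np.asarray(c_grid, dtype=float)
    rng = np.random.default_rng(seed)

    def _run(target: np.ndarray, reps: int) -> np.ndarray:
        acc = np.zeros(X.shape[0])
        for _ in range(reps):
            acc += _svr_one_repetition(xm, target, c_grid, outer_folds, inner_folds, rng)
        return acc / reps

    preds = _run(y, repetitions)
    r_obs = _pearson(preds, y)
    mae = float(np.abs(preds - y).mean())
    perm_p = None
    if n_perm and n_perm > 0:
        exceed = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            preds_p = _run(yp, perm_repetitions)
            if _pearson(preds_p, yp) >= r_obs:
                exceed += 1
        perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return PredictionReport(
        predictions=preds,
        r=r_obs,
        mae=mae,
        baseline_mae=float(np.abs(y - y.mean()).mean()),
        permutation_p=perm_p,
        c_grid=c_grid,
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        repetitions=repetitions,
        n_perm=n_perm,
        seed=seed,
        mask_n_selected=mask.n_selected,
        mask_data_derived=mask.data_derived,
        settings={"kernel": "rbf", "epsilon": SVR().epsilon, "gamma": "scale"},
    )


def _svm_one_repetition(
    x: np.ndarray, labels: np.ndarray, c_grid, gamma_grid, outer_folds, inner_folds, rng
):
    n = x.shape[0]
    pred = np.empty(n, dtype=int)
    decision = np.empty(n)
    outer = StratifiedKFold(
        n_splits=outer_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    for train_idx, test_idx in outer.split(x, labels):
        xtr_raw, xte_raw = x[train_idx], x[test_idx]
        ltr = labels[train_idx]
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        splits = list(inner.split(xtr_raw, ltr))
        best, best_acc = (c_grid[0], gamma_grid[0]), -np.inf
        for c in c_grid:
            for g in gamma_grid:
                hits = 0
                for itr, ite in splits:
                    xi, xv = _scale_train_test(xtr_raw[itr], xtr_raw[ite])
                    m = SVC(C=c, gamma=g, kernel="rbf")
                    m.fit(xi, ltr[itr])
                    hits += int((m.predict(xv) == ltr[ite]).sum())
                acc = hits / xtr_raw.shape[0]
                if acc > best_acc:
                    best, best_acc = (c, g), acc
        xtr, xte = _scale_train_test(xtr_raw, xte_raw)
        m = SVC(C=best[0], gamma=best[1], kernel="rbf")
        m.fit(xtr, ltr)
        pred[test_idx] = m.predict(xte)
        decision[test_idx] = m.decision_function(xte)
    return pred, decision


def _rates(pred: np.ndarray, labels: np.ndarray):
    tp = np.sum((pred == 1) & (labels == 1))
    tn = np.sum((pred == 0) & (labels == 0))
    fp = np.sum((pred == 1) & (labels == 0))
    fn = np.sum((pred == 0) & (labels == 1))
    acc = (tp + tn) / labels.size
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return acc, sens, spec


def svm_classify_cv(
    X: np.ndarray,
    labels: np.ndarray,
    mask: FeatureMask | None = None,
    c_grid=DEFAULT_SVM_C_GRID,
    gamma_grid=DEFAULT_SVM_GAMMA_GRID,
    outer_folds: int = 10,
    inner_folds: int = 10,
    repetitions: int = 100,
    n_perm: int = 1000,
    perm_repetitions: int = 1,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated nested-CV RBF-SVM classification with label-permutation p.

    Accuracy/sensitivity/specificity are computed from pooled outer-test
    predictions per repetition and averaged across repetitions; AUC comes
    from the per-subject mean decision values (the averaged-per-repetition
    alternative is also reported).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if np.any(np.bincount(labels) < 5):
        raise ValueError("each class needs at least 5 subjects")
    if mask is None:
        mask = FeatureMask.whole_brain(X.shape[1])
    xm = X[:, mask.selected]
    c_grid = np.asarray(c_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    rng = np.random.default_rng(seed)

    def _run(lab: np.ndarray, reps: int):
        accs, senss, specs, aucs = [], [], [], []
        dec_sum = np.zeros(X.shape[0])
        for _ in range(reps):
            pred, dec = _svm_one_repetition(
                xm, lab, c_grid, gamma_grid, outer_folds, inner_folds, rng
            )
            a, s, sp = _rates(pred, lab)
            accs.append(a)
            senss.append(s)
            specs.append(sp)
            aucs.append(roc_auc_score(lab, dec))
            dec_sum += dec
        return (
            float(np.mean(accs)),
            float(np.mean(senss)),
            float(np.mean(specs)),
            float(np.mean(aucs)),
            dec_sum / reps,
        )

    acc, sens, spec, auc_rep, dec_mean = _run(labels, repetitions)
    auc = float(roc_auc_score(labels, dec_mean))
    perm_p = None
    if n_perm and n_perm > 0:
        exceed = 0
        for _ in range(n_perm):
            lp = rng.permutation(labels)
            acc_p = _run(lp, perm_repetitions)[0]
            if acc_p >= acc:
                exceed += 1
        perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_per_repetition=auc_rep,
        decision_values=dec_mean,
        meaningful=acc > 0.70,
        permutation_p=perm_p,
        c_grid=c_grid,
        gamma_grid=gamma_grid,
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        repetitions=repetitions,
        n_perm=n_perm,
        seed=seed,
        mask_n_selected=mask.n_selected,
        mask_data_derived=mask.data_derived,
        settings={"kernel": "rbf", "class_weight": None},
    )


def compare_feature_sets(report_masked, report_wholebrain) -> dict:
    """Descriptive side-by-side of masked vs whole-brain reports (no test)."""
    for attr in ("outer_folds", "inner_folds", "repetitions", "seed"):
        if getattr(report_masked, attr) != getattr(report_wholebrain, attr):
            raise ValueError(f"reports differ in {attr}; comparison is invalid")
    if isinstance(report_masked, PredictionReport) != isinstance(
        report_wholebrain, PredictionReport
    ):
        raise ValueError("cannot compare a prediction report with a classification report")
    if isinstance(report_masked, PredictionReport):
        metrics = ("r", "mae")
    else:
        metrics = ("accuracy", "sensitivity", "specificity", "auc")
    out = {}
    for m in metrics:
        a, b = getattr(report_masked, m), getattr(report_wholebrain, m)
        out[m] = {"masked": a, "whole_brain": b, "difference": a - b}
    return out
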