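"""Behavioural PLS: SVD of the cross-covariance plus nonparametric inference.

The fit decomposes ``R = Y'X / (n - 1)`` computed on standardized blocks, so
``R`` is a cross-correlation matrix. Each latent variable (LV) pairs a
unit-norm edge salience with a unit-norm behaviour salience; subjects'
composite scores are plain projections of their data onto the saliences.
Feature importance is reported as *loadings*: Pearson correlations between
each raw column and its block's composite score.

Sign convention: per LV, signs are flipped so the largest-magnitude behaviour
salience entry is positive; resampled fits are aligned back to the reference
fit by the sign of the behaviour-salience inner product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import false_discovery_control

from .io_model import SchemaError
from .preprocess import apply_residualizer, fit_residualizer

__all__ = [
    "PlsModel",
    "BootstrapResult",
    "CvResult",
    "fit_pls",
    "covariance_explained",
    "permutation_test_lvs",
    "bootstrap_loadings",
    "cross_validate",
    "project",
    "compare_models",
    "first_principal_component",
]

_STD_TOL = 1e-8


@dataclass
class PlsModel:
    saliences_x: np.ndarray  # (E, K)
    saliences_y: np.ndarray  # (P, K)
    singular_values: np.ndarray  # (K,) descending
    covariance_explained: np.ndarray  # (K,) fractions of the full spectrum
    composite_x: np.ndarray  # (n, K)
    composite_y: np.ndarray  # (n, K)
    loadings_x: np.ndarray  # (E, K)
    loadings_y: np.ndarray  # (P, K)
    n_subjects: int
    lv_pvalues: np.ndarray | None = None
    lv_qvalues: np.ndarray | None = None

    @property
    def n_lvs(self) -> int:
        return self.singular_values.size

    def to_dict(self) -> dict:
        d = {
            "saliences_x": self.saliences_x.tolist(),
            "saliences_y": self.saliences_y.tolist(),
            "singular_values": self.singular_values.tolist(),
            "covariance_explained": self.covariance_explained.tolist(),
            "composite_x": self.composite_x.tolist(),
            "composite_y": self.composite_y.tolist(),
            "loadings_x": self.loadings_x.tolist(),
            "loadings_y": self.loadings_y.tolist(),
            "n_subjects": self.n_subjects,
        }
        if self.lv_pvalues is not None:
            d["lv_pvalues"] = self.lv_pvalues.tolist()
            d["lv_qvalues"] = self.lv_qvalues.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            saliences_x=np.array(d["saliences_x"]),
            saliences_y=np.array(d["saliences_y"]),
            singular_values=np.array(d["singular_values"]),
            covariance_explained=np.array(d["covariance_explained"]),
            composite_x=np.array(d["composite_x"]),
            composite_y=np.array(d["composite_y"]),
            loadings_x=np.array(d["loadings_x"]),
            loadings_y=np.array(d["loadings_y"]),
            n_subjects=int(d["n_subjects"]),
            lv_pvalues=np.array(d["lv_pvalues"]) if "lv_pvalues" in d else None,
            lv_qvalues=np.array(d["lv_qvalues"]) if "lv_qvalues" in d else None,
        )


@dataclass
class BootstrapResult:
    loading_sd_x: np.ndarray
    loading_sd_y: np.ndarray
    bootstrap_z_x: np.ndarray
    bootstrap_z_y: np.ndarray
    n_boot: int
    seed: int
    skipped_x: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    skipped_y: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class CvResult:
    fold_correlations: np.ndarray  # (repetitions, folds, K)
    mean_test_r: np.ndarray  # (K,)
    permuted_p: np.ndarray | None
    folds: int
    repetitions: int
    seed: int


def _standardize_block(m: np.ndarray, name: str, rescale: bool) -> np.ndarray:
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd < _STD_TOL):
        raise ValueError(f"{name} has constant column(s): {np.flatnonzero(sd < _STD_TOL).tolist()}")
    centered = np.abs(x.mean(axis=0)).max() < _STD_TOL
    scaled = np.abs(sd - 1.0).max() < 1e-6
    if centered and scaled:
        return x
    if not rescale:
        raise ValueError(f"{name} is not standardized and rescaling is disabled")
    warnings.warn(f"{name} was not standardized; re-standardizing (ddof=1)")
    return (x - x.mean(axis=0)) / sd


def _apply_sign_convention(sal_x: np.ndarray, sal_y: np.ndarray) -> np.ndarray:
    """Flip LV signs so the largest-|.| behaviour salience entry is positive."""
    flips = np.ones(sal_y.shape[1])
    for k in range(sal_y.shape[1]):
        col = sal_y[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            flips[k] = -1.0
    sal_x *= flips
    sal_y *= flips
    return flips


def _safe_standardize(m: np.ndarray, constant: np.ndarray) -> np.ndarray:
    sd = m.std(axis=0, ddof=1)
    sd = np.where(constant, 1.0, sd)
    out = (m - m.mean(axis=0)) / sd
    out[:, constant] = 0.0
    return out


def _column_correlations(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of every data column against every score column -> (M, K)."""
    dc = data - data.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    dn = np.sqrt((dc**2).sum(axis=0))
    sn = np.sqrt((sc**2).sum(axis=0))
    dn = np.where(dn == 0, np.nan, dn)
    sn = np.where(sn == 0, np.nan, sn)
    return (dc.T @ sc) / np.outer(dn, sn)


def fit_pls(X: np.ndarray, Y: np.ndarray, k="all", rescale: bool = True) -> PlsModel:
    """Fit behavioural PLS on standardized blocks ``X`` (n x E), ``Y`` (n x P)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Xs = _standardize_block(X, "X", rescale)
    Ys = _standardize_block(Y, "Y", rescale)
    r = Ys.T @ Xs / (n - 1)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("cross-covariance spectrum is identically zero")
    k_max = min(Y.shape[1], X.shape[1], n - 1)
    n_keep = k_max if k == "all" else min(int(k), k_max)
    sal_y = u[:, :n_keep].copy()
    sal_x = vt[:n_keep].T.copy()
    _apply_sign_convention(sal_x, sal_y)
    comp_x = Xs @ sal_x
    comp_y = Ys @ sal_y
    return PlsModel(
        saliences_x=sal_x,
        saliences_y=sal_y,
        singular_values=s[:n_keep],
        covariance_explained=s[:n_keep] ** 2 / total,
        composite_x=comp_x,
        composite_y=comp_y,
        loadings_x=_column_correlations(Xs, comp_x),
        loadings_y=_column_correlations(Ys, comp_y),
        n_subjects=n,
    )


def covariance_explained(singular_values) -> np.ndarray:
    """Fraction of total squared singular value per LV; sums to 1."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    total = (s**2).sum()
    if total == 0:
        raise ValueError("all-zero spectrum: covariance explained is undefined")
    return s**2 / total


def permutation_test_lvs(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    rescale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p/q-values for each LV's singular value (rank-matched).

    Rows of ``Y`` are permuted with ``X`` fixed; per permutation the singular
    values are recomputed and matched to the observed LVs by rank order.
    ``p_k = (1 + #{s_perm >= s_obs}) / (n_perm + 1)``; q-values are
    Benjamini-Hochberg across the K LVs.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    Xs = _standardize_block(X, "X", rescale)
    Ys = _standardize_block(Y, "Y", rescale)
    s_obs = np.linalg.svd(Ys.T @ Xs / (n - 1), compute_uv=False)
    k = min(Y.shape[1], X.shape[1], n - 1)
    s_obs = s_obs[:k]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_p = np.linalg.svd(Ys[perm].T @ Xs / (n - 1), compute_uv=False)[:k]
        exceed += s_p >= s_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = false_discovery_control(p, method="bh")
    return p, q


def bootstrap_loadings(
    X: np.ndarray,
    Y: np.ndarray,
    model: PlsModel,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap SDs of loadings and z = loading / SD, sign-aligned per LV."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    k = model.n_lvs
    rng = np.random.default_rng(seed)
    lx = np.full((n_boot, X.shape[1], k), np.nan)
    ly = np.full((n_boot, Y.shape[1], k), np.nan)
    skipped_x = np.zeros(X.shape[1], dtype=int)
    skipped_y = np.zeros(Y.shape[1], dtype=int)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = X[idx], Y[idx]
        # constant resampled columns drop out of the fit (zeroed rows of R)
        const_x = xb.std(axis=0, ddof=1) < _STD_TOL
        const_y = yb.std(axis=0, ddof=1) < _STD_TOL
        skipped_x += const_x
        skipped_y += const_y
        xs = _safe_standardize(xb, const_x)
        ys = _safe_standardize(yb, const_y)
        r = ys.T @ xs / (n - 1)
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        n_lv = min(k, s.size)
        sal_y = u[:, :n_lv]
        sal_x = vt[:n_lv].T
        comp_x = xs @ sal_x
        comp_y = ys @ sal_y
        # align each bootstrap LV sign to the reference fit
        flips = np.sign(np.sum(sal_y * model.saliences_y[:, :n_lv], axis=0))
        flips[flips == 0] = 1.0
        lx[b, :, :n_lv] = _column_correlations(xs, comp_x) * flips
        ly[b, :, :n_lv] = _column_correlations(ys, comp_y) * flips
        lx[b, const_x, :] = np.nan
        ly[b, const_y, :] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd_x = np.nanstd(lx, axis=0, ddof=1)
        sd_y = np.nanstd(ly, axis=0, ddof=1)
        z_x = np.where(sd_x > 0, model.loadings_x / np.where(sd_x > 0, sd_x, 1.0), np.inf)
        z_y = np.where(sd_y > 0, model.loadings_y / np.where(sd_y > 0, sd_y, 1.0), np.inf)
    return BootstrapResult(
        loading_sd_x=sd_x,
        loading_sd_y=sd_y,
        bootstrap_z_x=z_x,
        bootstrap_z_y=z_y,
        n_boot=n_boot,
        seed=seed,
        skipped_x=skipped_x,
        skipped_y=skipped_y,
    )


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between two (n, K) matrices -> (K,)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _cv_fold_correlations(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    confounds: np.ndarray | None,
    folds: int,
    repetitions: int,
    n_lvs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = X_raw.shape[0]
    out = np.full((repetitions, folds, n_lvs), np.nan)
    for rep in range(repetitions):
        assignment = np.array_split(rng.permutation(n), folds)
        for f, test_idx in enumerate(assignment):
            if test_idx.size < 3:
                raise ValueError("each fold needs at least 3 subjects")
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            conf_tr = None if confounds is None else confounds[train_idx]
            conf_te = None if confounds is None else confounds[test_idx]
            rx = fit_residualizer(X_raw[train_idx], conf_tr)
            ry = fit_residualizer(Y_raw[train_idx], conf_tr)
            xtr = apply_residualizer(rx, X_raw[train_idx], conf_tr)
            ytr = apply_residualizer(ry, Y_raw[train_idx], conf_tr)
            xte = apply_residualizer(rx, X_raw[test_idx], conf_te)
            yte = apply_residualizer(ry, Y_raw[test_idx], conf_te)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_pls(xtr, ytr, k=n_lvs)
            sx = xte @ model.saliences_x
            sy = yte @ model.saliences_y
            out[rep, f, : model.n_lvs] = _pearson_columns(sx, sy)
    return out


def cross_validate(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    confounds: np.ndarray | None,
    folds: int = 10,
    repetitions: int = 200,
    n_perm_cv: int = 100,
    perm_repetitions: int = 1,
    n_lvs: int | None = None,
    seed: int = 0,
) -> CvResult:
    """Leakage-safe repeated k-fold generalizability test.

    Residualization and standardization parameters are estimated on the
    training folds only and applied to the held-out fold; the test fold is
    projected onto the training saliences and the per-LV Pearson r between the
    two test composite scores is recorded. ``mean_test_r`` averages over all
    folds and repetitions. Significance repeats the whole procedure (with
    ``perm_repetitions`` repetitions per permutation as a cost trade-off)
    after shuffling the rows of ``Y_raw``.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    n = X_raw.shape[0]
    if Y_raw.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n_lvs is None:
        n_lvs = min(X_raw.shape[1], Y_raw.shape[1])
    rng = np.random.default_rng(seed)
    fold_r = _cv_fold_correlations(
        X_raw, Y_raw, confounds, folds, repetitions, n_lvs, rng
    )
    mean_r = np.nanmean(fold_r, axis=(0, 1))
    permuted_p = None
    if n_perm_cv and n_perm_cv > 0:
        exceed = np.zeros(n_lvs, dtype=int)
        for _ in range(n_perm_cv):
            perm = rng.permutation(n)
            r_p = _cv_fold_correlations(
                X_raw, Y_raw[perm], confounds, folds, perm_repetitions, n_lvs, rng
            )
            exceed += np.nanmean(r_p, axis=(0, 1)) >= mean_r
        permuted_p = (1.0 + exceed) / (n_perm_cv + 1.0)
    return CvResult(
        fold_correlations=fold_r,
        mean_test_r=mean_r,
        permuted_p=permuted_p,
        folds=folds,
        repetitions=repetitions,
        seed=seed,
    )


def project(
    model: PlsModel,
    X_new: np.ndarray,
    Y_new: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Project new data onto learned saliences; per-LV r with permuted p.

    The caller chooses the residualization/standardization policy for the new
    data. p-values come from shuffling the rows of ``Y_new`` (two-sided).
    """
    X_new = np.asarray(X_new, dtype=float)
    Y_new = np.asarray(Y_new, dtype=float)
    if X_new.shape[1] != model.saliences_x.shape[0]:
        raise SchemaError("X_new column count does not match the model")
    if Y_new.shape[1] != model.saliences_y.shape[0]:
        raise SchemaError("Y_new column count does not match the model")
    sx = X_new @ model.saliences_x
    sy = Y_new @ model.saliences_y
    r_obs = _pearson_columns(sx, sy)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(model.n_lvs, dtype=int)
    n = X_new.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += np.abs(_pearson_columns(sx, sy[perm])) >= np.abs(r_obs)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return {"composite_x": sx, "composite_y": sy, "r": r_obs, "p": p}


def compare_models(a: PlsModel, b: PlsModel, lv: int = 0) -> dict:
    """Correlations of saliences and loadings between two fits (sign-aligned)."""
    if a.saliences_x.shape[0] != b.saliences_x.shape[0] or (
        a.saliences_y.shape[0] != b.saliences_y.shape[0]
    ):
        raise SchemaError("models live in different feature spaces")
    if lv >= min(a.n_lvs, b.n_lvs):
        raise ValueError(f"lv={lv} out of range")
    sign = np.sign(a.saliences_y[:, lv] @ b.saliences_y[:, lv])
    if sign == 0:
        sign = 1.0

    def _r(u, v):
        return float(_pearson_columns(u[:, None], (sign * v)[:, None])[0])

    return {
        "salience_y_r": _r(a.saliences_y[:, lv], b.saliences_y[:, lv]),
        "salience_x_r": _r(a.saliences_x[:, lv], b.saliences_x[:, lv]),
        "loading_y_r": _r(a.loadings_y[:, lv], b.loadings_y[:, lv]),
        "loading_x_r": _r(a.loadings_x[:, lv], b.loadings_x[:, lv]),
        "sign": float(sign),
    }


def first_principal_component(
    Y: np.ndarray, salience: np.ndarray | None = None
) -> tuple[np.ndarray, float | None]:
    """Leading eigenvector of ``Y'Y/(n-1)`` and its correlation with a salience.

    The returned correlation is sign-aligned: the component is flipped so the
    correlation with the supplied salience is nonnegative.
    """
    Y = np.asarray(Y, dtype=float)
    yc = Y - Y.mean(axis=0)
    _, _, vt = np.linalg.svd(yc, full_matrices=False)
    pc = vt[0]
    if salience is None:
        return pc, None
    salience = np.asarray(salience, dtype=float)
    if salience.shape != pc.shape:
        raise SchemaError("salience length does not match the component")
    r = float(_pearson_columns(pc[:, None], salience[:, None])[0])
    if r < 0:
        pc = -pc
        r = -r
    return pc, r
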