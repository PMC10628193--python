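"""Confound residualization and standardization with strict train/test split.

A :class:`Residualizer` is always fitted on training subjects only and then
applied, with the *stored* parameters, to any other subjects. Fitting on the
full sample before splitting leaks test information into the model and
inflates cross-validated effect sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .io_model import SchemaError

__all__ = [
    "CollinearityError",
    "Residualizer",
    "fit_residualizer",
    "apply_residualizer",
    "quantile_normalize",
]

_CONST_TOL = 1e-12


class CollinearityError(ValueError):
    """The confound design matrix is rank deficient."""


@dataclass
class Residualizer:
    """OLS confound fit plus post-residual standardization statistics."""

    coefficients: np.ndarray  # (Q+1, M): intercept row then per-confound slopes
    column_means: np.ndarray  # (M,) training residual means
    column_sds: np.ndarray  # (M,) training residual SDs (1.0 where constant)
    constant_columns: np.ndarray  # (M,) bool
    fitted_on: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        self.constant_columns = np.asarray(self.constant_columns, dtype=bool)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("residualizer coefficients must be finite")
        if np.any(self.column_sds <= 0):
            raise ValueError("stored column SDs must be positive")

    @property
    def n_confounds(self) -> int:
        return self.coefficients.shape[0] - 1

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coefficients": self.coefficients.tolist(),
                    "column_means": self.column_means.tolist(),
                    "column_sds": self.column_sds.tolist(),
                    "constant_columns": self.constant_columns.tolist(),
                    "fitted_on": self.fitted_on,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "Residualizer":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.array(d["coefficients"]),
            column_means=np.array(d["column_means"]),
            column_sds=np.array(d["column_sds"]),
            constant_columns=np.array(d["constant_columns"], dtype=bool),
            fitted_on=int(d["fitted_on"]),
        )


def _design(confounds: np.ndarray | None, n: int) -> np.ndarray:
    if confounds is None:
        return np.ones((n, 1))
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise SchemaError("confound rows do not match data rows")
    return np.column_stack([np.ones(n), c])


def fit_residualizer(data: np.ndarray, confounds: np.ndarray | None) -> Residualizer:
    """Per-column OLS of ``data`` on ``[1 | confounds]``; stores residual stats."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    design = _design(confounds, n)
    q1 = design.shape[1]
    if n <= q1:
        raise ValueError(f"need more subjects ({n}) than confounds + 1 ({q1})")
    rank = np.linalg.matrix_rank(design)
    if rank < q1:
        offending = [
            j - 1
            for j in range(1, q1)
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise CollinearityError(
            f"confound design is rank deficient; redundant confound column(s) "
            f"{offending}"
        )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    means = resid.mean(axis=0)
    sds = resid.std(axis=0, ddof=1)
    constant = sds < _CONST_TOL
    sds = np.where(constant, 1.0, sds)
    return Residualizer(
        coefficients=coef,
        column_means=means,
        column_sds=sds,
        constant_columns=constant,
        fitted_on=n,
    )


def apply_residualizer(
    model: Residualizer,
    data: np.ndarray,
    confounds: np.ndarray | None,
    standardize: bool = True,
) -> np.ndarray:
    """Residualize (and by default standardize) using only stored parameters."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != model.coefficients.shape[1]:
        raise SchemaError(
            f"data has {x.shape[1]} columns but residualizer was fitted on "
            f"{model.coefficients.shape[1]}"
        )
    design = _design(confounds, x.shape[0])
    if design.shape[1] != model.coefficients.shape[0]:
        raise SchemaError(
            f"got {design.shape[1] - 1} confounds, residualizer expects "
            f"{model.n_confounds}"
        )
    resid = x - design @ model.coefficients
    if not standardize:
        return resid
    return (resid - model.column_means) / model.column_sds


def quantile_normalize(data: np.ndarray) -> np.ndarray:
    """Map each column by rank onto standard-normal quantiles.

    Ranks use midpoints ``(rank - 0.5) / n``; ties get the mean of their tied
    positions. Constant columns are flagged with a warning and returned as
    zeros.
    """
    x = np.asarray(data, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 3:
        raise ValueError("quantile normalization needs at least 3 subjects")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if col.std() < _CONST_TOL:
            warnings.warn(f"column {j} is constant; quantile-normalized to zeros")
            out[:, j] = 0.0
            continue
        ranks = rankdata(col, method="average")
        out[:, j] = ndtri((ranks - 0.5) / n)
    return out[:, 0] if squeeze else out
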