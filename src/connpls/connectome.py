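"""Subject-level edge construction: correlation, Fisher z, vectorization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import count_edges, n_regions_from_edges

__all__ = [
    "DegenerateSignalError",
    "ParcellatedTimeseries",
    "compute_fc",
    "fisher_z",
    "vectorize_fc",
    "devectorize_fc",
]

_CLIP = 1.0 - 1e-7


class DegenerateSignalError(ValueError):
    """A region's time course is constant, so its correlations are undefined."""


@dataclass
class ParcellatedTimeseries:
    """Timepoints x regions matrix of mean regional signals.

    ``tr`` (repetition time, seconds) is carried as metadata only.
    """

    values: np.ndarray
    tr: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("time series must be 2-D with at least 3 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series must be finite")
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            raise DegenerateSignalError(
                f"constant time course for region(s) {bad.tolist()}"
            )


def compute_fc(ts: ParcellatedTimeseries) -> np.ndarray:
    """Pairwise Pearson correlation matrix between regional time courses."""
    if not isinstance(ts, ParcellatedTimeseries):
        ts = ParcellatedTimeseries(np.asarray(ts))
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r, clip: bool = False):
    """Fisher r-to-z transform, z = atanh(r), elementwise.

    ``|r| = 1`` is a hard error by default: a perfect correlation almost always
    means a duplicated region. With ``clip=True`` inputs are clamped to
    ``|r| <= 1 - 1e-7`` instead.
    """
    arr = np.asarray(r, dtype=float)
    if clip:
        arr = np.clip(arr, -_CLIP, _CLIP)
    elif np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| >= 1 encountered (pass clip=True to clamp)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def vectorize_fc(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle (row-major, diagonal excluded) vector of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=atol, rtol=0):
        raise ValueError(f"matrix asymmetry exceeds tolerance {atol}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize_fc(vec: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`; diagonal filled with ``diagonal``."""
    v = np.asarray(vec, dtype=float).ravel()
    n = n_regions_from_edges(v.size)
    assert count_edges(n) == v.size
    m = np.full((n, n), 0.0)
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m
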