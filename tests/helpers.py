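"""Independent oracles used by the test suite.

These deliberately avoid the code paths they are checking: the PLS oracle is
a dense grid search on the unit sphere, not an eigendecomposition.
"""

import numpy as np


def sphere_grid(dim: int, step_deg: float) -> np.ndarray:
    """All unit vectors on S^{dim-1} from a spherical-coordinate angle grid."""
    if dim == 1:
        return np.array([[1.0], [-1.0]])
    polar = [np.arange(0.0, 180.0, step_deg)] * (dim - 2)
    azimuth = [np.arange(0.0, 360.0, step_deg)]
    grids = np.meshgrid(*(polar + azimuth), indexing="ij")
    angles = np.stack([g.ravel() for g in grids], axis=1)
    return _angles_to_unit(np.deg2rad(angles))


def _angles_to_unit(angles: np.ndarray) -> np.ndarray:
    m, k = angles.shape
    out = np.ones((m, k + 1))
    for j in range(k):
        out[:, j] *= np.cos(angles[:, j])
        out[:, j + 1 :] *= np.sin(angles[:, j])[:, None]
    return out


def grid_search_max_covariance(r: np.ndarray, coarse_deg: float = 4.0, fine_deg: float = 0.2):
    """Maximize u'Rv over unit u, v by gridding u and taking v = R'u/||R'u||.

    ``r`` is the (P, E) cross-covariance with P <= 4; the grid runs over the
    small behaviour side, coarse-to-fine. Returns (max_value, u, v).
    """
    p = r.shape[0]

    def _best(candidates: np.ndarray):
        norms = np.linalg.norm(candidates @ r, axis=1)
        k = int(np.argmax(norms))
        return norms[k], candidates[k]

    val, u = _best(sphere_grid(p, coarse_deg))
    # local refinement: perturb the best direction along tangent grid steps
    if p > 1:
        offsets = np.deg2rad(np.arange(-coarse_deg, coarse_deg + fine_deg / 2, fine_deg))
        basis = _tangent_basis(u)
        grids = np.meshgrid(*([offsets] * (p - 1)), indexing="ij")
        t = np.stack([g.ravel() for g in grids], axis=1)
        cand = u[None, :] + t @ basis
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        val2, u2 = _best(np.vstack([u[None, :], cand]))
        if val2 > val:
            val, u = val2, u2
    ru = r.T @ u
    v = ru / np.linalg.norm(ru)
    return val, u, v


def _tangent_basis(v: np.ndarray) -> np.ndarray:
    p = v.size
    a = np.eye(p) - np.outer(v, v)
    q, _ = np.linalg.qr(a)
    cols = [q[:, j] for j in range(p) if abs(np.dot(q[:, j], v)) < 0.99]
    return np.array(cols[: p - 1])


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))
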