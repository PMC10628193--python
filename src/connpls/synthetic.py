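"""Synthetic cohorts with planted latent structure, annotation maps, groups.

Cohorts are generated directly at the edge-matrix level: a single latent score
per subject loads onto a sparse support of edges and behaviours, so the target
latent correlation is exact analytically and every downstream stage can be
tested against known ground truth. No time-series simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_model import BehaviorTable, EdgeMatrix, RegionTable, count_edges

__all__ = [
    "SyntheticCohort",
    "TwoGroupCohort",
    "generate_cohort",
    "generate_annotation_map",
    "generate_two_group_cohort",
    "make_region_table",
]

_NETWORKS = [
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "subcortical",
]


@dataclass
class SyntheticCohort:
    """Edge + behaviour blocks sharing one planted latent dimension."""

    edges: EdgeMatrix
    behavior: BehaviorTable
    true_salience_x: np.ndarray  # unit vector, length E
    true_salience_y: np.ndarray  # unit vector, length P
    latent_scores: np.ndarray  # (n,) planted subject scores
    latent_strength: float
    confound_effects_x: np.ndarray
    confound_effects_y: np.ndarray
    seed: int

    @property
    def true_score_x(self) -> np.ndarray:
        return self.edges.values @ self.true_salience_x

    @property
    def true_score_y(self) -> np.ndarray:
        return self.behavior.values @ self.true_salience_y


@dataclass
class TwoGroupCohort:
    """Edge matrix for two groups shifted along the planted latent dimension."""

    edges: EdgeMatrix
    labels: np.ndarray  # (n,) 0/1
    true_salience_x: np.ndarray
    group_shift: float
    seed: int


def _sparse_unit_vector(size: int, support_fraction: float, rng: np.random.Generator) -> np.ndarray:
    if not 0 < support_fraction <= 1:
        raise ValueError("support fraction must be in (0, 1]")
    k = max(1, int(np.ceil(support_fraction * size)))
    v = np.zeros(size)
    idx = rng.choice(size, size=k, replace=False)
    vals = rng.standard_normal(k)
    while np.linalg.norm(vals) == 0:  # pragma: no cover - probability zero
        vals = rng.standard_normal(k)
    v[idx] = vals / np.linalg.norm(vals)
    return v


def _confound_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    # two continuous + two binary columns, mirroring age/FD + sex/handedness
    cont = rng.standard_normal((n, 2))
    binary = (rng.random((n, 2)) < 0.5).astype(float)
    return np.column_stack([cont, binary])


def _latent_amplitude(latent_strength: float, noise_sd: float) -> float:
    # corr(a z + e1, a z + e2) = a^2 / (a^2 + noise_sd^2) for independent
    # unit-variance z and N(0, noise_sd^2) projections of the noise
    if latent_strength == 0:
        return 0.0
    if latent_strength == 1:
        return 1.0  # noise is orthogonalized to the planted directions below
    return noise_sd * np.sqrt(latent_strength / (1.0 - latent_strength))


def generate_cohort(
    n_subjects: int,
    n_regions: int,
    n_behav: int,
    latent_strength: float = 0.5,
    support_fraction_x: float = 0.25,
    support_fraction_y: float = 0.5,
    confound_effects: tuple | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate paired edge/behaviour blocks with one shared latent factor.

    Each subject draws a latent score ``z ~ N(0,1)``; ``X = a z u' + C g_x m_x'
    + noise`` and ``Y = b z v' + C g_y m_y' + noise`` with sparse unit vectors
    ``u, v`` and amplitudes chosen so that ``corr(X u, Y v)`` equals
    ``latent_strength`` in expectation. Confound directions are orthogonalized
    to the planted saliences so contamination never masquerades as signal.
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    if n_regions < 3 or n_behav < 2:
        raise ValueError("degenerate cohort sizes")
    if not 0 <= latent_strength <= 1:
        raise ValueError("latent_strength must be in [0, 1]")
    if not np.isfinite(noise_sd) or noise_sd <= 0:
        raise ValueError("noise_sd must be positive and finite")
    rng = np.random.default_rng(seed)
    n_edges = count_edges(n_regions)

    u = _sparse_unit_vector(n_edges, support_fraction_x, rng)
    v = _sparse_unit_vector(n_behav, support_fraction_y, rng)
    z = rng.standard_normal(n_subjects)
    a = _latent_amplitude(latent_strength, noise_sd)

    confounds = _confound_matrix(n_subjects, rng)
    if confound_effects is None:
        gx = np.zeros(confounds.shape[1])
        gy = np.zeros(confounds.shape[1])
    else:
        ce = np.asarray(confound_effects, dtype=float)
        if ce.ndim == 1:
            gx = gy = ce
        else:
            gx, gy = ce[0], ce[1]
        if gx.shape != (confounds.shape[1],):
            raise ValueError(
                f"confound_effects must have {confounds.shape[1]} entries per block"
            )

    def _contamination_direction(size: int, planted: np.ndarray) -> np.ndarray:
        d = rng.standard_normal(size)
        d -= (d @ planted) * planted
        return d / np.linalg.norm(d)

    mx = _contamination_direction(n_edges, u)
    my = _contamination_direction(n_behav, v)

    ex = rng.standard_normal((n_subjects, n_edges)) * noise_sd
    ey = rng.standard_normal((n_subjects, n_behav)) * noise_sd
    if latent_strength == 1:
        ex -= np.outer(ex @ u, u)
        ey -= np.outer(ey @ v, v)

    x = a * np.outer(z, u) + np.outer(confounds @ gx, mx) + ex
    y = a * np.outer(z, v) + np.outer(confounds @ gy, my) + ey

    ids = [f"sub-{k:04d}" for k in range(n_subjects)]
    edges = EdgeMatrix(values=x, subject_ids=ids, n_regions=n_regions)
    behavior = BehaviorTable(
        values=y,
        measure_names=[f"behav_{j}" for j in range(n_behav)],
        subject_ids=ids,
        confounds=confounds,
        confound_names=["age", "mean_fd", "sex", "handedness"],
    )
    return SyntheticCohort(
        edges=edges,
        behavior=behavior,
        true_salience_x=u,
        true_salience_y=v,
        latent_scores=z,
        latent_strength=float(latent_strength),
        confound_effects_x=gx,
        confound_effects_y=gy,
        seed=int(seed),
    )


def make_region_table(n_regions: int, n_networks: int = 8, box_mm: float = 140.0, seed: int = 0) -> RegionTable:
    """Random region metadata: uniform centroids in a box, cyclic network labels."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    nets = [_NETWORKS[k % len(_NETWORKS)] for k in range(n_networks)]
    return RegionTable(
        region_id=np.arange(n_regions),
        name=[f"region_{k}" for k in range(n_regions)],
        network=[nets[k % n_networks] for k in range(n_regions)],
        hemisphere=["L" if k % 2 == 0 else "R" for k in range(n_regions)],
        centroid=rng.uniform(-box_mm / 2, box_mm / 2, size=(n_regions, 3)),
    )


def generate_annotation_map(
    regions: RegionTable, correlation_length: float, seed: int = 0
):
    """Draw a spatially autocorrelated per-region map over the centroids.

    Gaussian process with squared-exponential kernel
    ``exp(-d^2 / (2 L^2))``; the draw is standardized to zero mean and unit
    variance across regions.
    """
    from .annotation import AnnotationMap  # local import to avoid a cycle

    if regions.n_regions < 3:
        raise ValueError("need at least 3 regions for an annotation map")
    if not np.isfinite(correlation_length) or correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    d = squareform(pdist(regions.centroid))
    k = np.exp(-(d**2) / (2.0 * correlation_length**2))
    k[np.diag_indices_from(k)] += 1e-8
    chol = np.linalg.cholesky(k)
    vals = chol @ rng.standard_normal(regions.n_regions)
    vals = (vals - vals.mean()) / vals.std()
    return AnnotationMap(
        values=vals,
        name=f"synthetic_gp_L{correlation_length:g}",
        source={"generator": "squared_exponential_gp", "seed": int(seed)},
    )


def generate_two_group_cohort(
    n_per_group: int,
    n_regions: int,
    group_shift: float,
    support_fraction_x: float = 0.25,
    noise_sd: float = 1.0,
    latent_sd: float = 1.0,
    seed: int = 0,
) -> TwoGroupCohort:
    """Two groups of subjects whose latent scores differ by ``group_shift``."""
    if n_per_group < 5:
        raise ValueError("need at least 5 subjects per group")
    if n_regions < 3:
        raise ValueError("degenerate region count")
    rng = np.random.default_rng(seed)
    n_edges = count_edges(n_regions)
    u = _sparse_unit_vector(n_edges, support_fraction_x, rng)
    n = 2 * n_per_group
    labels = np.repeat([0, 1], n_per_group)
    z = rng.standard_normal(n) * latent_sd + group_shift * labels
    x = np.outer(z, u) + rng.standard_normal((n, n_edges)) * noise_sd
    ids = [f"sub-{k:04d}" for k in range(n)]
    return TwoGroupCohort(
        edges=EdgeMatrix(values=x, subject_ids=ids, n_regions=n_regions),
        labels=labels,
        true_salience_x=u,
        group_shift=float(group_shift),
        seed=int(seed),
    )
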