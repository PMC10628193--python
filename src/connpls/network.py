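"""Edge thresholding, network block averages, and region importance scores."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm, t as t_dist

from .io_model import RegionTable, SchemaError, count_edges, n_regions_from_edges

__all__ = [
    "EdgeSignificanceMap",
    "RegionImportance",
    "loading_pvalues",
    "threshold_edges",
    "threshold_edges_by_z",
    "summarize_mask",
    "summarize_counts",
    "network_block_average",
    "region_importance",
    "top_nodes",
]


@dataclass
class EdgeSignificanceMap:
    loading: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    mask: np.ndarray  # bool
    sign: np.ndarray  # {+1, -1, 0}

    def __post_init__(self) -> None:
        for name in ("loading", "p_value", "q_value"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sign = np.asarray(self.sign, dtype=int)
        sizes = {v.size for v in (self.loading, self.p_value, self.q_value, self.mask, self.sign)}
        if len(sizes) != 1:
            raise ValueError("edge map vectors must have equal lengths")

    @property
    def n_edges(self) -> int:
        return self.loading.size


@dataclass
class RegionImportance:
    positive_score: np.ndarray  # sum of |loading| over significant positive edges
    negative_score: np.ndarray  # likewise for negative edges (magnitudes)
    degree_pos: np.ndarray  # significant positive edge counts per region
    degree_neg: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.positive_score.size


def loading_pvalues(loading: np.ndarray, n_subjects: int) -> np.ndarray:
    """Two-sided p-values for loadings treated as Pearson correlations."""
    r = np.clip(np.asarray(loading, dtype=float), -1.0, 1.0)
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation test")
    df = n_subjects - 2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        tval = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * t_dist.sf(np.abs(tval), df)


def threshold_edges(
    loading: np.ndarray, p_value: np.ndarray, q_threshold: float = 0.05
) -> EdgeSignificanceMap:
    """Benjamini-Hochberg across all edges; mask and signed loadings."""
    loading = np.asarray(loading, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if loading.shape != p.shape:
        raise ValueError("loading and p-value vectors must have equal lengths")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = false_discovery_control(p, method="bh")
    mask = q <= q_threshold
    sign = np.where(mask, np.sign(loading).astype(int), 0)
    return EdgeSignificanceMap(loading=loading, p_value=p, q_value=q, mask=mask, sign=sign)


def threshold_edges_by_z(
    loading: np.ndarray, bootstrap_z: np.ndarray, z_threshold: float = 3.0
) -> EdgeSignificanceMap:
    """Alternative mode: threshold on bootstrap |z|; same map shape.

    Normal-approximation p-values are attached for reporting; the mask itself
    is ``|z| >= z_threshold``.
    """
    loading = np.asarray(loading, dtype=float)
    z = np.asarray(bootstrap_z, dtype=float)
    if loading.shape != z.shape:
        raise ValueError("loading and z vectors must have equal lengths")
    p = 2.0 * norm.sf(np.abs(np.nan_to_num(z, posinf=np.inf)))
    q = false_discovery_control(np.clip(p, 0, 1), method="bh")
    mask = np.abs(z) >= z_threshold
    sign = np.where(mask, np.sign(loading).astype(int), 0)
    return EdgeSignificanceMap(loading=loading, p_value=p, q_value=q, mask=mask, sign=sign)


def _pct(count: int, total: int) -> float:
    # half-up rounding to 2 decimals for report parity
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_counts(n_pos: int, n_neg: int, n_total: int) -> dict:
    """Counts and half-up two-decimal percentages of significant edges."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    n_sig = int(n_pos) + int(n_neg)
    return {
        "n_sig": n_sig,
        "n_pos": int(n_pos),
        "n_neg": int(n_neg),
        "n_total": int(n_total),
        "pct_sig": _pct(n_sig, n_total),
        "pct_pos": _pct(int(n_pos), n_total),
        "pct_neg": _pct(int(n_neg), n_total),
    }


def summarize_mask(edge_map: EdgeSignificanceMap, n_total_edges: int | None = None) -> dict:
    """Summary of a significance map: counts and percentages of the total."""
    if n_total_edges is None:
        n_total_edges = edge_map.n_edges
    n_pos = int(np.sum(edge_map.mask & (edge_map.sign > 0)))
    n_neg = int(np.sum(edge_map.mask & (edge_map.sign < 0)))
    return summarize_counts(n_pos, n_neg, n_total_edges)


def network_block_average(
    edge_values: np.ndarray,
    regions: RegionTable,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean edge value per within/between-network block (NaN when empty).

    ``edge_values`` follows the canonical edge order; with ``mask``, only
    selected edges enter the averages.
    """
    v = np.asarray(edge_values, dtype=float)
    n = regions.n_regions
    if v.size != count_edges(n):
        raise SchemaError(
            f"edge vector length {v.size} does not match {n} regions"
        )
    labels = np.asarray(regions.network)
    nets = regions.networks
    net_idx = {lbl: k for k, lbl in enumerate(nets)}
    iu, ju = np.triu_indices(n, k=1)
    a = np.array([net_idx[labels[i]] for i in iu])
    b = np.array([net_idx[labels[j]] for j in ju])
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    keep = np.ones(v.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    m = len(nets)
    out = np.full((m, m), np.nan)
    for p in range(m):
        for q in range(p, m):
            sel = keep & (lo == p) & (hi == q)
            if sel.any():
                out[p, q] = out[q, p] = v[sel].mean()
    return pd.DataFrame(out, index=nets, columns=nets)


def region_importance(edge_map: EdgeSignificanceMap, n_regions: int | None = None) -> RegionImportance:
    """Signed weighted degree: each significant edge contributes ``|loading|``
    to both endpoints' positive or negative score according to its sign."""
    if n_regions is None:
        n_regions = n_regions_from_edges(edge_map.n_edges)
    if count_edges(n_regions) != edge_map.n_edges:
        raise ValueError("edge map length inconsistent with n_regions")
    iu, ju = np.triu_indices(n_regions, k=1)
    pos = edge_map.mask & (edge_map.sign > 0)
    neg = edge_map.mask & (edge_map.sign < 0)
    w = np.abs(edge_map.loading)
    pos_score = np.bincount(iu[pos], w[pos], n_regions) + np.bincount(ju[pos], w[pos], n_regions)
    neg_score = np.bincount(iu[neg], w[neg], n_regions) + np.bincount(ju[neg], w[neg], n_regions)
    deg_pos = np.bincount(iu[pos], minlength=n_regions) + np.bincount(ju[pos], minlength=n_regions)
    deg_neg = np.bincount(iu[neg], minlength=n_regions) + np.bincount(ju[neg], minlength=n_regions)
    return RegionImportance(
        positive_score=pos_score,
        negative_score=neg_score,
        degree_pos=deg_pos.astype(int),
        degree_neg=deg_neg.astype(int),
    )


def top_nodes(
    importance: RegionImportance,
    k: int = 5,
    side: str = "positive",
    by: str = "weight",
) -> np.ndarray:
    """Region ids ranked descending by score; ties broken by id ascending.

    ``by='weight'`` ranks by summed |loading| (default); ``by='count'`` ranks
    by significant-edge counts.
    """
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    if by not in ("weight", "count"):
        raise ValueError("by must be 'weight' or 'count'")
    if side == "positive":
        score = importance.positive_score if by == "weight" else importance.degree_pos
    else:
        score = importance.negative_score if by == "weight" else importance.degree_neg
    n = score.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of regions ({n})")
    order = np.lexsort((np.arange(n), -np.asarray(score, dtype=float)))
    return order[:k]
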