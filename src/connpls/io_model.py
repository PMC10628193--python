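"""Data model and I/O for region metadata, connectivity and behaviour tables.

Defines the canonical edge indexing used by every downstream stage: the strict
upper triangle of the region-by-region matrix, diagonal excluded, enumerated
row-major with 0-based region ids — ``(0,1), (0,2), ..., (0,n-1), (1,2), ...``.
Saved loading vectors are portable only under this fixed convention.
"""

from __future__ import annotations

import json
import numbers
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "AlignmentError",
    "RegionTable",
    "EdgeMatrix",
    "BehaviorTable",
    "count_edges",
    "edge_index",
    "edge_pair",
    "n_regions_from_edges",
    "read_region_table",
    "write_region_table",
    "read_edge_matrix",
    "write_edge_matrix",
    "read_behavior_table",
    "write_behavior_table",
    "read_square_matrix",
    "align_tables",
    "write_result",
    "read_result",
]

_HEMISPHERES = {"L", "R", "NA"}


class SchemaError(ValueError):
    """A table violates the declared column/row schema."""


class AlignmentError(ValueError):
    """Paired tables disagree on subject identity or order."""


def _check_region_count(n_regions) -> int:
    if isinstance(n_regions, bool) or not isinstance(n_regions, numbers.Integral):
        raise TypeError(f"n_regions must be an integer, got {n_regions!r}")
    n = int(n_regions)
    if n < 1:
        raise ValueError(f"n_regions must be >= 1, got {n}")
    return n


def count_edges(n_regions) -> int:
    """Number of unique undirected edges among ``n_regions`` nodes: n(n-1)/2."""
    n = _check_region_count(n_regions)
    return n * (n - 1) // 2


def n_regions_from_edges(n_edges: int) -> int:
    """Invert :func:`count_edges`; raises if ``n_edges`` is not triangular."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if count_edges(max(n, 1)) != n_edges:
        raise ValueError(f"{n_edges} is not n(n-1)/2 for any integer n")
    return n


def _row_offset(i: int, n: int) -> int:
    # index of edge (i, i+1) in the canonical order
    return i * n - i * (i + 1) // 2


def edge_index(i, j, n_regions) -> int:
    """Canonical position of edge ``(i, j)`` in the row-major upper triangle."""
    n = _check_region_count(n_regions)
    for name, v in (("i", i), ("j", j)):
        if isinstance(v, bool) or not isinstance(v, numbers.Integral):
            raise TypeError(f"{name} must be an integer, got {v!r}")
    i, j = int(i), int(j)
    if not (0 <= i < j < n):
        raise ValueError(f"require 0 <= i < j < n_regions, got (i={i}, j={j}, n={n})")
    return _row_offset(i, n) + (j - i - 1)


def edge_pair(k, n_regions) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: region pair at canonical position ``k``."""
    n = _check_region_count(n_regions)
    if isinstance(k, bool) or not isinstance(k, numbers.Integral):
        raise TypeError(f"k must be an integer, got {k!r}")
    k = int(k)
    e = count_edges(n)
    if not (0 <= k < e):
        raise ValueError(f"edge position {k} out of range [0, {e})")
    offsets = np.array([_row_offset(i, n) for i in range(n - 1)])
    i = int(np.searchsorted(offsets, k, side="right") - 1)
    j = k - _row_offset(i, n) + i + 1
    return i, j


@dataclass
class RegionTable:
    """Per-region metadata defining edge order and network blocks."""

    region_id: np.ndarray
    name: list[str]
    network: list[str]
    hemisphere: list[str]
    centroid: np.ndarray  # (N, 3) millimetres

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        self.centroid = np.asarray(self.centroid, dtype=float)
        n = self.region_id.size
        if len(set(self.region_id.tolist())) != n:
            raise SchemaError("duplicate region_id values")
        if not np.array_equal(np.sort(self.region_id), np.arange(n)):
            raise SchemaError("region_id must be contiguous 0..N-1")
        if len(self.name) != n or len(self.network) != n or len(self.hemisphere) != n:
            raise SchemaError("region table columns have unequal lengths")
        if any(not str(lbl).strip() for lbl in self.network):
            raise SchemaError("network labels must be non-empty")
        bad = set(self.hemisphere) - _HEMISPHERES
        if bad:
            raise SchemaError(f"hemisphere labels must be in {_HEMISPHERES}, got {bad}")
        if self.centroid.shape != (n, 3) or not np.all(np.isfinite(self.centroid)):
            raise SchemaError("centroids must be a finite (N, 3) array")
        # store in region_id order
        order = np.argsort(self.region_id)
        self.region_id = self.region_id[order]
        self.name = [self.name[k] for k in order]
        self.network = [self.network[k] for k in order]
        self.hemisphere = [self.hemisphere[k] for k in order]
        self.centroid = self.centroid[order]

    @property
    def n_regions(self) -> int:
        return self.region_id.size

    @property
    def networks(self) -> list[str]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lbl in self.network:
            seen.setdefault(lbl, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "name": self.name,
                "network": self.network,
                "hemisphere": self.hemisphere,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionTable":
        required = {"region_id", "name", "network", "hemisphere", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"region table missing columns: {sorted(missing)}")
        return cls(
            region_id=df["region_id"].to_numpy(),
            name=[str(v) for v in df["name"]],
            network=[str(v) for v in df["network"]],
            hemisphere=[str(v) for v in df["hemisphere"]],
            centroid=df[["x", "y", "z"]].to_numpy(dtype=float),
        )


@dataclass
class EdgeMatrix:
    """Subjects x edges block of Fisher-z connectivity values (the X block)."""

    values: np.ndarray
    subject_ids: list[str]
    n_regions: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("edge values must be 2-D (subjects x edges)")
        if self.n_regions == 0:
            self.n_regions = n_regions_from_edges(self.values.shape[1])
        if count_edges(self.n_regions) != self.values.shape[1]:
            raise SchemaError(
                f"{self.values.shape[1]} edges is inconsistent with "
                f"{self.n_regions} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("edge values must be finite")
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.values.shape[0]:
            raise SchemaError("subject_ids length does not match row count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise SchemaError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


@dataclass
class BehaviorTable:
    """Subjects x measures behaviour block plus optional confound columns."""

    values: np.ndarray
    measure_names: list[str]
    subject_ids: list[str]
    confounds: np.ndarray | None = None
    confound_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise SchemaError("behaviour values must be 2-D with P >= 2 measures")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(
                "behaviour values contain missing/non-finite entries; "
                "impute or drop before constructing the table"
            )
        if len(self.measure_names) != self.values.shape[1]:
            raise SchemaError("measure_names length does not match column count")
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.values.shape[0]:
            raise SchemaError("subject_ids length does not match row count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise SchemaError("subject_ids must be unique")
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.shape[0] != self.values.shape[0]:
                raise SchemaError("confound rows do not match behaviour rows")
            if not np.all(np.isfinite(self.confounds)):
                raise SchemaError("confound values must be finite")
            if len(self.confound_names) != self.confounds.shape[1]:
                raise SchemaError("confound_names length does not match columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_measures(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# readers / writers (TSV with header row; JSON for result artifacts)
# ---------------------------------------------------------------------------

def read_region_table(path) -> RegionTable:
    df = pd.read_csv(path, sep="\t")
    return RegionTable.from_dataframe(df)


def write_region_table(regions: RegionTable, path) -> None:
    regions.to_dataframe().to_csv(path, sep="\t", index=False)


def read_edge_matrix(path) -> EdgeMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError("edge matrix file must have a 'subject_id' column")
    ids = [str(s) for s in df["subject_id"]]
    values = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
    return EdgeMatrix(values=values, subject_ids=ids)


def write_edge_matrix(edges: EdgeMatrix, path) -> None:
    cols = [f"e{k}" for k in range(edges.n_edges)]
    df = pd.DataFrame(edges.values, columns=cols)
    df.insert(0, "subject_id", edges.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_behavior_table(path, confounds_path=None, impute_missing: bool = False) -> BehaviorTable:
    """Read a behaviour TSV (and optional confound TSV) keyed by subject_id.

    Missing values are rejected by default; with ``impute_missing`` they are
    replaced by the column mean and a warning is emitted.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError("behaviour file must have a 'subject_id' column")
    ids = [str(s) for s in df["subject_id"]]
    data = df.drop(columns=["subject_id"])
    if data.isna().any().any():
        if not impute_missing:
            raise SchemaError(
                "behaviour table contains missing values "
                "(pass impute_missing=True to column-mean impute)"
            )
        warnings.warn("imputing missing behaviour values with column means")
        data = data.fillna(data.mean())
    confounds = None
    confound_names: list[str] = []
    if confounds_path is not None:
        cdf = pd.read_csv(confounds_path, sep="\t", float_precision="round_trip")
        if "subject_id" not in cdf.columns:
            raise SchemaError("confound file must have a 'subject_id' column")
        cids = [str(s) for s in cdf["subject_id"]]
        if cids != ids:
            raise AlignmentError("confound subject_ids do not match behaviour rows")
        confound_names = [c for c in cdf.columns if c != "subject_id"]
        confounds = cdf[confound_names].to_numpy(dtype=float)
    return BehaviorTable(
        values=data.to_numpy(dtype=float),
        measure_names=list(data.columns),
        subject_ids=ids,
        confounds=confounds,
        confound_names=confound_names,
    )


def write_behavior_table(behavior: BehaviorTable, path, confounds_path=None) -> None:
    df = pd.DataFrame(behavior.values, columns=behavior.measure_names)
    df.insert(0, "subject_id", behavior.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if confounds_path is not None and behavior.confounds is not None:
        cdf = pd.DataFrame(behavior.confounds, columns=behavior.confound_names)
        cdf.insert(0, "subject_id", behavior.subject_ids)
        cdf.to_csv(confounds_path, sep="\t", index=False, float_format="%.17g")


def read_square_matrix(path) -> np.ndarray:
    """Read an N x N whitespace-delimited square matrix (no header)."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SchemaError(f"expected a square matrix, got shape {m.shape}")
    return m


def align_tables(edges: EdgeMatrix, behavior: BehaviorTable) -> BehaviorTable:
    """Reorder ``behavior`` rows to the edge matrix's subject order, by id."""
    if set(edges.subject_ids) != set(behavior.subject_ids):
        missing = set(edges.subject_ids) ^ set(behavior.subject_ids)
        raise AlignmentError(
            f"subject sets differ between edge and behaviour tables: {sorted(missing)[:5]}"
        )
    if edges.subject_ids == behavior.subject_ids:
        return behavior
    pos = {s: k for k, s in enumerate(behavior.subject_ids)}
    order = np.array([pos[s] for s in edges.subject_ids])
    return BehaviorTable(
        values=behavior.values[order],
        measure_names=behavior.measure_names,
        subject_ids=list(edges.subject_ids),
        confounds=None if behavior.confounds is None else behavior.confounds[order],
        confound_names=behavior.confound_names,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_result(artifact, path) -> None:
    """Write a result artifact (dict or dataclass with ``to_dict``) as JSON."""
    if hasattr(artifact, "to_dict"):
        artifact = artifact.to_dict()
    Path(path).write_text(json.dumps(artifact, cls=_NumpyEncoder, indent=1))


def read_result(path) -> dict:
    return json.loads(Path(path).read_text())
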