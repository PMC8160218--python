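"""k-nearest-neighbor distance statistics between marker-positive cell sets.

For each cell positive for a query marker, the Euclidean distances to its
k nearest cells positive for a reference marker are averaged; pooling
over query cells gives the directed mean k-NN distance between the two
markers (k = 10 by default, matching the ten-neighbor convention).
Intra-/inter-cluster summaries restrict or pool these pairwise means by
anatomical cluster. The proximity fraction is the k = 1 special case with
a physical cutoff (30 µm by default).

Distances are computed in pixel units and reported in µm via the point
set's ``pixel_size_um``. When query and reference are the same marker,
exact self-pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import EmptyInputError
from .io_formats import CellTable
from .single_cell_quant import PositivityTable

__all__ = [
    "PointSet",
    "DistanceSummary",
    "points_by_marker",
    "knn_mean_distance",
    "marker_pair_distance_matrix",
    "intra_cluster_distances",
    "inter_cluster_distance",
    "proximity_fraction",
]


@dataclass
class PointSet:
    """Centroids of the cells positive for one marker."""

    marker_name: str
    centroids: np.ndarray  # (n, 2) (row, col) pixel coordinates
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError(f"{self.marker_name}: non-finite centroid coordinates")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class DistanceSummary:
    marker_pair: tuple[str, str]  # (query, reference), directed
    k_used: int
    mean_knn_distance_um: float
    n_query_cells: int
    fraction_below_cutoff: float | None = None
    cutoff_um: float | None = None


def points_by_marker(
    cells: CellTable, positivity: PositivityTable
) -> dict[str, PointSet]:
    """One PointSet per marker: centroids of its positive cells."""
    centroids = cells.centroids()
    out = {}
    for m in positivity.markers:
        sel = positivity.expressed[m].to_numpy()
        out[m] = PointSet(m, centroids[sel], cells.pixel_size_um)
    return out


def _knn_distances_px(
    query: PointSet, reference: PointSet, k: int
) -> tuple[np.ndarray, int]:
    """(n_query, k_used) sorted neighbor distances in pixels, excluding
    exact self-pairs when query and reference are the same marker."""
    if len(query) == 0:
        raise EmptyInputError(f"marker {query.marker_name!r} has no positive cells")
    if len(reference) == 0:
        raise EmptyInputError(f"marker {reference.marker_name!r} has no positive cells")
    same_set = query.marker_name == reference.marker_name and len(query) == len(
        reference
    ) and np.array_equal(query.centroids, reference.centroids)
    n_ref = len(reference)
    if same_set:
        if n_ref < 2:
            raise EmptyInputError(
                f"marker {query.marker_name!r} has a single cell; "
                "self-distance is undefined"
            )
        k_used = min(k, n_ref - 1)
        nn = NearestNeighbors(n_neighbors=k_used + 1).fit(reference.centroids)
        dist, idx = nn.kneighbors(query.centroids)
        n_q = len(query)
        self_col = idx == np.arange(n_q)[:, None]
        # each row drops exactly one entry: its own index if found among
        # the k+1 neighbors (duplicates may displace it), else the last
        drop = np.where(
            self_col.any(axis=1), self_col.argmax(axis=1), dist.shape[1] - 1
        )
        keep = np.ones_like(dist, dtype=bool)
        keep[np.arange(n_q), drop] = False
        dist = dist[keep].reshape(n_q, k_used)
        return dist, k_used
    k_used = min(k, n_ref)
    nn = NearestNeighbors(n_neighbors=k_used).fit(reference.centroids)
    dist, _ = nn.kneighbors(query.centroids)
    return dist, k_used


def knn_mean_distance(query: PointSet, reference: PointSet, k: int) -> DistanceSummary:
    """Mean over all query cells and their k nearest reference cells.

    k clamps to the reference set size (never an error): sparse markers
    are common in both phantoms and real tissue.
    """
    if query.pixel_size_um != reference.pixel_size_um:
        raise ValueError("query and reference pixel sizes differ")
    dist, k_used = _knn_distances_px(query, reference, k)
    return DistanceSummary(
        marker_pair=(query.marker_name, reference.marker_name),
        k_used=k_used,
        mean_knn_distance_um=float(dist.mean()) * query.pixel_size_um,
        n_query_cells=len(query),
    )


def marker_pair_distance_matrix(
    cells_by_marker: Mapping[str, PointSet], k: int
) -> pd.DataFrame:
    """Directed matrix of mean k-NN distances; entry (i, j) is the mean
    distance from marker i's cells to their k nearest marker-j cells.

    Generally asymmetric. Markers with no positive cells yield NaN rows
    and columns, not zeros.
    """
    names = list(cells_by_marker)
    if sum(len(cells_by_marker[m]) > 0 for m in names) < 1:
        raise EmptyInputError("all markers are empty")
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for qi in names:
        q = cells_by_marker[qi]
        if len(q) == 0:
            continue
        for rj in names:
            r = cells_by_marker[rj]
            if len(r) == 0 or (qi == rj and len(r) < 2):
                continue
            mat.loc[qi, rj] = knn_mean_distance(q, r, k).mean_knn_distance_um
    return mat


def intra_cluster_distances(
    matrix: pd.DataFrame, assignment
) -> list[tuple[str, str, float]]:
    """Undirected same-cluster marker pair distances: mean of the two
    directed entries, one edge per unordered pair."""
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    names = [m for m in matrix.index if m in labels]
    edges = []
    for i, mi in enumerate(names):
        for mj in names[i + 1 :]:
            if labels[mi] != labels[mj]:
                continue
            d = np.nanmean([matrix.loc[mi, mj], matrix.loc[mj, mi]])
            if np.isfinite(d):
                edges.append((mi, mj, float(d)))
    return edges


def inter_cluster_distance(
    matrix: pd.DataFrame, assignment, c1: int, c2: int
) -> float:
    """Mean directed k-NN distance over all marker pairs drawn from two
    distinct clusters, both directions."""
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    if c1 == c2:
        raise ValueError("inter-cluster distance requires two distinct clusters")
    a = [m for m, c in labels.items() if c == c1 and m in matrix.index]
    b = [m for m, c in labels.items() if c == c2 and m in matrix.index]
    if not a or not b:
        raise ValueError(f"unknown or empty cluster id in ({c1}, {c2})")
    vals = []
    for mi in a:
        for mj in b:
            vals.append(matrix.loc[mi, mj])
            vals.append(matrix.loc[mj, mi])
    return float(np.nanmean(vals))


def proximity_fraction(
    query: PointSet, reference: PointSet, cutoff_um: float = 30.0
) -> tuple[float, float]:
    """Per-query-cell nearest-neighbor (k = 1) distances: their mean in µm
    and the fraction strictly below the cutoff."""
    if cutoff_um <= 0:
        raise ValueError("cutoff_um must be > 0")
    dist, _ = _knn_distances_px(query, reference, 1)
    d_um = dist[:, 0] * query.pixel_size_um
    return float(d_um.mean()), float(np.mean(d_um < cutoff_um))
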