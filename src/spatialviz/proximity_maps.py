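"""Spatial proximity maps: per-cell nearest-neighbor links between a
marker pair, their distance histogram, and the all-pairs average heatmap.

Each cell of the origin marker is linked to its single nearest cell of
the destination marker; the link distances are binned into a proportion
histogram (20 equal-width bins by default). Taking only nearest-neighbor
distances — rather than all pairwise distances — keeps the map unbiased
by the destination marker's area and density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyInputError
from .spatial_distance import PointSet, marker_pair_distance_matrix

__all__ = [
    "ProximityLinks",
    "nearest_links",
    "proximity_histogram",
    "average_proximity_heatmap",
]


@dataclass
class ProximityLinks:
    """One nearest-neighbor link per origin cell."""

    marker_pair: tuple[str, str]  # (origin, destination)
    links: list[tuple[int, int, float]]  # (origin idx, destination idx, distance µm)
    bin_edges: np.ndarray | None = None
    proportions: np.ndarray | None = None

    @property
    def distances_um(self) -> np.ndarray:
        return np.asarray([d for _, _, d in self.links], dtype=float)


def nearest_links(origin: PointSet, destination: PointSet) -> ProximityLinks:
    """Link every origin cell to its nearest destination cell.

    Ties are broken by the lowest destination index, making the output
    deterministic. Exactly one link per origin cell.
    """
    if len(origin) == 0 or len(destination) == 0:
        empty = origin.marker_name if len(origin) == 0 else destination.marker_name
        raise EmptyInputError(f"marker {empty!r} has no cells to link")
    d = cdist(origin.centroids, destination.centroids)
    nearest = d.argmin(axis=1)  # argmin returns the lowest index on ties
    links = [
        (int(i), int(j), float(d[i, j]) * origin.pixel_size_um)
        for i, j in enumerate(nearest)
    ]
    return ProximityLinks((origin.marker_name, destination.marker_name), links)


def proximity_histogram(links: ProximityLinks, bins: int = 20) -> ProximityLinks:
    """Fill the proportion histogram of link distances.

    Equal-width bins span [0, max distance]; the last bin is
    right-inclusive (numpy convention). When every distance is zero the
    range is degenerate and all mass lands in a single bin at 0.
    """
    d = links.distances_um
    if d.size == 0:
        raise EmptyInputError("no links to histogram")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    hi = d.max() if d.max() > 0 else 1.0
    counts, edges = np.histogram(d, bins=bins, range=(0.0, hi))
    links.bin_edges = edges
    links.proportions = counts / d.size
    return links


def average_proximity_heatmap(cells_by_marker, k: int = 1):
    """Square matrix of mean k-nearest distances between all marker
    pairs (diagonal computed with self-exclusion).

    This is the same quantity as
    :func:`spatialviz.spatial_distance.marker_pair_distance_matrix`;
    the default k = 1 matches the per-cell nearest-neighbor links.
    """
    return marker_pair_distance_matrix(cells_by_marker, k)
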