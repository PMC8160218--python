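"""Top-down anatomy discovery from binarized marker masks.

Each marker image is thresholded at a fixed raw-count value (default 60)
into an expression mask; the masks, flattened to pixel vectors, are the
observations of a k-means clustering that groups markers by where in the
tissue they light up. Markers sharing an anatomical compartment (crypt,
surface epithelium, germinal centre, ...) land in the same cluster. The
module also computes area ratios, per-cluster mean images, percentile
contrast rescaling and the rainbow-tinted combined overlay.

The marker-by-pixel orientation is deliberate: observations are markers
(rows), features are pixels — the module clusters markers, never pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from sklearn.cluster import KMeans

from .errors import EmptyInputError
from .io_formats import AnalysisConfig, ImageStack, MarkerImage

__all__ = [
    "BinaryMaskSet",
    "ClusterAssignment",
    "binarize_marker",
    "binarize_stack",
    "area_ratio",
    "cluster_markers_kmeans",
    "cluster_mean_image",
    "percentile_rescale",
    "compose_cluster_overlay",
]


@dataclass
class BinaryMaskSet:
    """Per-marker boolean expression masks at a common threshold."""

    masks: dict[str, np.ndarray]
    threshold_used: float

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"mixed mask dimensions: {sorted(shapes)}")

    @property
    def marker_names(self) -> list[str]:
        return list(self.masks)


@dataclass
class ClusterAssignment:
    """Marker -> anatomical cluster labels from k-means."""

    labels: dict[str, int]
    k: int
    inertia: float
    seed: int

    def members(self, cluster_id: int) -> list[str]:
        return [m for m, c in self.labels.items() if c == cluster_id]

    def partition(self) -> set[frozenset[str]]:
        """Label-free view of the clustering, for comparison with a
        planted grouping."""
        return {frozenset(self.members(c)) for c in set(self.labels.values())}


def binarize_marker(img: MarkerImage, threshold: float) -> np.ndarray:
    """Expression mask: pixels with intensity strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return img.pixels > threshold


def binarize_stack(stack: ImageStack, threshold: float) -> BinaryMaskSet:
    return BinaryMaskSet(
        {m.marker_name: binarize_marker(m, threshold) for m in stack.markers},
        threshold_used=threshold,
    )


def area_ratio(mask: np.ndarray) -> float:
    """Fraction of image pixels inside the expression mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise EmptyInputError("area ratio of an empty grid is undefined")
    return float(np.count_nonzero(mask)) / mask.size


def cluster_markers_kmeans(
    masks: BinaryMaskSet, config: AnalysisConfig, k: int | None = None,
    downsample_stride: int = 1,
) -> ClusterAssignment:
    """Group markers into anatomical clusters by k-means on flattened
    binary masks.

    Markers are the observations (one row per marker, one feature per
    pixel); Lloyd's algorithm with ``kmeans_n_init`` restarts keeps the
    best inertia. Markers are ordered canonically (sorted by name) before
    clustering so the result does not depend on input order; the
    assignment is deterministic given ``config.rng_seed``. An optional
    stride subsamples pixels on both axes for very large ROIs.
    """
    k = config.kmeans_k if k is None else k
    names = sorted(masks.marker_names)
    if not names:
        raise EmptyInputError("no masks to cluster")
    if k > len(names):
        raise ValueError(f"K={k} exceeds the number of markers ({len(names)})")
    s = downsample_stride
    X = np.stack([masks.masks[n][::s, ::s].ravel() for n in names]).astype(np.float32)
    km = KMeans(
        n_clusters=k,
        n_init=config.kmeans_n_init,
        max_iter=config.kmeans_max_iter,
        tol=config.kmeans_tol,
        random_state=config.rng_seed % (2**32),
    ).fit(X)
    return ClusterAssignment(
        labels={n: int(c) for n, c in zip(names, km.labels_)},
        k=k,
        inertia=float(km.inertia_),
        seed=config.rng_seed,
    )


def cluster_mean_image(
    stack: ImageStack, assignment: ClusterAssignment, cluster_id: int
) -> MarkerImage:
    """Pixel-wise mean of the raw intensity images of a cluster's markers."""
    members = assignment.members(cluster_id)
    if not members:
        raise EmptyInputError(f"cluster {cluster_id} has no member markers")
    mean = np.mean([stack.get(m).pixels.astype(float) for m in members], axis=0)
    return MarkerImage(f"cluster{cluster_id}_mean", mean, stack.pixel_size_um)


def percentile_rescale(
    img: MarkerImage | np.ndarray, low_pct: float = 2.0, high_pct: float = 98.0
) -> np.ndarray:
    """Linear contrast stretch mapping [p_low, p_high] to [0, 1], clipped.

    A degenerate range (p_low == p_high, e.g. a constant image) maps to
    all zeros: a constant image carries no contrast.
    """
    pixels = img.pixels if isinstance(img, MarkerImage) else np.asarray(img)
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    lo, hi = np.percentile(pixels, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(pixels, dtype=float)
    return np.clip((pixels.astype(float) - lo) / (hi - lo), 0.0, 1.0)


def compose_cluster_overlay(
    stack: ImageStack, assignment: ClusterAssignment, config: AnalysisConfig
) -> np.ndarray:
    """Rainbow-tinted composite of all cluster mean images.

    Each cluster's mean image is percentile-rescaled, tinted with the
    colour at position i/K on the ``gist_rainbow`` colormap, and the
    layers are combined by per-pixel maximum so every region keeps its
    own hue. Output is (rows, cols, 3) in [0, 1].
    """
    cluster_ids = sorted(set(assignment.labels.values()))
    if not cluster_ids:
        raise EmptyInputError("assignment has no clusters")
    cmap = colormaps["gist_rainbow"]
    lo, hi = config.rescale_percentiles
    composite = np.zeros((*stack.shape, 3), dtype=float)
    for i, cid in enumerate(cluster_ids):
        mean_img = cluster_mean_image(stack, assignment, cid)
        scaled = percentile_rescale(mean_img, lo, hi)
        tint = np.asarray(cmap(i / len(cluster_ids)))[:3]
        layer = scaled[..., None] * tint[None, None, :]
        composite = np.maximum(composite, layer)
    return composite
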