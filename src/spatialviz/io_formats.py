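"""Containers, file formats and unit conventions.

Every module in the toolkit shares the conventions defined here:

* images are 2-D numpy arrays indexed ``[row, col]``, 0-based;
* physical distances are Euclidean pixel distances multiplied by
  ``pixel_size_um`` (micrometres per pixel, nominally 1.0 for IMC);
* intensities are raw counts and are never rescaled on read — the fixed
  binarization threshold (60 counts) is defined on raw values.

Supported formats: single-channel TIFF / multi-channel OME-TIFF for
marker images and label masks, CSV for single-cell tables (CellProfiler
``ExportToSpreadsheet`` dialect: header row, comma separated, UTF-8),
YAML for the analysis configuration.
"""

from __future__ import annotations

import dataclasses
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    ConfigError,
    DimensionMismatchError,
    FormatError,
    SchemaError,
)

__all__ = [
    "MarkerImage",
    "ImageStack",
    "LabelMask",
    "CellTable",
    "AnalysisConfig",
    "read_marker_stack",
    "write_marker_stack",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
]

CELL_ID = "cell_id"
CENTROID_ROW = "centroid_row"
CENTROID_COL = "centroid_col"
_REQUIRED_COLUMNS = (CELL_ID, CENTROID_ROW, CENTROID_COL)


@dataclass
class MarkerImage:
    """One marker's 2-D intensity grid with its physical pixel size."""

    marker_name: str
    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DimensionMismatchError(
                f"marker {self.marker_name!r}: image must be a non-empty 2-D grid, "
                f"got shape {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise FormatError(f"marker {self.marker_name!r}: negative intensities")
        if not self.pixel_size_um > 0:
            raise FormatError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """An ordered collection of same-size marker images from one ROI."""

    roi_id: str
    markers: list[MarkerImage]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.markers:
            raise FormatError("stack must contain at least one marker image")
        shapes = {m.shape for m in self.markers}
        if len(shapes) != 1:
            raise DimensionMismatchError(
                f"stack {self.roi_id!r}: mixed image dimensions {sorted(shapes)}"
            )
        sizes = {m.pixel_size_um for m in self.markers}
        if len(sizes) != 1:
            raise DimensionMismatchError(
                f"stack {self.roi_id!r}: mixed pixel sizes {sorted(sizes)}"
            )
        names = [m.marker_name for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate marker names: {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.markers[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.markers[0].pixel_size_um

    @property
    def marker_names(self) -> list[str]:
        return [m.marker_name for m in self.markers]

    def get(self, marker_name: str) -> MarkerImage:
        for m in self.markers:
            if m.marker_name == marker_name:
                return m
        raise KeyError(marker_name)


@dataclass
class LabelMask:
    """Integer-labelled cell segmentation mask; 0 is background.

    Labels need not be consecutive and are never renumbered (CellProfiler
    masks may skip labels).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise DimensionMismatchError("label mask must be a non-empty 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.all(self.labels == np.round(self.labels)):
                self.labels = self.labels.astype(np.int64)
            else:
                raise FormatError("label mask contains non-integer pixel values")
        if np.any(self.labels < 0):
            raise FormatError("label mask contains negative labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


@dataclass
class CellTable:
    """Per-cell centroids and per-marker mean intensities.

    Backed by a :class:`pandas.DataFrame` with columns ``cell_id``,
    ``centroid_row``, ``centroid_col`` plus one mean-intensity column per
    marker. Centroids are 0-based (row, col) pixel coordinates.
    """

    data: pd.DataFrame
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cell table missing required columns: {missing}")
        if self.data[CELL_ID].duplicated().any():
            raise SchemaError("cell_id values must be unique")
        self.data = self.data.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return [c for c in self.data.columns if c not in _REQUIRED_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids."""
        return self.data[[CENTROID_ROW, CENTROID_COL]].to_numpy(dtype=float)

    def intensity(self, marker: str) -> np.ndarray:
        if marker not in self.markers:
            raise KeyError(marker)
        return self.data[marker].to_numpy(dtype=float)


@dataclass
class AnalysisConfig:
    """All fixed analysis parameters in one place.

    Defaults follow the published workflow: a pixel binarization threshold
    of 60 raw counts, k-means with 6 clusters and scikit-learn defaults
    (10 restarts, 300 iterations, tolerance 1e-4), k = 10 spatial nearest
    neighbors, a 30 µm proximity cutoff, 20 histogram bins, 2–98 percentile
    contrast rescaling, spring layouts (k = 0.3, 30 iterations for cluster
    maps; k = 3.0, 5 iterations for the fixed-landmark reference), five
    reference edges per marker and seven nuclear/lymphocyte landmark
    markers shared across tonsil datasets.
    """

    binary_threshold: float = 60.0
    kmeans_k: int = 6
    kmeans_n_init: int = 10
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-4
    knn_k: int = 10
    proximity_k: int = 1
    proximity_cutoff_um: float = 30.0
    histogram_bins: int = 20
    rescale_percentiles: tuple[float, float] = (2.0, 98.0)
    spring_k_cluster: float = 0.3
    spring_iter_cluster: int = 30
    spring_k_reference: float = 3.0
    spring_iter_reference: int = 5
    reference_edges_per_marker: int = 5
    landmark_markers: list[str] = field(
        default_factory=lambda: [
            "DNA1",
            "DNA2",
            "Histone3",
            "CD3",
            "CD4",
            "CD8a",
            "CD20",
        ]
    )
    positivity_threshold: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "kmeans_k",
            "kmeans_n_init",
            "kmeans_max_iter",
            "knn_k",
            "proximity_k",
            "histogram_bins",
            "spring_iter_cluster",
            "spring_iter_reference",
            "reference_edges_per_marker",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.rescale_percentiles
        if not (0 <= lo < hi <= 100):
            raise ConfigError("rescale_percentiles must be strictly increasing in [0, 100]")
        if not self.proximity_cutoff_um > 0:
            raise ConfigError("proximity_cutoff_um must be > 0")

    def threshold_for(self, marker: str) -> float:
        """Positivity threshold for a marker (per-marker override or the
        global binary threshold)."""
        return float(self.positivity_threshold.get(marker, self.binary_threshold))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "rescale_percentiles" in raw:
            raw["rescale_percentiles"] = tuple(raw["rescale_percentiles"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rescale_percentiles"] = list(d["rescale_percentiles"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# image I/O


def _ome_channel_names(tf: tifffile.TiffFile) -> list[str] | None:
    xml_text = tf.ome_metadata
    if not xml_text:
        return None
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    names = []
    for chan in root.iter():
        if chan.tag.endswith("Channel"):
            names.append(chan.get("Name") or "")
    if names and all(names):
        return names
    return None


def read_marker_stack(
    path: str | Path,
    naming: str = r"(?P<marker>.+?)\.(?:tif|tiff)$",
    roi_id: str | None = None,
    pixel_size_um: float = 1.0,
    condition_label: str = "",
) -> ImageStack:
    """Read a marker stack from a multi-channel OME-TIFF file or a
    directory of single-channel TIFFs.

    For directories the ``naming`` regular expression is matched against
    each filename; its ``marker`` group provides the marker name. For
    OME-TIFF files channel names are taken from the OME metadata and win
    over any filename-derived name.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise IOError(f"no TIFF files found in {path}")
        pattern = re.compile(naming)
        markers: list[MarkerImage] = []
        for f in files:
            m = pattern.search(f.name)
            name = m.group("marker") if m else f.stem
            try:
                pixels = tifffile.imread(f)
            except Exception as exc:  # pragma: no cover - passthrough naming the file
                raise IOError(f"cannot read {f}: {exc}") from exc
            markers.append(MarkerImage(name, pixels, pixel_size_um))
        return ImageStack(roi_id or path.name, markers, condition_label)

    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            names = _ome_channel_names(tf)
    except Exception as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a (channels, rows, cols) stack, got shape {data.shape}")
    if names is None:
        names = [f"channel{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise FormatError(
            f"{path}: {len(names)} channel names for {data.shape[0]} channels"
        )
    markers = [MarkerImage(n, plane, pixel_size_um) for n, plane in zip(names, data)]
    return ImageStack(roi_id or path.stem, markers, condition_label)


def write_marker_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-channel OME-TIFF (``.tif``/``.tiff`` path)
    or as one single-channel TIFF per marker (directory path)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.stack([m.pixels for m in stack.markers])
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": stack.marker_names},
            },
        )
    else:
        path.mkdir(parents=True, exist_ok=True)
        for m in stack.markers:
            tifffile.imwrite(path / f"{m.marker_name}.tiff", m.pixels)


def read_label_mask(path: str | Path) -> LabelMask:
    """Read an integer-labelled cell mask from a single-channel TIFF."""
    try:
        labels = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    if labels.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-channel 2-D")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise FormatError(f"{path}: label mask contains non-integer pixel values")
        labels = labels.astype(np.int64)
    return LabelMask(labels)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.int32
    tifffile.imwrite(path, labels.astype(dtype))


def read_cell_table(path: str | Path, pixel_size_um: float = 1.0) -> CellTable:
    """Read a single-cell table from CSV.

    Requires ``cell_id``, ``centroid_row``, ``centroid_col`` and at least
    one intensity column; raises :class:`SchemaError` listing any missing
    required columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    if len(df.columns) <= len(_REQUIRED_COLUMNS):
        raise SchemaError(f"{path}: no marker intensity columns present")
    return CellTable(df, pixel_size_um)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)
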