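"""Bottom-up single-cell quantification and statistics.

Given a marker image stack and a cell segmentation label mask, this module
extracts per-cell mean intensities and centroids (the CellProfiler
``MeasureObjectIntensity`` measurement), calls marker positivity, and
computes the statistics used to compare tissue conditions: percentage
counts, Pearson correlations with the Fisher Z two-sample comparison, the
two-sample Kolmogorov–Smirnov test, and box-plot summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    ConfigError,
    DegenerateInputError,
    DimensionMismatchError,
    EmptyInputError,
)
from .io_formats import (
    CELL_ID,
    CENTROID_COL,
    CENTROID_ROW,
    AnalysisConfig,
    CellTable,
    ImageStack,
    LabelMask,
)

__all__ = [
    "PositivityTable",
    "CorrelationResult",
    "quantify_cells",
    "call_positivity",
    "percentage_count",
    "marker_correlation",
    "compare_correlations_fisher",
    "compare_distributions_ks",
    "intensity_summary",
]


@dataclass
class PositivityTable:
    """Boolean expressed/not-expressed calls per cell per marker.

    ``expressed`` is indexed by cell_id with one boolean column per marker.
    ``n_any_positive`` counts cells expressing at least one marker — the
    denominator of the percentage count.
    """

    expressed: pd.DataFrame

    @property
    def markers(self) -> list[str]:
        return list(self.expressed.columns)

    def n_positive(self, marker: str) -> int:
        return int(self.expressed[marker].sum())

    @property
    def n_any_positive(self) -> int:
        if self.expressed.empty:
            return 0
        return int(self.expressed.any(axis=1).sum())

    def positive_cells(self, marker: str) -> pd.Index:
        col = self.expressed[marker]
        return self.expressed.index[col]


@dataclass
class CorrelationResult:
    marker_pair: tuple[str, str]
    r: float
    n: int

    @property
    def z_fisher(self) -> float:
        return math.atanh(self.r)


def quantify_cells(stack: ImageStack, mask: LabelMask) -> CellTable:
    """Per-cell centroids and per-marker mean intensities.

    The centroid is the unweighted mean of member pixel (row, col)
    coordinates; the intensity is the mean over member pixels of the raw
    marker image. Cells are ordered by ascending label. An empty mask
    yields an empty table, not an error.
    """
    if stack.shape != mask.shape:
        raise DimensionMismatchError(
            f"stack shape {stack.shape} != mask shape {mask.shape}"
        )
    ids = mask.cell_ids
    columns: dict[str, np.ndarray] = {}
    if ids.size == 0:
        data = pd.DataFrame(
            {CELL_ID: pd.Series([], dtype=int),
             CENTROID_ROW: pd.Series([], dtype=float),
             CENTROID_COL: pd.Series([], dtype=float),
             **{m: pd.Series([], dtype=float) for m in stack.marker_names}}
        )
        return CellTable(data, stack.pixel_size_um)
    centroids = ndimage.center_of_mass(
        np.ones(mask.shape), labels=mask.labels, index=ids
    )
    centroids = np.asarray(centroids, dtype=float)
    columns[CELL_ID] = ids
    columns[CENTROID_ROW] = centroids[:, 0]
    columns[CENTROID_COL] = centroids[:, 1]
    for img in stack.markers:
        columns[img.marker_name] = ndimage.mean(
            img.pixels.astype(float), labels=mask.labels, index=ids
        )
    return CellTable(pd.DataFrame(columns), stack.pixel_size_um)


def call_positivity(cells: CellTable, config: AnalysisConfig) -> PositivityTable:
    """Call each cell positive for a marker iff its mean intensity is
    strictly greater than that marker's threshold.

    The default threshold for every marker is the global pixel
    binarization threshold (60 counts); per-marker overrides come from
    ``config.positivity_threshold``.
    """
    if not cells.markers:
        raise ConfigError("cell table has no marker columns")
    calls = {}
    for m in cells.markers:
        thr = config.threshold_for(m)
        calls[m] = cells.intensity(m) > thr
    expressed = pd.DataFrame(calls, index=pd.Index(cells.data[CELL_ID], name=CELL_ID))
    return PositivityTable(expressed)


def percentage_count(pos: PositivityTable, marker: str) -> float:
    """Cells positive for *marker* divided by cells positive for at least
    one marker."""
    denom = pos.n_any_positive
    if denom == 0:
        raise DegenerateInputError(
            "percentage count undefined: no cell expresses any marker"
        )
    return pos.n_positive(marker) / denom


def marker_correlation(cells: CellTable, m1: str, m2: str) -> CorrelationResult:
    """Pearson correlation of two markers' per-cell mean intensities over
    all cells (no positivity gating)."""
    x = cells.intensity(m1)
    y = cells.intensity(m2)
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 cells for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(
            f"zero variance for {m1 if np.std(x) == 0 else m2!r}"
        )
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult((m1, m2), float(r), int(len(x)))


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sample comparison of independent Pearson correlations via the
    Fisher Z-transformation.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal tail p-value.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def compare_distributions_ks(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def intensity_summary(cells: CellTable, marker: str) -> dict:
    """Box-plot summary: median, quartiles (linear interpolation), and
    min/max excluding 1.5*IQR outliers, with the outlier values listed."""
    values = cells.intensity(marker)
    if values.size == 0:
        raise EmptyInputError("intensity summary requires at least one cell")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    outlier_mask = (values < lo_fence) | (values > hi_fence)
    kept = values[~outlier_mask]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(kept.min()),
        "max": float(kept.max()),
        "outliers": sorted(float(v) for v in values[outlier_mask]),
    }
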