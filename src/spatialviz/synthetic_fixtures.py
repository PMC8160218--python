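"""Synthetic tissue phantoms with known ground truth.

A phantom emulates one multiplexed imaging-mass-cytometry ROI: a handful
of geometric anatomical regions (discs, annuli, bands, half-planes), a
panel of markers each enriched in some regions over a low background, and
non-overlapping circular cells placed inside regions with per-marker
positivity driven by the region they sit in plus optional pairwise
coexpression. The emitted cell table is recomputed from the rendered
images and mask — never copied from ground truth — so quantification is
honestly exercised downstream.

Intensity model: a marker's image is ``baseline + weight(region)`` as a
smooth tissue field; each cell positive for the marker is rendered as a
flat disc at ``baseline + amplitude + N(0, noise_sd)`` clipped at zero,
where the amplitude is the marker's maximum regional weight. Noise is
drawn once per cell and marker (not per pixel), mimicking cell-level
expression variability while keeping per-cell means exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError
from .io_formats import CellTable, ImageStack, LabelMask, MarkerImage

__all__ = [
    "Disc",
    "Annulus",
    "Band",
    "HalfPlane",
    "Region",
    "MarkerProfile",
    "TissuePhantomSpec",
    "TissueGroundTruth",
    "generate_phantom",
    "generate_point_pattern",
]


# ---------------------------------------------------------------------------
# geometric primitives


@dataclass
class Disc:
    center: tuple[float, float]  # (row, col)
    radius: float

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass
class Annulus:
    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)


@dataclass
class Band:
    """Axis-aligned stripe: pixels with lo <= coordinate < hi."""

    axis: str  # "row" or "col"
    lo: float
    hi: float

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        coord = rr if self.axis == "row" else cc
        return (coord >= self.lo) & (coord < self.hi)


@dataclass
class HalfPlane:
    """Pixels with normal . (row, col) >= offset."""

    normal: tuple[float, float]
    offset: float

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        return self.normal[0] * rr + self.normal[1] * cc >= self.offset


@dataclass
class Region:
    region_id: int
    shape: Disc | Annulus | Band | HalfPlane

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer (0 is background)")


@dataclass
class MarkerProfile:
    """Per-marker enrichment: baseline background plus a weight per region."""

    name: str
    baseline: float = 5.0
    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline < 0 or any(w < 0 for w in self.weights.values()):
            raise ValueError("baseline and enrichment weights must be >= 0")

    @property
    def amplitude(self) -> float:
        return max(self.weights.values(), default=0.0)

    @property
    def dominant_region(self) -> int:
        """Region with the largest enrichment weight (0 if unenriched;
        ties broken by lowest region id)."""
        if not self.weights:
            return 0
        best = max(self.weights.values())
        return min(r for r, w in self.weights.items() if w == best)


@dataclass
class TissuePhantomSpec:
    """Full recipe for one phantom ROI.

    ``cell_density`` is cells per 100x100 px block, per region id.
    ``coexpression`` maps unordered marker-name pairs to the probability
    that a cell positive for one member is also positive for the other.
    """

    image_size: tuple[int, int] = (500, 500)
    regions: list[Region] = field(default_factory=list)
    marker_profiles: list[MarkerProfile] = field(default_factory=list)
    cell_density: dict[int, float] = field(default_factory=dict)
    cell_radius_px: float = 3.0
    coexpression: dict[tuple[str, str], float] = field(default_factory=dict)
    intensity_noise_sd: float = 0.0
    rng_seed: int = 0
    pixel_size_um: float = 1.0
    roi_id: str = "phantom"
    condition_label: str = "synthetic"

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.cell_density.values()):
            raise ValueError("cell densities must be >= 0")
        for pair, p in self.coexpression.items():
            if not 0 <= p <= 1:
                raise ValueError(f"coexpression probability for {pair} not in [0, 1]")
        names = [m.name for m in self.marker_profiles]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "TissuePhantomSpec":
        shapes = {"disc": Disc, "annulus": Annulus, "band": Band, "half_plane": HalfPlane}
        regions = []
        for r in raw.get("regions", []):
            r = dict(r)
            rid = r.pop("region_id")
            kind = r.pop("shape")
            for key in ("center", "normal"):
                if key in r:
                    r[key] = tuple(r[key])
            regions.append(Region(rid, shapes[kind](**r)))
        profiles = [
            MarkerProfile(
                p["name"],
                p.get("baseline", 5.0),
                {int(k): float(v) for k, v in p.get("weights", {}).items()},
            )
            for p in raw.get("marker_profiles", [])
        ]
        coex = {
            tuple(sorted(k.split(","))): float(v)
            for k, v in raw.get("coexpression", {}).items()
        }
        return cls(
            image_size=tuple(raw.get("image_size", (500, 500))),
            regions=regions,
            marker_profiles=profiles,
            cell_density={int(k): float(v) for k, v in raw.get("cell_density", {}).items()},
            cell_radius_px=float(raw.get("cell_radius_px", 3.0)),
            coexpression=coex,
            intensity_noise_sd=float(raw.get("intensity_noise_sd", 0.0)),
            rng_seed=int(raw.get("rng_seed", 0)),
            pixel_size_um=float(raw.get("pixel_size_um", 1.0)),
            roi_id=str(raw.get("roi_id", "phantom")),
            condition_label=str(raw.get("condition_label", "synthetic")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissuePhantomSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TissueGroundTruth:
    """What was planted: the region map, the true marker grouping by
    dominant region, cell centers, and true per-cell positivity."""

    region_map: np.ndarray
    true_marker_grouping: dict[str, int]
    cell_positions: np.ndarray  # (n, 2) planted centers, (row, col)
    true_positivity: pd.DataFrame  # index cell_id, one bool column per marker

    def grouping_partition(self) -> dict[int, frozenset[str]]:
        """Markers partitioned by dominant region id."""
        part: dict[int, set[str]] = {}
        for m, r in self.true_marker_grouping.items():
            part.setdefault(r, set()).add(m)
        return {r: frozenset(s) for r, s in part.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_marker_grouping": self.true_marker_grouping,
            "cell_positions": self.cell_positions.tolist(),
            "true_positivity": {
                m: self.true_positivity[m].astype(bool).tolist()
                for m in self.true_positivity.columns
            },
            "cell_ids": [int(i) for i in self.true_positivity.index],
            "region_map_shape": list(self.region_map.shape),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _region_map(spec: TissuePhantomSpec) -> np.ndarray:
    region_map = np.zeros(spec.image_size, dtype=np.int32)
    for region in spec.regions:
        fp = region.shape.footprint(spec.image_size)
        region_map[(region_map == 0) & fp] = region.region_id
    return region_map


def _place_cells(
    spec: TissuePhantomSpec, region_map: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping disc centers by rejection sampling.

    Returns (centers (n,2) int array, region id per cell)."""
    radius = spec.cell_radius_px
    min_sep2 = (2 * radius) ** 2
    centers: list[tuple[int, int]] = []
    cell_regions: list[int] = []
    nrows, ncols = spec.image_size
    for region in spec.regions:
        density = spec.cell_density.get(region.region_id, 0.0)
        if density <= 0:
            continue
        pix = np.argwhere(region_map == region.region_id)
        if pix.size == 0:
            continue
        n_cells = int(round(density * len(pix) / 1e4))
        for _ in range(n_cells):
            for attempt in range(1000):
                r, c = pix[rng.integers(len(pix))]
                if not (radius <= r < nrows - radius and radius <= c < ncols - radius):
                    continue
                ok = all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers)
                if ok:
                    centers.append((int(r), int(c)))
                    cell_regions.append(region.region_id)
                    break
            else:
                raise GenerationError(
                    f"could not place cell {len(centers) + 1} in region "
                    f"{region.region_id} after 1000 attempts; lower cell_density "
                    "or cell_radius_px"
                )
    return np.asarray(centers, dtype=int).reshape(-1, 2), np.asarray(cell_regions, dtype=int)


def _positivity(
    spec: TissuePhantomSpec, cell_regions: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    names = [m.name for m in spec.marker_profiles]
    n = len(cell_regions)
    pos = pd.DataFrame(
        False, index=pd.Index(np.arange(1, n + 1), name="cell_id"), columns=names
    )
    for prof in spec.marker_profiles:
        enriched = {r for r, w in prof.weights.items() if w > 0}
        pos[prof.name] = np.isin(cell_regions, list(enriched))
    # pairwise coexpression, applied in sorted pair order for determinism
    for pair in sorted(spec.coexpression):
        p = spec.coexpression[pair]
        a, b = pair
        if a not in pos.columns or b not in pos.columns:
            continue
        only_a = pos[a].to_numpy() & ~pos[b].to_numpy()
        only_b = pos[b].to_numpy() & ~pos[a].to_numpy()
        pos.loc[only_a & (rng.random(n) < p), b] = True
        pos.loc[only_b & (rng.random(n) < p), a] = True
    return pos


def generate_phantom(
    spec: TissuePhantomSpec,
) -> tuple[ImageStack, LabelMask, CellTable, TissueGroundTruth]:
    """Render a phantom ROI. Deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    region_map = _region_map(spec)
    centers, cell_regions = _place_cells(spec, region_map, rng)
    n_cells = len(centers)
    true_pos = _positivity(spec, cell_regions, rng)

    # label mask: filled discs, labels 1..n in placement order
    labels = np.zeros(spec.image_size, dtype=np.int32)
    rad = int(np.ceil(spec.cell_radius_px))
    rr_off, cc_off = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disc = rr_off**2 + cc_off**2 <= spec.cell_radius_px**2
    disc_r = rr_off[disc]
    disc_c = cc_off[disc]
    for i, (r, c) in enumerate(centers, start=1):
        labels[r + disc_r, c + disc_c] = i
    mask = LabelMask(labels)

    # marker images
    markers: list[MarkerImage] = []
    for prof in spec.marker_profiles:
        weight_lut = np.zeros(int(region_map.max()) + 1, dtype=float)
        for rid, w in prof.weights.items():
            if rid < len(weight_lut):
                weight_lut[rid] = w
        pixels = prof.baseline + weight_lut[region_map]
        if n_cells:
            noise = (
                rng.normal(0.0, spec.intensity_noise_sd, size=n_cells)
                if spec.intensity_noise_sd > 0
                else np.zeros(n_cells)
            )
            pos = true_pos[prof.name].to_numpy()
            cell_values = np.clip(
                prof.baseline + prof.amplitude * pos + noise, 0.0, None
            )
            for i, (r, c) in enumerate(centers):
                if pos[i] or spec.intensity_noise_sd > 0:
                    pixels[r + disc_r, c + disc_c] = cell_values[i]
        markers.append(
            MarkerImage(prof.name, pixels.astype(np.float32), spec.pixel_size_um)
        )
    stack = ImageStack(spec.roi_id, markers, spec.condition_label)

    # honest quantification: the emitted table is measured, not copied
    from .single_cell_quant import quantify_cells

    cells = quantify_cells(stack, mask)

    truth = TissueGroundTruth(
        region_map=region_map,
        true_marker_grouping={m.name: m.dominant_region for m in spec.marker_profiles},
        cell_positions=centers.astype(float),
        true_positivity=true_pos,
    )
    return stack, mask, cells, truth


def generate_point_pattern(
    n_a: int,
    n_b: int,
    planted_offset_um: float,
    jitter_sd: float,
    seed: int,
    frame_size_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two planar point sets with a planted nearest-neighbor offset.

    Each of the first ``min(n_a, n_b)`` B points sits at a fixed-magnitude
    offset from a distinct A point, in a random direction, with isotropic
    Gaussian positional jitter; surplus B points are uniform over the
    frame. For small jitter the mean A→B nearest-neighbor distance is
    approximately ``planted_offset_um``; to make that hold the default
    frame scales with the offset and point count
    (``max(500, 20 * offset * sqrt(max(n_a, n_b)))`` µm) so a point's
    planted partner is almost surely its nearest neighbor rather than a
    bystander. Coordinates are in µm (equal to pixels at 1 µm/px).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    if planted_offset_um < 0:
        raise ValueError("planted_offset_um must be >= 0")
    if frame_size_um is None:
        frame_size_um = max(
            500.0, 20.0 * planted_offset_um * float(np.sqrt(max(n_a, n_b)))
        )
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, frame_size_um, size=(n_a, 2))
    n_paired = min(n_a, n_b)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_paired)
    offset = planted_offset_um * np.column_stack([np.cos(theta), np.sin(theta)])
    jitter = (
        rng.normal(0.0, jitter_sd, size=(n_paired, 2))
        if jitter_sd > 0
        else np.zeros((n_paired, 2))
    )
    b = a[:n_paired] + offset + jitter
    if n_b > n_a:
        extra = rng.uniform(0.0, frame_size_um, size=(n_b - n_a, 2))
        b = np.vstack([b, extra])
    return a, b
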