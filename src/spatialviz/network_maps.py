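"""Spatial network graphs and the fixed-landmark reference framework.

Markers become nodes (node size = area ratio, colour = anatomical
cluster); mean k-NN distances become edge weights, min-max normalized
over the edge set so a red-to-blue colormap reads close-to-distant.
Intra-cluster graphs connect only same-cluster markers; inter-cluster
graphs connect cluster supernodes. The reference framework fixes a set
of landmark markers (nuclear and core lymphocyte markers shared across
datasets) on a circle and lets the remaining markers arrange themselves
by force-directed layout, so healthy and diseased datasets can be
compared on one map.

Graphs are :class:`networkx` graphs with node attributes ``size``,
``cluster``, ``color_index``, ``fixed``, ``x``, ``y`` and edge attributes
``weight_um``, ``normalized_weight``; serialized to GraphML or JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from dataclasses import dataclass

from .errors import EmptyInputError
from .io_formats import AnalysisConfig, CellTable
from .single_cell_quant import PositivityTable
from .spatial_distance import (
    inter_cluster_distance,
    intra_cluster_distances,
    points_by_marker,
    proximity_fraction,
)

__all__ = [
    "DotSummary",
    "build_cluster_graph",
    "layout_spring",
    "build_reference_graph",
    "dot_summary",
    "write_graph",
]


def _normalize_edges(graph: nx.Graph) -> None:
    """Min-max normalize edge weights into [0, 1]; a single edge (or all
    equal weights) normalizes to 0 (the "close" end of the colormap)."""
    weights = [d["weight_um"] for _, _, d in graph.edges(data=True)]
    if not weights:
        return
    lo, hi = min(weights), max(weights)
    span = hi - lo
    for _, _, d in graph.edges(data=True):
        d["normalized_weight"] = 0.0 if span == 0 else (d["weight_um"] - lo) / span


def build_cluster_graph(
    matrix: pd.DataFrame,
    assignment,
    area_ratios: Mapping[str, float],
    mode: str = "intra",
) -> nx.Graph:
    """Spatial network of markers grouped by anatomical cluster.

    ``intra``: undirected edges between same-cluster markers, weighted by
    the mean of the two directed k-NN distances. ``inter``: cluster
    supernodes (size = mean member area ratio) joined by one edge per
    cluster pair weighted by the inter-cluster distance; marker nodes are
    kept, coloured by cluster, without edges.
    """
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown mode {mode!r}")
    g = nx.Graph(mode=mode)
    for m in matrix.index:
        cluster = labels.get(m)
        g.add_node(
            m,
            size=float(area_ratios.get(m, 0.0)),
            cluster=-1 if cluster is None else int(cluster),
            color_index=-1 if cluster is None else int(cluster),
            fixed=False,
        )
    if mode == "intra":
        for mi, mj, d in intra_cluster_distances(matrix, assignment):
            g.add_edge(mi, mj, weight_um=float(d))
    else:
        clusters = sorted({c for c in labels.values()})
        for c in clusters:
            members = [m for m, ci in labels.items() if ci == c]
            size = float(np.mean([area_ratios.get(m, 0.0) for m in members]))
            g.add_node(f"cluster_{c}", size=size, cluster=int(c),
                       color_index=int(c), fixed=False)
        for i, c1 in enumerate(clusters):
            for c2 in clusters[i + 1 :]:
                d = inter_cluster_distance(matrix, assignment, c1, c2)
                if math.isfinite(d):
                    g.add_edge(f"cluster_{c1}", f"cluster_{c2}", weight_um=float(d))
    _normalize_edges(g)
    return g


def layout_spring(
    graph: nx.Graph,
    k: float,
    iterations: int,
    seed: int,
    fixed_nodes: Sequence[str] = (),
    pos: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Fruchterman–Reingold force-directed layout.

    Fixed nodes keep their input positions exactly; the layout is
    deterministic given the seed. Edge ``weight_um`` attributes act as
    spring weights.
    """
    fixed_nodes = list(fixed_nodes)
    unknown = [n for n in fixed_nodes if n not in graph]
    if unknown:
        raise ValueError(f"fixed nodes not in graph: {unknown}")
    init = dict(pos) if pos else {}
    missing = [n for n in fixed_nodes if n not in init]
    if missing:
        raise ValueError(f"fixed nodes lack initial positions: {missing}")
    result = nx.spring_layout(
        graph,
        k=k,
        iterations=iterations,
        pos=init or None,
        fixed=fixed_nodes or None,
        seed=seed,
        weight="weight_um",
    )
    out = {}
    for n, p in result.items():
        # guarantee bit-exact invariance for fixed nodes
        out[n] = tuple(init[n]) if n in fixed_nodes else (float(p[0]), float(p[1]))
    return out


def landmark_circle_positions(
    landmarks: Sequence[str],
) -> dict[str, tuple[float, float]]:
    """Evenly spaced positions on the unit circle, in landmark order."""
    n = len(landmarks)
    return {
        m: (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
        for i, m in enumerate(landmarks)
    }


def build_reference_graph(
    matrix: pd.DataFrame,
    area_ratios: Mapping[str, float],
    config: AnalysisConfig,
) -> nx.DiGraph:
    """Fixed-landmark spatial reference framework.

    Every marker gets directed edges to the ``reference_edges_per_marker``
    (default 5) markers closest to it by mean k-NN distance — the arrow
    points at the close marker. With fewer than 6 markers the out-degree
    clamps to n-1. Landmark markers present in the matrix are flagged
    fixed and pre-positioned evenly on a unit circle.
    """
    names = list(matrix.index)
    if not names:
        raise EmptyInputError("empty distance matrix")
    landmarks = [m for m in config.landmark_markers if m in names]
    positions = landmark_circle_positions(landmarks)
    g = nx.DiGraph()
    for m in names:
        attrs = dict(size=float(area_ratios.get(m, 0.0)), fixed=m in positions,
                     cluster=-1, color_index=-1)
        if m in positions:
            attrs["x"], attrs["y"] = positions[m]
        g.add_node(m, **attrs)
    n_out = min(config.reference_edges_per_marker, len(names) - 1)
    for m in names:
        row = matrix.loc[m].drop(labels=[m]).dropna()
        targets = row.nsmallest(n_out)
        for t, d in targets.items():
            g.add_edge(m, t, weight_um=float(d))
    _normalize_edges(g)
    return g


@dataclass
class DotSummary:
    """Dot-plot summary statistics across datasets.

    ``expression``: datasets x markers, per-dataset mean marker intensity
    scaled so the dataset maximum is 1 (dot colour). ``prevalence``: the
    marker's positive-cell footprint as a fraction of the image (dot
    area). ``pairwise``: per dataset and ordered marker pair, the mean
    cell-to-cell nearest distance in µm and the fraction below the
    cutoff; rows for empty markers are NaN-flagged, not dropped.
    """

    expression: pd.DataFrame
    prevalence: pd.DataFrame
    pairwise: pd.DataFrame
    cutoff_um: float = 30.0


def dot_summary(
    cell_tables: Mapping[str, CellTable],
    prevalence_areas: Mapping[str, Mapping[str, float]],
    positivity: Mapping[str, PositivityTable],
    cutoff_um: float = 30.0,
) -> DotSummary:
    """Cross-dataset dot-plot statistics.

    ``prevalence_areas`` maps dataset -> marker -> area ratio of the
    marker's positive-cell footprint (fraction of image pixels).
    """
    if not cell_tables:
        raise EmptyInputError("dot_summary requires at least one dataset")
    expr_rows = {}
    prev_rows = {}
    pair_rows = []
    for ds, cells in cell_tables.items():
        if cells.n_cells == 0:
            raise EmptyInputError(f"dataset {ds!r} has no cells")
        means = {m: float(cells.intensity(m).mean()) for m in cells.markers}
        top = max(means.values())
        expr_rows[ds] = {m: (v / top if top > 0 else 0.0) for m, v in means.items()}
        prev_rows[ds] = {
            m: float(prevalence_areas.get(ds, {}).get(m, 0.0)) for m in cells.markers
        }
        pts = points_by_marker(cells, positivity[ds])
        for a in cells.markers:
            for b in cells.markers:
                if a == b:
                    continue
                if len(pts[a]) == 0 or len(pts[b]) == 0 or (
                    a == b and len(pts[a]) < 2
                ):
                    mean_d, frac = float("nan"), float("nan")
                else:
                    mean_d, frac = proximity_fraction(pts[a], pts[b], cutoff_um)
                pair_rows.append(
                    {
                        "dataset": ds,
                        "origin": a,
                        "destination": b,
                        "mean_distance_um": mean_d,
                        "fraction_below_cutoff": frac,
                    }
                )
    return DotSummary(
        expression=pd.DataFrame(expr_rows).T,
        prevalence=pd.DataFrame(prev_rows).T,
        pairwise=pd.DataFrame(pair_rows),
        cutoff_um=cutoff_um,
    )


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """Serialize a graph to GraphML (``.graphml``) or JSON node-link
    (``.json``); positions, if present, are stored as ``x``/``y``."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
    elif path.suffix == ".json":
        payload = nx.node_link_data(graph, edges="edges")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        raise ValueError(f"unsupported graph format: {path.suffix}")


def apply_positions(graph: nx.Graph, positions: Mapping[str, tuple[float, float]]) -> None:
    """Store layout positions on nodes as ``x``/``y`` attributes."""
    for n, (x, y) in positions.items():
        graph.nodes[n]["x"] = float(x)
        graph.nodes[n]["y"] = float(y)
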