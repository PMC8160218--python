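"""Spatial network graphs, layouts, landmarks and dot summaries."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from spatialviz.errors import EmptyInputError
from spatialviz.io_formats import AnalysisConfig, CellTable
from spatialviz.network_maps import (
    build_cluster_graph,
    build_reference_graph,
    dot_summary,
    landmark_circle_positions,
    layout_spring,
    write_graph,
)
from spatialviz.single_cell_quant import call_positivity
from spatialviz.spatial_distance import marker_pair_distance_matrix, points_by_marker


def _matrix(names, rng_seed=0, n=25, spread=100.0, offsets=None):
    from spatialviz.spatial_distance import PointSet

    rng = np.random.default_rng(rng_seed)
    sets = {}
    for i, m in enumerate(names):
        center = (offsets or {}).get(m, (0.0, 0.0))
        sets[m] = PointSet(m, rng.uniform(0, spread, (n, 2)) + np.asarray(center))
    return marker_pair_distance_matrix(sets, k=3), sets


class TestBuildClusterGraph:
    def test_single_edge_normalizes_to_zero(self):
        mat, _ = _matrix(["A", "B"])
        g = build_cluster_graph(mat, {"A": 0, "B": 0}, {"A": 0.2, "B": 0.3})
        assert g.number_of_edges() == 1
        (_, _, d), = g.edges(data=True)
        assert d["normalized_weight"] == 0.0

    def test_singleton_clusters_give_edgeless_graph(self):
        mat, _ = _matrix(["A", "B", "C"])
        g = build_cluster_graph(mat, {"A": 0, "B": 1, "C": 2}, {})
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B", "C"}

    def test_node_size_is_area_ratio_and_cluster_colors(self):
        mat, _ = _matrix(["A", "B"])
        g = build_cluster_graph(mat, {"A": 0, "B": 1}, {"A": 0.25, "B": 0.5})
        assert g.nodes["A"]["size"] == 0.25
        assert g.nodes["B"]["cluster"] == 1

    def test_normalized_weights_span_unit_interval(self):
        mat, _ = _matrix(list("ABCD"), rng_seed=5)
        g = build_cluster_graph(mat, {m: 0 for m in "ABCD"}, {})
        weights = [d["normalized_weight"] for _, _, d in g.edges(data=True)]
        assert min(weights) == 0.0 and max(weights) == 1.0
        assert all(0.0 <= w <= 1.0 for w in weights)

    def test_inter_mode_edge_order_follows_region_geometry(self):
        """Three marker groups at increasing spatial separation: the
        inter-cluster edge weights must order the same way."""
        offsets = {"A": (0, 0), "B": (0, 0), "C": (300, 0), "D": (300, 0),
                   "E": (900, 0), "F": (900, 0)}
        mat, _ = _matrix(list("ABCDEF"), rng_seed=6, offsets=offsets)
        labels = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2, "F": 2}
        g = build_cluster_graph(mat, labels, {}, mode="inter")
        w01 = g.edges["cluster_0", "cluster_1"]["weight_um"]
        w12 = g.edges["cluster_1", "cluster_2"]["weight_um"]
        w02 = g.edges["cluster_0", "cluster_2"]["weight_um"]
        assert w01 < w02 and w12 < w02


class TestLayoutSpring:
    def test_all_nodes_fixed_positions_unchanged(self):
        g = nx.path_graph(["A", "B", "C"])
        pos = {"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (2.0, 0.0)}
        out = layout_spring(g, k=0.3, iterations=30, seed=0,
                            fixed_nodes=["A", "B", "C"], pos=pos)
        assert out == pos

    def test_deterministic_given_seed(self):
        g = nx.complete_graph(["A", "B", "C", "D"])
        nx.set_edge_attributes(g, 1.0, "weight_um")
        p1 = layout_spring(g, 0.3, 30, seed=42)
        p2 = layout_spring(g, 0.3, 30, seed=42)
        assert p1 == p2

    def test_single_spring_settles_at_force_balance_length(self):
        """One spring with one end pinned settles within 50% of k,
        cross-checked against an independent small-step integration of
        the Fruchterman-Reingold forces (attraction d^2/k, repulsion
        k^2/d), whose equilibrium is d = k."""
        k = 0.3
        g = nx.Graph()
        g.add_edge("A", "B", weight_um=1.0)
        out = layout_spring(g, k=k, iterations=200, seed=1,
                            fixed_nodes=["A"], pos={"A": (0.0, 0.0),
                                                    "B": (0.5, 0.5)})
        sep = np.hypot(out["A"][0] - out["B"][0], out["A"][1] - out["B"][1])

        pa = np.zeros(2)
        pb = np.array([0.5, 0.5])
        for _ in range(20000):
            delta = pb - pa
            d = max(np.hypot(*delta), 1e-9)
            force = (d * d / k - k * k / d) * delta / d
            pb = pb - 1e-3 * force  # A stays pinned
        oracle = np.hypot(*(pb - pa))
        assert oracle == pytest.approx(k, rel=1e-3)  # sanity: equilibrium is k
        assert abs(sep - oracle) <= 0.5 * k

    def test_unknown_fixed_node_rejected(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            layout_spring(g, 0.3, 30, 0, fixed_nodes=["Z"], pos={"Z": (0, 0)})


class TestReferenceGraph:
    def _setup(self, names, config=None, **kw):
        mat, sets = _matrix(names, **kw)
        config = config or AnalysisConfig()
        areas = {m: 0.1 for m in names}
        return build_reference_graph(mat, areas, config), mat

    def test_three_markers_two_outgoing_edges_each(self):
        g, _ = self._setup(["A", "B", "C"])
        assert all(g.out_degree(n) == 2 for n in g)

    def test_out_degree_is_min_five_or_n_minus_one(self):
        names = [f"M{i}" for i in range(9)]
        g, _ = self._setup(names)
        assert all(g.out_degree(n) == 5 for n in g)

    def test_edges_point_at_closest_markers(self):
        """Every directed edge (u, v): v is among u's 5 closest markers
        by mean k-NN distance, recomputed from the matrix."""
        names = [f"M{i}" for i in range(8)]
        g, mat = self._setup(names, rng_seed=9)
        for u in g:
            closest = set(mat.loc[u].drop(u).nsmallest(5).index)
            for _, v in g.out_edges(u):
                assert v in closest

    def test_planted_nearest_partner_is_targeted(self):
        from spatialviz.spatial_distance import PointSet
        from spatialviz.synthetic_fixtures import generate_point_pattern

        a, b = generate_point_pattern(50, 50, 5.0, 0.1, seed=3)
        rng = np.random.default_rng(4)
        far = {f"F{i}": PointSet(f"F{i}", rng.uniform(5000, 6000, (50, 2)))
               for i in range(5)}
        sets = {"A": PointSet("A", a), "B": PointSet("B", b), **far}
        mat = marker_pair_distance_matrix(sets, k=1)
        g = build_reference_graph(mat, {m: 0.1 for m in sets}, AnalysisConfig())
        assert ("A", "B") in g.edges

    def test_landmarks_fixed_on_circle(self):
        config = AnalysisConfig()
        names = config.landmark_markers + ["GranzymeB", "CD68", "Vimentin"]
        g, _ = self._setup(names, config=config)
        circle = landmark_circle_positions(config.landmark_markers)
        for m in config.landmark_markers:
            assert g.nodes[m]["fixed"] is True
            assert (g.nodes[m]["x"], g.nodes[m]["y"]) == circle[m]
        assert g.nodes["GranzymeB"]["fixed"] is False

    def test_landmarks_unmoved_by_layout(self):
        config = AnalysisConfig()
        names = config.landmark_markers + ["GranzymeB", "CD68"]
        g, _ = self._setup(names, config=config)
        landmarks = config.landmark_markers
        init = {m: (g.nodes[m]["x"], g.nodes[m]["y"]) for m in landmarks}
        pos = layout_spring(g, config.spring_k_reference,
                            config.spring_iter_reference, seed=0,
                            fixed_nodes=landmarks, pos=init)
        for m in landmarks:
            assert pos[m] == init[m]
        pos2 = layout_spring(g, config.spring_k_reference,
                             config.spring_iter_reference, seed=0,
                             fixed_nodes=landmarks, pos=init)
        assert pos == pos2


class TestDotSummary:
    def _dataset(self, intensities: dict[str, list[float]]):
        n = len(next(iter(intensities.values())))
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "cell_id": np.arange(1, n + 1),
            "centroid_row": rng.uniform(0, 100, n),
            "centroid_col": rng.uniform(0, 100, n),
            **intensities,
        })
        return CellTable(df)

    def test_single_marker_normalizes_to_one(self):
        cells = self._dataset({"A": [70.0, 90.0]})
        pos = call_positivity(cells, AnalysisConfig())
        s = dot_summary({"d1": cells}, {"d1": {"A": 0.4}}, {"d1": pos})
        assert s.expression.loc["d1", "A"] == 1.0
        assert s.prevalence.loc["d1", "A"] == 0.4

    def test_max_marker_expression_is_one_per_dataset(self):
        cells = self._dataset({"A": [70.0, 90.0], "B": [10.0, 20.0]})
        pos = call_positivity(cells, AnalysisConfig())
        s = dot_summary({"d1": cells}, {"d1": {}}, {"d1": pos})
        assert s.expression.loc["d1"].max() == 1.0
        assert s.expression.loc["d1", "B"] < 1.0

    def test_absent_marker_has_nan_pairwise_rows(self):
        cells = self._dataset({"A": [70.0, 90.0, 80.0], "B": [0.0, 0.0, 0.0]})
        pos = call_positivity(cells, AnalysisConfig())
        s = dot_summary({"d1": cells}, {"d1": {"B": 0.0}}, {"d1": pos})
        assert s.prevalence.loc["d1", "B"] == 0.0
        rows = s.pairwise[(s.pairwise["origin"] == "A")
                          & (s.pairwise["destination"] == "B")]
        assert rows["mean_distance_um"].isna().all()

    def test_planted_offsets_mostly_below_cutoff(self):
        from spatialviz.synthetic_fixtures import generate_point_pattern

        a, b = generate_point_pattern(200, 200, 25.0, 1.0, seed=6)
        n = len(a)
        df = pd.DataFrame({
            "cell_id": np.arange(1, 2 * n + 1),
            "centroid_row": np.concatenate([a[:, 0], b[:, 0]]),
            "centroid_col": np.concatenate([a[:, 1], b[:, 1]]),
            "A": [100.0] * n + [0.0] * n,
            "B": [0.0] * n + [100.0] * n,
        })
        cells = CellTable(df)
        pos = call_positivity(cells, AnalysisConfig())
        s = dot_summary({"d1": cells}, {"d1": {}}, {"d1": pos}, cutoff_um=30.0)
        row = s.pairwise[(s.pairwise["origin"] == "A")
                         & (s.pairwise["destination"] == "B")].iloc[0]
        assert row["fraction_below_cutoff"] >= 0.99

    def test_empty_dataset_rejected(self):
        empty = CellTable(pd.DataFrame({
            "cell_id": pd.Series([], dtype=int),
            "centroid_row": pd.Series([], dtype=float),
            "centroid_col": pd.Series([], dtype=float),
            "A": pd.Series([], dtype=float),
        }))
        with pytest.raises(EmptyInputError):
            dot_summary({"d1": empty}, {}, {})


class TestSerialization:
    def test_graphml_and_json_round_trip_structure(self, tmp_path):
        mat, _ = _matrix(["A", "B", "C"])
        g = build_cluster_graph(mat, {m: 0 for m in "ABC"}, {"A": 0.1})
        write_graph(g, tmp_path / "g.graphml")
        write_graph(g, tmp_path / "g.json")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.number_of_edges()
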