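import math

import numpy as np
import pytest

from braingraph.graph_core import (
    FiberBundleRecord,
    InputError,
    Parcellation,
    Scope,
    WeightScheme,
    apply_weight_scheme,
    build_graph,
    read_graph,
    subgraph_by_scope,
    write_graph,
)

from conftest import fiber_frame, make_graph


class TestWeightSchemes:
    @pytest.mark.parametrize(
        "scheme,expected",
        [
            ("Unweighted", 1.0),
            ("FiberN", 3.0),
            ("FAMean", 0.5),
            ("FiberLengthMean", 20.0),
            ("FiberNDivLength", 0.15),
        ],
    )
    def test_weight_definitions(self, scheme, expected):
        record = FiberBundleRecord("a", "b", 3, 20.0, 0.5)
        assert apply_weight_scheme(record, scheme) == pytest.approx(expected)

    def test_unweighted_ignores_bundle_summary(self):
        record = FiberBundleRecord("x", "y", 7, 33.0, 0.42)
        assert apply_weight_scheme(record, WeightScheme.UNWEIGHTED) == 1.0

    def test_unknown_scheme_is_configuration_error(self):
        record = FiberBundleRecord("a", "b", 1, 1.0, 0.5)
        with pytest.raises(InputError):
            apply_weight_scheme(record, "FiberCount")

    @pytest.mark.parametrize(
        "count,length,fa", [(0, 10.0, 0.5), (1, 0.0, 0.5), (1, 10.0, 1.5)]
    )
    def test_record_invariants(self, count, length, fa):
        with pytest.raises(InputError):
            FiberBundleRecord("a", "b", count, length, fa)


class TestBuildGraph:
    def test_single_bundle(self, square_parcellation):
        g = build_graph(
            fiber_frame([("a", "b", 3, 20.0, 0.5)]), square_parcellation, "FiberN"
        )
        assert g.n == 4  # isolated parcellation nodes retained
        assert g.edge_dict() == {("a", "b"): 3.0}

    def test_loops_deleted(self, square_parcellation):
        g = build_graph(
            fiber_frame([("a", "a", 5, 10.0, 0.4)]), square_parcellation, "FiberN"
        )
        assert g.n_edges == 0

    def test_empty_records_keep_all_nodes(self):
        nodes = tuple(f"r{i:03d}" for i in range(83))
        parc = Parcellation(nodes, {n: "left" for n in nodes})
        g = build_graph(fiber_frame([]), parc, "Unweighted")
        assert g.n == 83 and g.n_edges == 0

    def test_duplicate_pair_rejected(self, square_parcellation):
        rows = [("a", "b", 1, 5.0, 0.5), ("b", "a", 2, 6.0, 0.4)]
        with pytest.raises(InputError, match="duplicate"):
            build_graph(fiber_frame(rows), square_parcellation, "FiberN")

    def test_unknown_endpoint_rejected(self, square_parcellation):
        with pytest.raises(InputError, match="not in parcellation"):
            build_graph(
                fiber_frame([("a", "zz", 1, 5.0, 0.5)]), square_parcellation,
                "FiberN",
            )

    def test_zero_fa_edge_dropped(self, square_parcellation):
        rows = [("a", "b", 1, 5.0, 0.0), ("a", "c", 1, 5.0, 0.5)]
        g = build_graph(fiber_frame(rows), square_parcellation, "FAMean")
        assert g.edge_dict() == {("a", "c"): 0.5}

    def test_matrix_invariants(self, square_parcellation, rng):
        rows = [
            ("a", "b", 3, 20.0, 0.5),
            ("a", "c", 1, 10.0, 0.4),
            ("b", "d", 2, 12.0, 0.3),
            ("c", "d", 4, 30.0, 0.6),
        ]
        for scheme in WeightScheme:
            g = build_graph(fiber_frame(rows), square_parcellation, scheme)
            A = g.adjacency
            assert np.allclose(A, A.T)
            assert np.all(np.diag(A) == 0)
            assert np.all(g.w > 0)
            assert np.allclose(g.laplacian.sum(axis=1), 0.0, atol=1e-9)
            assert np.allclose(g.degrees, A.sum(axis=1))
            P = g.transition_matrix()
            assert np.allclose(P.sum(axis=1), 1.0)


class TestScopes:
    def test_left_induced_subgraph(self, square_parcellation):
        rows = [
            ("a", "b", 1, 5.0, 0.5),  # left-left
            ("c", "d", 1, 5.0, 0.5),  # right-right
            ("a", "c", 1, 5.0, 0.5),
            ("b", "d", 1, 5.0, 0.5),
            ("a", "d", 1, 5.0, 0.5),
            ("b", "c", 1, 5.0, 0.5),
        ]
        g = build_graph(fiber_frame(rows), square_parcellation, "Unweighted")
        left = subgraph_by_scope(g, square_parcellation, Scope.LEFT)
        assert left.nodes == ("a", "b")
        assert left.edge_dict() == {("a", "b"): 1.0}

    def test_all_scope_is_identity(self, square_parcellation):
        g = build_graph(
            fiber_frame([("a", "d", 2, 9.0, 0.5)]), square_parcellation, "FiberN"
        )
        assert subgraph_by_scope(g, square_parcellation, "All") is g

    def test_only_interhemispheric_edges_gives_edgeless_left(
        self, square_parcellation
    ):
        rows = [("a", "c", 1, 5.0, 0.5), ("b", "d", 1, 5.0, 0.5)]
        g = build_graph(fiber_frame(rows), square_parcellation, "Unweighted")
        left = subgraph_by_scope(g, square_parcellation, "Left")
        assert left.n == 2 and left.n_edges == 0

    def test_other_nodes_only_in_all_scope(self):
        parc = Parcellation(
            ("l1", "o1", "r1"), {"l1": "left", "o1": "other", "r1": "right"}
        )
        g = build_graph(
            fiber_frame([("l1", "o1", 1, 5.0, 0.5)]), parc, "Unweighted"
        )
        assert subgraph_by_scope(g, parc, "Left").nodes == ("l1",)
        assert subgraph_by_scope(g, parc, "All").n == 3

    def test_edge_partition_counts(self, rng):
        nodes = [f"l{i}" for i in range(5)] + [f"r{i}" for i in range(5)] + ["o0"]
        hemi = {n: ("left" if n[0] == "l" else "right" if n[0] == "r" else "other")
                for n in nodes}
        parc = Parcellation(tuple(sorted(nodes)), hemi)
        rows = []
        for i, u in enumerate(sorted(nodes)):
            for v in sorted(nodes)[i + 1:]:
                if rng.random() < 0.5:
                    rows.append((u, v, 1, 5.0, 0.5))
        g = build_graph(fiber_frame(rows), parc, "Unweighted")
        left = subgraph_by_scope(g, parc, "Left").n_edges
        right = subgraph_by_scope(g, parc, "Right").n_edges
        cross_or_other = sum(
            1 for (u, v) in g.edge_dict()
            if hemi[u] != hemi[v] or "other" in (hemi[u], hemi[v])
        )
        assert left + right + cross_or_other == g.n_edges == len(rows)


class TestGraphIO:
    def test_csv_round_trip(self, tmp_path):
        g = make_graph({("a", "b"): 1.0, ("b", "c"): 2.0, ("a", "c"): 3.0})
        path = tmp_path / "g.csv"
        write_graph(g, path)
        g2 = read_graph(path)
        assert g2.nodes == g.nodes
        assert g2.edge_dict() == pytest.approx(g.edge_dict(), rel=1e-12)

    def test_graphml_round_trip_preserves_isolated_node(self, tmp_path):
        g = make_graph({("a", "b"): 0.25}, nodes=["isolated"])
        path = tmp_path / "g.graphml"
        write_graph(g, path)
        g2 = read_graph(path)
        assert g2.nodes == ("a", "b", "isolated")
        assert g2.edge_dict() == pytest.approx({("a", "b"): 0.25}, rel=1e-12)

    def test_negative_weight_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("node_u,node_v,weight\na,b,-1\n")
        with pytest.raises(InputError, match="invalid weight"):
            read_graph(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("node_u,node_v,weight\na,b,1.0\nc,d\n")
        with pytest.raises(InputError, match=":3"):
            read_graph(path)
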