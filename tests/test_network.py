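"""Correlation matrix, HRR transform, network thresholds and topology metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrrnet.expression import ExpressionMatrix
from hrrnet.network import (
    CorrelationMatrix,
    build_network,
    hrr_transform,
    pearson_matrix,
    topology_report,
    write_sif,
)
from conftest import toy_matrix


def corr_from(gene_ids, entries):
    """Build a CorrelationMatrix from {(a, b): r} (symmetrised, diag 1)."""
    n = len(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    r = np.eye(n)
    for (a, b), val in entries.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    return CorrelationMatrix(tuple(gene_ids), r)


def brute_force_hrr(absr, gene_ids):
    """Independent rank enumerator: explicit per-gene sorted partner lists."""
    n = len(gene_ids)
    rank = {}
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        partners.sort(key=lambda j: (-absr[i][j], gene_ids[j]))
        for pos, j in enumerate(partners, start=1):
            rank[(i, j)] = pos
    out = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i][j] = max(rank[(i, j)], rank[(j, i)])
    return np.array(out)


class TestPearson:
    def test_self_correlation_is_one(self):
        m = toy_matrix({"g1": [1, 2, 3, 4], "g2": [1, 3, 2, 4], "g3": [4, 1, 2, 2]})
        corr = pearson_matrix(m)
        assert np.allclose(np.diag(corr.r), 1.0)

    def test_perfect_anticorrelation(self):
        m = toy_matrix({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1], "c": [1, 1, 2, 1]})
        assert pearson_matrix(m).value("a", "b") == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r((1,2,3), (1,2,4)) by the definition: 0.981980...
        cols = ["A_1", "A_2", "A_3"]
        df = pd.DataFrame([[1, 2, 3], [1, 2, 4], [2, 2, 3]], index=["x", "y", "z"], columns=cols)
        corr = pearson_matrix(ExpressionMatrix(df.astype(float)))
        assert corr.value("x", "y") == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_fewer_than_three_samples_errors(self):
        m = toy_matrix({"a": [1, 2], "b": [2, 1]}, stages=("A",), reps=2)
        with pytest.raises(ValueError, match="3 observations"):
            pearson_matrix(m)

    def test_zero_variance_gene_flagged_and_zeroed(self):
        m = toy_matrix({"flat": [2, 2, 2, 2], "g": [1, 2, 3, 4], "h": [1, 3, 2, 4]})
        corr = pearson_matrix(m)
        assert corr.constant_genes == {"flat"}
        assert corr.value("flat", "g") == 0.0
        assert corr.value("flat", "flat") == 1.0


class TestHrrTransform:
    def test_three_gene_hand_enumeration(self):
        # |r|: AB=0.9, AC=0.85, BC=0.95
        corr = corr_from("ABC", {("A", "B"): 0.9, ("A", "C"): 0.85, ("B", "C"): 0.95})
        hrr = hrr_transform(corr)
        idx = {g: i for i, g in enumerate("ABC")}
        assert hrr[idx["B"], idx["C"]] == 1
        assert hrr[idx["A"], idx["B"]] == 2
        assert hrr[idx["A"], idx["C"]] == 2

    def test_reciprocal_best_hit_is_one(self):
        corr = corr_from("ABCD", {("A", "B"): 0.99, ("A", "C"): 0.5, ("B", "D"): 0.4,
                                  ("A", "D"): 0.1, ("B", "C"): 0.2, ("C", "D"): 0.3})
        hrr = hrr_transform(corr)
        assert hrr[0, 1] == 1

    def test_negative_correlations_rank_by_magnitude(self):
        corr = corr_from("ABC", {("A", "B"): -0.95, ("A", "C"): 0.5, ("B", "C"): 0.1})
        hrr = hrr_transform(corr)
        assert hrr[0, 1] == 1  # |−0.95| is A's and B's strongest partner

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(10, 30))
    def test_matches_brute_force_enumerator(self, seed, n):
        """Vectorised HRR equals the explicit double-loop rank enumerator."""
        rng = np.random.default_rng(seed)
        r = np.clip((rng.uniform(-1, 1, (n, n)) + rng.uniform(-1, 1, (n, n)).T) / 2, -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        genes = tuple(f"g{i:03d}" for i in range(n))
        corr = CorrelationMatrix(genes, r)
        expected = brute_force_hrr(np.abs(r), genes)
        np.testing.assert_array_equal(hrr_transform(corr), expected)

    def test_symmetric_by_construction(self, rng):
        r = rng.uniform(-1, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        hrr = hrr_transform(CorrelationMatrix(tuple(f"g{i}" for i in range(12)), r))
        np.testing.assert_array_equal(hrr, hrr.T)


class TestBuildNetwork:
    def test_r_boundary_inclusive(self):
        corr = corr_from("ABC", {("A", "B"): 0.8, ("A", "C"): 0.79, ("B", "C"): 0.1})
        g = build_network(corr, hrr_transform(corr), r_min=0.8, hrr_max=30)
        assert g.has_edge("A", "B")
        assert not g.has_edge("A", "C")

    def test_hrr_cutoff_inclusive(self):
        corr = corr_from("ABCD", {("A", "B"): 0.99, ("A", "C"): 0.95, ("A", "D"): 0.9,
                                  ("B", "C"): 0.85, ("B", "D"): 0.84, ("C", "D"): 0.83})
        hrr = hrr_transform(corr)
        full = build_network(corr, hrr, r_min=0.8, hrr_max=3)
        cut = build_network(corr, hrr, r_min=0.8, hrr_max=2)
        dropped = set(full.edges()) - set(cut.edges())
        assert all(hrr[ord(a) - 65, ord(b) - 65] > 2 for a, b in dropped)
        assert all(d["hrr"] <= 2 for _, _, d in cut.edges(data=True))

    def test_high_correlation_quartet_is_complete(self):
        corr = corr_from(
            "ABCD",
            {(a, b): 0.9 + 0.01 * i for i, (a, b) in enumerate(itertools.combinations("ABCD", 2))},
        )
        g = build_network(corr, hrr_transform(corr))
        assert g.number_of_edges() == 6

    def test_negative_edge_sign(self):
        corr = corr_from("ABC", {("A", "B"): -0.9, ("A", "C"): 0.85, ("B", "C"): 0.2})
        g = build_network(corr, hrr_transform(corr))
        assert g.edges["A", "B"]["sign"] == "negative"

    def test_edge_monotonicity_in_both_thresholds(self, rng):
        r = rng.uniform(-1, 1, (15, 15))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = CorrelationMatrix(tuple(f"g{i:02d}" for i in range(15)), r)
        hrr = hrr_transform(corr)
        loose = build_network(corr, hrr, r_min=0.3, hrr_max=10)
        tight = build_network(corr, hrr, r_min=0.5, hrr_max=5)
        assert set(tight.edges()) <= set(loose.edges())

    def test_constant_gene_excluded(self):
        corr = CorrelationMatrix(("a", "b", "c"), np.eye(3), frozenset({"c"}))
        g = build_network(corr, hrr_transform(corr))
        assert "c" not in g

    def test_inverse_hrr_weight_rule(self):
        corr = corr_from("ABC", {("A", "B"): 0.9, ("A", "C"): 0.85, ("B", "C"): 0.95})
        g = build_network(corr, hrr_transform(corr), weight="inverse_hrr")
        assert g.edges["B", "C"]["weight"] == 1.0
        assert g.edges["A", "B"]["weight"] == 0.5

    def test_cutoff_bin_weight_matches_printed_mapping(self):
        corr = corr_from("ABC", {("A", "B"): 0.9, ("A", "C"): 0.85, ("B", "C"): 0.95})
        hrr = hrr_transform(corr)
        for cutoff, expected in ((10, 1 / 5), (20, 1 / 15), (30, 1 / 25)):
            g = build_network(corr, hrr, hrr_max=cutoff)
            assert g.edges["A", "B"]["weight"] == pytest.approx(expected)

    def test_sif_export_lists_edges_and_orphans(self, tmp_path):
        corr = corr_from("ABC", {("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.2})
        g = build_network(corr, hrr_transform(corr))
        path = tmp_path / "net.sif"
        write_sif(g, path)
        lines = path.read_text().splitlines()
        assert "A\tco-expr\tB" in lines
        assert "C" in lines  # isolated node row


class TestTopology:
    def test_triangle_closed_forms(self):
        rep = topology_report(nx.complete_graph(3))
        assert (rep.density, rep.clustering_coefficient, rep.diameter) == (1.0, 1.0, 1)
        assert rep.connected_components == 1

    def test_complete_graphs_closed_forms(self):
        for n in (4, 6, 8):
            rep = topology_report(nx.complete_graph(n))
            assert rep.density == pytest.approx(1.0)
            assert rep.avg_neighbors == pytest.approx(n - 1)
            assert rep.characteristic_path_length == pytest.approx(1.0)
            assert rep.heterogeneity == 0.0

    def test_star_has_no_triangles(self):
        rep = topology_report(nx.star_graph(4))  # hub + 4 leaves
        assert rep.clustering_coefficient == 0.0
        assert rep.diameter == 2
        assert rep.centralization == pytest.approx(1.0)

    def test_path_graph_metrics(self):
        rep = topology_report(nx.path_graph(5))
        assert rep.diameter == 4
        # CPL over connected pairs: mean of {1,2,3,4} distances
        dists = [abs(i - j) for i in range(5) for j in range(5) if i != j]
        assert rep.characteristic_path_length == pytest.approx(np.mean(dists))

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        rep = topology_report(g)
        assert rep.connected_components == 2
        assert rep.avg_neighbors == pytest.approx(1.0)
        assert rep.density == pytest.approx(1 / 3)
        assert rep.diameter == 1  # finite distances only

    def test_diameter_bounds_path_length(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=7)
        rep = topology_report(g)
        assert rep.diameter >= rep.characteristic_path_length

    def test_permutation_invariance(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        mapping = dict(zip(g.nodes(), rng.permutation(list(g.nodes()))))
        h = nx.relabel_nodes(g, {k: int(v) for k, v in mapping.items()})
        a, b = topology_report(g), topology_report(h)
        for field_name in ("n_nodes", "n_edges", "diameter", "connected_components"):
            assert getattr(a, field_name) == getattr(b, field_name)
        for field_name in ("density", "clustering_coefficient", "heterogeneity",
                           "centralization", "characteristic_path_length"):
            assert getattr(a, field_name) == pytest.approx(getattr(b, field_name))
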