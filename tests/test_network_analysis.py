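"""Thresholded subnetworks, neighbor augmentation, orphan rescue, overlap."""

import itertools

import networkx as nx
import numpy as np
import pytest

from yana.network_analysis import (
    clusters,
    cross_species_overlap,
    degree_filter,
    export_graph,
    extend_with_neighbors,
    import_graphml,
    load_edges,
    primary_network,
    rescue_orphans,
    write_edges,
)
from yana.ortholog_map import OrthologTable

from conftest import build_network


def write_edge_file(tmp_path, rows, name="edges.tsv"):
    path = tmp_path / name
    path.write_text("geneA\tgeneB\tscore\n" +
                    "".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))
    return path


class TestLoadEdges:
    def test_threshold_is_inclusive(self, tmp_path):
        path = write_edge_file(tmp_path, [("A", "B", 900), ("B", "C", 899)])
        net = load_edges(path, 0.900)
        assert set(net.graph.edges) == {("A", "B")}

    def test_symmetric_duplicates_keep_max(self, tmp_path):
        path = write_edge_file(tmp_path, [("A", "B", 950), ("B", "A", 920)])
        net = load_edges(path)
        assert net.graph.edges["A", "B"]["confidence"] == 0.95

    def test_score_out_of_range_is_parse_error(self, tmp_path):
        path = write_edge_file(tmp_path, [("A", "B", 1500)])
        with pytest.raises(ValueError, match="outside"):
            load_edges(path)

    def test_raising_threshold_never_adds_edges(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = [(f"n{i}", f"n{j}", int(rng.integers(0, 1001)))
                for i in range(15) for j in range(i + 1, 15)]
        path = write_edge_file(tmp_path, rows)
        low = set(load_edges(path, 0.5).graph.edges)
        high = set(load_edges(path, 0.9).graph.edges)
        assert {frozenset(e) for e in high} <= {frozenset(e) for e in low}

    def test_round_trip_through_writer(self, tmp_path):
        path = write_edge_file(tmp_path, [("A", "B", 950), ("C", "D", 901)])
        net = load_edges(path)
        out = tmp_path / "back.tsv"
        write_edges(net, out)
        again = load_edges(out)
        assert set(again.graph.edges) == set(net.graph.edges)


class TestPrimaryNetwork:
    def test_edgeless_hits_are_all_orphans(self):
        full = build_network([("X", "Y")])
        prim = primary_network({"A", "B"}, full)
        assert prim.orphans() == {"A", "B"}
        assert prim.graph.number_of_edges() == 0

    def test_induced_subgraph_with_orphan(self, toy_full_network):
        prim = primary_network({"A", "B", "C", "D"}, toy_full_network)
        assert set(prim.graph.edges) == {("A", "B"), ("B", "C")}
        assert prim.orphans() == {"D"}

    def test_idempotent(self, toy_full_network):
        once = primary_network({"A", "B", "C"}, toy_full_network)
        twice = primary_network({"A", "B", "C"}, once)
        assert nx.utils.graphs_equal(once.graph, twice.graph)


class TestClusters:
    def test_edgeless_graph_has_no_clusters(self):
        net = build_network([], nodes=["A", "B", "C"])
        assert clusters(net) == []

    def test_component_partition(self):
        net = build_network(
            [("a", "b"), ("b", "c"), ("d", "e"), ("f", "g")], nodes=["h"]
        )
        cs = clusters(net)
        assert [len(c) for c in cs] == [3, 2, 2]
        assert sum(len(c) for c in cs) + len(net.orphans()) == len(net.nodes)

    def test_sorted_by_size_then_smallest_member(self):
        net = build_network([("z", "y"), ("a", "b")])
        cs = clusters(net)
        assert sorted(cs[0].members) == ["a", "b"]


class TestDegreeFilter:
    def test_path_collapses_under_k2(self):
        full = build_network([("A", "B"), ("B", "C")])
        out = degree_filter({"A", "B", "C"}, full, k=2)
        assert out.nodes == {"B"}
        assert clusters(out) == []

    def test_triangle_survives_k2(self):
        full = build_network([("A", "B"), ("B", "C"), ("A", "C")])
        out = degree_filter({"A", "B", "C"}, full, k=2)
        assert out.nodes == {"A", "B", "C"}
        assert len(clusters(out)) == 1

    def test_k_zero_is_identity(self, toy_full_network):
        assert degree_filter({"A"}, toy_full_network, k=0) is toy_full_network

    def test_negative_k_rejected(self, toy_full_network):
        with pytest.raises(ValueError):
            degree_filter({"A"}, toy_full_network, k=-1)

    def test_single_pass_not_iterated_to_core(self):
        # B and C each see 2 modifiers; A and D see 1.  One pass keeps
        # {B, C} (edge B-C survives); an iterative 2-core would empty it.
        full = build_network([("A", "B"), ("B", "C"), ("C", "D")])
        out = degree_filter({"A", "B", "C", "D"}, full, k=2)
        assert out.nodes == {"B", "C"}
        assert set(out.graph.edges) == {("B", "C")}


class TestExtendWithNeighbors:
    def test_isolated_hit_stays_alone(self):
        full = build_network([("X", "Y")])
        ext = extend_with_neighbors({"A"}, full)
        assert ext.nodes == {"A"}

    def test_neighbors_and_their_edges_included(self):
        full = build_network([("A", "N"), ("N", "D"), ("D", "E")])
        ext = extend_with_neighbors({"A", "D"}, full)
        assert ext.nodes == {"A", "D", "N", "E"}
        assert {frozenset(e) for e in ext.graph.edges} == {
            frozenset(p) for p in [("A", "N"), ("N", "D"), ("D", "E")]
        }
        assert ext.roles() == {"A": "hit", "D": "hit", "N": "neighbor",
                               "E": "neighbor"}

    def test_hits_always_contained(self, toy_full_network):
        hits = {"A", "B", "Q"}
        assert hits <= extend_with_neighbors(hits, toy_full_network).nodes


def oracle_rescue(hits, edges):
    """Brute-force restatement of orphan rescue from raw qualifying edges."""
    hits = set(hits)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    orphans = {h for h in hits if not (adj.get(h, set()) & hits)}
    extended = set(hits)
    for h in hits:
        extended |= adj.get(h, set())
    rescued = {}
    for n in extended - hits:
        linked = adj.get(n, set()) & orphans
        if len(linked) >= 2:
            rescued[n] = linked
    return rescued


def run_rescue(hits, edges):
    full = build_network(edges, nodes=sorted(hits))
    prim = primary_network(hits, full)
    ext = extend_with_neighbors(hits, full)
    return rescue_orphans(hits, prim, ext)


class TestRescueOrphans:
    def test_no_orphans_means_no_rescue(self):
        assert run_rescue({"A", "B"}, [("A", "B"), ("A", "N")]) == {}

    def test_shared_neighbor_of_two_orphans_rescued(self):
        rescued = run_rescue({"A", "D"}, [("A", "N"), ("N", "D")])
        assert rescued == {"N": {"A", "D"}}

    def test_neighbor_of_single_orphan_not_rescued(self):
        assert run_rescue({"A", "D"}, [("A", "N")]) == {}

    def test_connected_hits_are_not_orphans(self):
        # A-B edge removes both from the orphan pool; N links A and D but
        # only D is still an orphan
        rescued = run_rescue(
            {"A", "B", "D"}, [("A", "B"), ("A", "N"), ("N", "D")]
        )
        assert rescued == {}

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            nodes = [f"n{i}" for i in range(n)]
            p = rng.uniform(0.1, 0.6)
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < p
            ]
            n_hits = int(rng.integers(2, n + 1))
            hits = set(rng.choice(nodes, size=n_hits, replace=False))
            assert run_rescue(hits, edges) == oracle_rescue(hits, edges)

    def test_matches_oracle_exhaustively_on_five_node_template(self):
        nodes = ["A", "B", "C", "D", "N"]
        hits = {"A", "B", "C", "D"}
        pairs = list(itertools.combinations(nodes, 2))
        for mask in range(2 ** len(pairs)):
            edges = [p for i, p in enumerate(pairs) if mask >> i & 1]
            assert run_rescue(hits, edges) == oracle_rescue(hits, edges)

    def test_rescued_nodes_get_role_in_extended(self, toy_full_network):
        hits = {"A", "D"}
        prim = primary_network(hits, toy_full_network)
        ext = extend_with_neighbors(hits, toy_full_network)
        rescue_orphans(hits, prim, ext)
        assert ext.roles()["N"] == "rescued"


class TestCrossSpeciesOverlap:
    def test_empty_tables_give_empty_overlap(self, toy_full_network):
        ext = extend_with_neighbors({"A", "D"}, toy_full_network)
        human = build_network([("CUL3", "COPS5")], species="human")
        tables = [OrthologTable("db", {"zzz": {"ZZZ"}})]
        assert cross_species_overlap(ext, human, tables).shared == set()

    def test_overlap_with_provenance(self, toy_full_network):
        ext = extend_with_neighbors({"A", "D"}, toy_full_network)
        human = build_network([("CUL3", "COPS5")], species="human")
        tables = [OrthologTable("db", {"N": {"CUL3"}, "A": {"XYZ"}})]
        report = cross_species_overlap(ext, human, tables)
        assert report.shared == {"CUL3"}
        assert report.provenance["CUL3"] == [("N", "neighbor")]
        assert report.shared <= human.nodes


class TestExport:
    def test_empty_network_exports_valid_documents(self, tmp_path):
        net = build_network([])
        export_graph(net, tmp_path / "e.sif", "sif")
        export_graph(net, tmp_path / "e.graphml", "graphml")
        assert (tmp_path / "e.sif").read_text() == ""
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0

    def test_sif_lines(self, toy_full_network, tmp_path):
        prim = primary_network({"A", "B", "C", "D"}, toy_full_network)
        export_graph(prim, tmp_path / "p.sif", "sif")
        assert (tmp_path / "p.sif").read_text() == "A pp B\nB pp C\nD\n"

    def test_graphml_round_trip(self, toy_full_network, tmp_path):
        ext = extend_with_neighbors({"A", "D"}, toy_full_network)
        export_graph(ext, tmp_path / "g.graphml", "graphml")
        back = import_graphml(tmp_path / "g.graphml")
        assert back.nodes == ext.nodes
        assert back.roles() == ext.roles()
        for u, v, c in ext.graph.edges(data="confidence"):
            assert back.graph.edges[u, v]["confidence"] == c

    def test_exports_are_byte_deterministic(self, toy_full_network, tmp_path):
        ext = extend_with_neighbors({"A", "D"}, toy_full_network)
        export_graph(ext, tmp_path / "a.graphml", "graphml")
        export_graph(ext, tmp_path / "b.graphml", "graphml")
        assert (tmp_path / "a.graphml").read_bytes() == (
            tmp_path / "b.graphml"
        ).read_bytes()

    def test_unknown_format_rejected(self, toy_full_network, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_graph(toy_full_network, tmp_path / "x", "xgmml")
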