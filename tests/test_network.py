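"""network: edge-list IO, merging, centralities vs a brute-force oracle,
assortativity classification and hub ranking."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nupvar.network import (
    assortativity_fit,
    merge_networks,
    node_metrics,
    read_edge_list,
    top_hubs,
    write_sif,
)
from nupvar.synthetic_data import SyntheticGraphSpec, gen_ppi_graph


# ---------------------------------------------------------------------------
# brute-force oracle: BFS enumeration of all shortest paths
# ---------------------------------------------------------------------------

def _all_shortest_paths(graph, source, target):
    if source == target:
        return [[source]]
    dist = {source: 0}
    queue = deque([source])
    parents = {source: []}
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    if target not in dist:
        return []
    paths = []

    def walk(node, tail):
        if node == source:
            paths.append([source] + tail[::-1])
            return
        for p in parents[node]:
            walk(p, tail + [node])

    walk(target, [])
    return [p[::-1] for p in (q[::-1] for q in paths)]


def _oracle_metrics(graph):
    n = graph.number_of_nodes()
    betweenness = {v: 0.0 for v in graph}
    closeness = {}
    for s, t in itertools.combinations(graph.nodes, 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for v in graph:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2 if n > 2 else 1
    betweenness = {v: b / scale for v, b in betweenness.items()}
    for v in graph:
        dists = [
            len(_all_shortest_paths(graph, v, u)[0]) - 1
            for u in graph
            if u != v and _all_shortest_paths(graph, v, u)
        ]
        if not dists:
            closeness[v] = 0.0
        else:
            r = len(dists)
            closeness[v] = (r / (n - 1)) * (r / sum(dists)) if n > 1 else 0.0
    knn = {
        v: (np.mean([graph.degree(u) for u in graph.neighbors(v)]) if graph.degree(v) else None)
        for v in graph
    }
    return betweenness, closeness, knn


def _assert_matches_oracle(graph):
    metrics = node_metrics(graph)
    betweenness, closeness, knn = _oracle_metrics(graph)
    for v in graph:
        assert metrics[v].betweenness == pytest.approx(betweenness[v], abs=1e-12)
        assert metrics[v].closeness == pytest.approx(closeness[v], abs=1e-12)
        if knn[v] is None:
            assert metrics[v].neighborhood_connectivity is None
        else:
            assert metrics[v].neighborhood_connectivity == pytest.approx(knn[v])


class TestEdgeListIO:
    def test_reversed_duplicate_edges_collapse(self, tmp_path):
        path = tmp_path / "g.sif"
        path.write_text("A\tpp\tB\nB\tpp\tA\n")
        graph = read_edge_list(path, format="sif")
        assert graph.number_of_edges() == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "g.sif"
        path.write_text("")
        graph = read_edge_list(path)
        assert graph.number_of_nodes() == 0

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "g.sif"
        path.write_text("A\tpp\tA\nA\tpp\tB\n")
        with caplog.at_level("WARNING"):
            graph = read_edge_list(path)
        assert graph.number_of_edges() == 1 and "self-loop" in caplog.text

    def test_multi_target_sif_line(self, tmp_path):
        path = tmp_path / "g.sif"
        path.write_text("A\tpp\tB\tC\tD\n")
        graph = read_edge_list(path)
        assert sorted(graph.edges) == [("A", "B"), ("A", "C"), ("A", "D")]

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "g.sif"
        path.write_text("A\tpp\tB\nA\tB\n")
        with pytest.raises(ValueError, match=":2"):
            read_edge_list(path)

    def test_35_node_subnetwork_roundtrip(self, tmp_path):
        graph, _ = gen_ppi_graph(SyntheticGraphSpec(n_nodes=35, seed=0))
        path = tmp_path / "g.sif"
        write_sif(graph, path)
        back = read_edge_list(path)
        assert back.number_of_nodes() == 35
        assert set(back.edges) == {tuple(sorted(e)) for e in graph.edges} or set(
            map(frozenset, back.edges)
        ) == set(map(frozenset, graph.edges))


class TestMerge:
    def test_merge_identical_is_identity(self):
        g, _ = gen_ppi_graph(SyntheticGraphSpec(n_nodes=10, seed=1))
        merged = merge_networks([g, g])
        assert set(merged.nodes) == set(g.nodes)
        assert set(map(frozenset, merged.edges)) == set(map(frozenset, g.edges))

    def test_disjoint_graphs_add(self):
        g1 = nx.path_graph(["A", "B", "C"])
        g2 = nx.path_graph(["X", "Y"])
        assert merge_networks([g1, g2]).number_of_nodes() == 5

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_union_matches_set_oracle(self, seed1, seed2):
        g1 = nx.gnp_random_graph(8, 0.4, seed=seed1)
        g2 = nx.gnp_random_graph(8, 0.4, seed=seed2)
        g2 = nx.relabel_nodes(g2, {i: i + 4 for i in g2.nodes})  # overlap 4..7
        merged = merge_networks([g1, g2])
        assert set(merged.nodes) == set(g1.nodes) | set(g2.nodes)
        union_edges = set(map(frozenset, g1.edges)) | set(map(frozenset, g2.edges))
        assert set(map(frozenset, merged.edges)) == union_edges


class TestNodeMetrics:
    def test_path_graph_closed_forms(self):
        metrics = node_metrics(nx.path_graph(["A", "B", "C"]))
        assert metrics["B"].betweenness == 1.0
        assert metrics["A"].betweenness == 0.0
        assert metrics["A"].closeness == pytest.approx(2 / 3)

    def test_complete_graph_closed_forms(self):
        metrics = node_metrics(nx.complete_graph(4))
        assert all(m.betweenness == 0.0 for m in metrics.values())
        assert all(m.closeness == 1.0 for m in metrics.values())

    def test_isolate_conventions(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("A", "B")
        m = node_metrics(g)["solo"]
        assert m.betweenness == 0.0 and m.closeness == 0.0
        assert m.neighborhood_connectivity is None

    def test_atlas_graphs_match_brute_force(self):
        # every connected-or-not simple graph on <= 6 nodes from the atlas
        from networkx.generators.atlas import graph_atlas_g

        for graph in graph_atlas_g()[1:209]:
            assert graph.number_of_nodes() <= 6
            _assert_matches_oracle(graph)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_random_graphs_match_brute_force(self, seed):
        graph = nx.gnp_random_graph(8, 0.35, seed=seed)
        _assert_matches_oracle(graph)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_label_permutation_invariance(self, seed):
        graph = nx.gnp_random_graph(9, 0.3, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(list(graph.nodes))
        mapping = dict(zip(graph.nodes, (f"n{p}" for p in perm)))
        metrics = node_metrics(graph)
        shuffled = node_metrics(nx.relabel_nodes(graph, mapping))
        for v in graph.nodes:
            assert shuffled[mapping[v]] == metrics[v]

    def test_betweenness_conservation_on_trees(self):
        tree = nx.random_labeled_tree(12, seed=5)
        metrics = node_metrics(tree)
        n = tree.number_of_nodes()
        raw = sum(m.betweenness for m in metrics.values()) * (n - 1) * (n - 2) / 2
        interior = sum(
            nx.shortest_path_length(tree, s, t) - 1
            for s, t in itertools.combinations(tree.nodes, 2)
        )
        assert raw == pytest.approx(interior)


class TestAssortativity:
    def test_star_is_disassortative(self):
        fit = assortativity_fit(nx.star_graph(8))
        assert fit.mixing == "disassortative" and fit.slope < 0

    def test_ring_is_undefined(self):
        fit = assortativity_fit(nx.cycle_graph(6))
        assert fit.mixing == "neutral/undefined" and fit.slope is None

    def test_star_slope_closed_form(self):
        # two degree classes: knn(8) = 1, knn(1) = 8 -> slope = -1 on log-log
        fit = assortativity_fit(nx.star_graph(8))
        assert fit.slope == pytest.approx(np.log(1 / 8) / np.log(8 / 1))

    def test_preferential_attachment_graphs_disassortative(self):
        hits = sum(
            assortativity_fit(
                gen_ppi_graph(SyntheticGraphSpec(n_nodes=175, attachment=2, seed=s))[0]
            ).mixing
            == "disassortative"
            for s in range(20)
        )
        assert hits >= 18


class TestTopHubs:
    def test_star_center_is_top_hub(self):
        metrics = node_metrics(nx.star_graph(8))
        assert top_hubs(metrics, 1, key="betweenness") == [0]

    def test_full_tie_breaks_lexicographically(self):
        metrics = node_metrics(nx.complete_graph(["b", "a", "c"]))
        assert top_hubs(metrics, 3, key="betweenness") == ["a", "b", "c"]

    def test_k_larger_than_n_returns_all_with_warning(self, caplog):
        metrics = node_metrics(nx.path_graph(3))
        with caplog.at_level("WARNING"):
            assert len(top_hubs(metrics, 10)) == 3

    def test_planted_hub_recovered(self):
        hits = 0
        for seed in range(20):
            graph, hubs = gen_ppi_graph(
                SyntheticGraphSpec(n_nodes=175, attachment=2, seed=seed)
            )
            metrics = node_metrics(graph)
            hits += top_hubs(metrics, 1, key="betweenness")[0] in hubs
        assert hits >= 18
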