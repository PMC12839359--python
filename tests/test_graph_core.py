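"""Topology metrics against hand computations, brute-force enumeration and
an independent library implementation."""

import io
import math

import networkx as nx
import numpy as np
import pytest

from mimicnet.graph_core import (
    Network,
    betweenness,
    centrality_report,
    closeness,
    connected_components,
    ego_network,
    topology_summary,
    write_centrality_tsv,
    write_graphml,
)

from .oracles import (
    all_shortest_paths,
    adjacency,
    brute_betweenness,
    brute_closeness,
    brute_topology,
    random_network,
    random_tree,
)


class TestNetworkConstruction:
    def test_self_loops_and_duplicates_collapse(self):
        net = Network([("A", "B"), ("B", "A"), ("A", "A"), ("A", "B")])
        assert net.n_nodes == 2
        assert net.n_edges == 1
        assert net.n_loops_dropped == 1
        assert net.n_duplicates_dropped == 2

    def test_edge_endpoints_are_members(self):
        net = Network([("A", "B")])
        assert set(net.nodes) == {"A", "B"}
        assert net.has_edge("B", "A")  # symmetric

    def test_unknown_node_raises(self):
        net = Network([("A", "B")])
        with pytest.raises(KeyError, match="unknown node"):
            net.neighbors("Z")

    def test_iteration_is_sorted(self):
        net = Network([("z", "a"), ("m", "a")])
        assert net.nodes == ["a", "m", "z"]
        assert net.edges() == [("a", "m"), ("a", "z")]


class TestConnectedComponents:
    @pytest.mark.parametrize(
        "edges, nodes, expected_sizes",
        [
            ([("A", "B"), ("B", "C")], (), [3]),
            ([], ("A", "B"), [1, 1]),
            # two triangles plus an isolated node
            (
                [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")],
                ("iso",),
                [3, 3, 1],
            ),
        ],
    )
    def test_component_sizes(self, edges, nodes, expected_sizes):
        comps = connected_components(Network(edges, nodes))
        assert sorted((len(c) for c in comps), reverse=True) == sorted(expected_sizes, reverse=True)

    def test_partition_covers_every_node_once(self, barbell7):
        comps = connected_components(barbell7)
        allnodes = [n for c in comps for n in c]
        assert sorted(allnodes) == barbell7.nodes

    def test_empty_network(self):
        assert connected_components(Network()) == []


class TestBetweenness:
    def test_path_intermediate(self, path3):
        assert betweenness(path3) == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_counts_leaf_pairs(self, star4):
        cb = betweenness(star4)
        assert cb["X"] == pytest.approx(3.0)
        assert all(cb[leaf] == 0.0 for leaf in ("L1", "L2", "L3"))

    def test_four_cycle_split_paths(self):
        net = Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        cb = betweenness(net)
        # each opposite pair has two shortest paths; every node carries 1/2
        assert all(v == pytest.approx(0.5) for v in cb.values())

    def test_zero_for_degree_le_one(self, rng):
        for _ in range(20):
            net = random_network(rng)
            cb = betweenness(net)
            for n in net.nodes:
                if net.degree(n) <= 1:
                    assert cb[n] == 0.0

    def test_matches_networkx(self, rng):
        for _ in range(25):
            net = random_network(rng)
            ours = betweenness(net)
            theirs = nx.betweenness_centrality(net.to_networkx(), normalized=False)
            for n in net.nodes:
                assert ours[n] == pytest.approx(theirs[n], abs=1e-9)


class TestCloseness:
    def test_path_closed_form(self, path3):
        assert closeness(path3, "B") == (pytest.approx(1.0), 3)
        assert closeness(path3, "A")[0] == pytest.approx(2 / 3)

    def test_complete_graph_all_one(self):
        nodes = ["a", "b", "c", "d", "e"]
        net = Network([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]])
        assert all(closeness(net, n)[0] == pytest.approx(1.0) for n in nodes)

    def test_six_node_tree_hand_values(self):
        # star center S with leaves l1,l2,l3 and pendant chain S-p1-p2
        net = Network([("S", "l1"), ("S", "l2"), ("S", "l3"), ("S", "p1"), ("p1", "p2")])
        # distances from S: 1,1,1,1,2 -> 5/6
        assert closeness(net, "S")[0] == pytest.approx(5 / 6)
        # from p2: p1=1, S=2, leaves=3 each -> 5/(1+2+9)
        assert closeness(net, "p2")[0] == pytest.approx(5 / 12)

    def test_component_restricted_sum(self):
        net = Network([("A", "B"), ("C", "D")])
        raw, n = closeness(net, "A")
        assert (raw, n) == (1.0, 2)  # only its own component counts

    def test_isolated_node_zero(self):
        net = Network(nodes=("A",))
        assert closeness(net, "A") == (0.0, 1)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            net = random_network(rng)
            for n in net.nodes:
                assert closeness(net, n)[0] == pytest.approx(brute_closeness(net, n), abs=1e-12)


class TestCentralityReport:
    def test_norm_attains_one_at_argmax(self, rng):
        for _ in range(20):
            net = random_network(rng)
            reports = centrality_report(net)
            raws = [r.closeness_raw for r in reports]
            if max(raws) == 0:
                continue
            norms = [r.closeness_norm for r in reports]
            assert max(norms) == pytest.approx(1.0)
            argmax_raw = {r.node for r in reports if r.closeness_raw == max(raws)}
            argmax_norm = {r.node for r in reports if r.closeness_norm == pytest.approx(1.0)}
            assert argmax_raw == argmax_norm

    def test_degree_column_counts_incident_edges(self, barbell7):
        for r in centrality_report(barbell7):
            assert r.degree == barbell7.degree(r.node)

    def test_tsv_layout(self, path3):
        buf = io.StringIO()
        write_centrality_tsv(centrality_report(path3), buf, ["demo"])
        lines = buf.getvalue().splitlines()
        assert lines[0] == "# demo"
        assert lines[1].split("\t") == ["node", "degree", "betweenness", "closeness_raw", "closeness_norm"]
        assert len(lines) == 2 + path3.n_nodes


class TestTopologySummary:
    def test_path_example(self, path3):
        s = topology_summary(path3)
        assert (s.n_nodes, s.n_edges, s.n_components, s.lcc_size) == (3, 2, 1, 3)
        assert s.avg_path_length == pytest.approx(4 / 3)

    def test_disjoint_edges_exclude_cross_pairs(self):
        s = topology_summary(Network([("A", "B"), ("C", "D")]))
        assert s.avg_path_length == pytest.approx(1.0)
        assert s.n_components == 2

    def test_no_connected_pair_is_nan_not_zero(self):
        s = topology_summary(Network(nodes=("A", "B")))
        assert math.isnan(s.avg_path_length)

    def test_component_sizes_sum_to_n(self, rng):
        for _ in range(20):
            net = random_network(rng)
            comps = connected_components(net)
            assert sum(len(c) for c in comps) == net.n_nodes

    def test_barbell_matches_brute_force(self, barbell7):
        s = topology_summary(barbell7)
        ncomp, lcc, avg = brute_topology(barbell7)
        assert (s.n_components, s.lcc_size) == (ncomp, lcc)
        assert s.avg_path_length == pytest.approx(avg, abs=1e-12)


class TestOracleEquivalence:
    def test_betweenness_equals_path_enumeration(self, rng):
        for _ in range(60):
            net = random_network(rng)
            fast = betweenness(net)
            slow = brute_betweenness(net)
            for n in net.nodes:
                assert fast[n] == pytest.approx(slow[n], abs=1e-9)

    def test_summary_equals_all_pairs_bfs(self, rng):
        for _ in range(60):
            net = random_network(rng)
            s = topology_summary(net)
            ncomp, lcc, avg = brute_topology(net)
            assert (s.n_components, s.lcc_size) == (ncomp, lcc)
            if math.isnan(avg):
                assert math.isnan(s.avg_path_length)
            else:
                assert s.avg_path_length == pytest.approx(avg, abs=1e-9)

    def test_tree_identity_subtree_pairs(self, rng):
        """On a tree Cb(v) equals the number of node pairs whose unique path
        crosses v: sum over branch pairs of |branch_i| * |branch_j|."""
        for _ in range(20):
            tree = random_tree(rng)
            cb = betweenness(tree)
            adj = adjacency(tree)
            for v in tree.nodes:
                branch_sizes = []
                for nb in adj[v]:
                    seen = {v, nb}
                    stack = [nb]
                    while stack:
                        u = stack.pop()
                        for w in adj[u]:
                            if w not in seen:
                                seen.add(w)
                                stack.append(w)
                    branch_sizes.append(len(seen) - 1)
                expected = sum(
                    branch_sizes[i] * branch_sizes[j]
                    for i in range(len(branch_sizes))
                    for j in range(i + 1, len(branch_sizes))
                )
                assert cb[v] == pytest.approx(expected)

    def test_total_betweenness_equals_mean_intermediates(self, rng):
        """Sum of Cb over nodes = sum over connected pairs of the average
        number of interior nodes on their shortest paths."""
        for _ in range(15):
            net = random_network(rng, n_max=9)
            adj = adjacency(net)
            total = sum(betweenness(net).values())
            expected = 0.0
            nodes = net.nodes
            for i, s in enumerate(nodes):
                for t in nodes[i + 1 :]:
                    paths = all_shortest_paths(adj, s, t)
                    if paths:
                        expected += sum(len(p) - 2 for p in paths) / len(paths)
            assert total == pytest.approx(expected, abs=1e-9)


class TestEgoNetwork:
    def test_radius_zero_single_ring0_node(self, star4):
        ego = ego_network(star4, "L1", radius=0)
        assert ego.nodes == ["L1"]
        assert ego.node_attrs("L1")["ring"] == 0

    def test_star_radius_one_is_whole_star(self, star4):
        ego = ego_network(star4, "X", radius=1)
        assert set(ego.nodes) == {"X", "L1", "L2", "L3"}
        assert ego.node_attrs("L2")["ring"] == 1

    def test_path_radius_two_induced_subgraph(self):
        net = Network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        ego = ego_network(net, "A", radius=2)
        assert set(ego.nodes) == {"A", "B", "C"}
        assert [ego.node_attrs(n)["ring"] for n in ("A", "B", "C")] == [0, 1, 2]
        assert not ego.has_edge("C", "D") and "D" not in ego

    def test_unknown_seed_raises(self, path3):
        with pytest.raises(KeyError):
            ego_network(path3, "Z")

    def test_radius_diameter_returns_whole_component(self, rng):
        for _ in range(15):
            net = random_network(rng)
            seed = net.nodes[0]
            comp = next(c for c in connected_components(net) if seed in c)
            ego = ego_network(net, seed, radius=net.n_nodes)  # >= any diameter
            assert set(ego.nodes) == comp


class TestGraphml:
    def test_round_trip_preserves_topology_and_rings(self, tmp_path, star4):
        ego = ego_network(star4, "X", radius=1)
        path = tmp_path / "ego.graphml"
        write_graphml(ego, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(ego.nodes)
        assert back.nodes["L1"]["ring"] == 1
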