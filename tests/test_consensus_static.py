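import itertools

import networkx as nx
import numpy as np
import pytest

import pwconsensus as pw
from pwconsensus.consensus_static import (
    ConsensusSet, build_consensus_graph, consensus_profiles, intersect_layers,
    steiner_tree,
)
from pwconsensus.errors import ValidationError
from pwconsensus.knowledge_base import KnowledgeBase, Pathway, PPINetwork, TFTargetMap
from pwconsensus.layer_analysis import DownstreamResult, UpstreamResult


def ppi_from_edges(edges):
    graph = nx.Graph()
    for u, v, s in edges:
        graph.add_edge(u, v, score=s)
    return PPINetwork(graph)


def exhaustive_steiner_weight(graph, terminals):
    """Minimum Steiner tree weight by enumeration over non-terminal subsets."""
    others = sorted(set(graph.nodes) - set(terminals))
    best = None
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            sub = graph.subgraph(set(terminals) | set(extra))
            comps = [c for c in nx.connected_components(sub) if set(terminals) <= c]
            if not comps:
                continue
            tree = nx.minimum_spanning_tree(sub.subgraph(comps[0]), weight="weight")
            pruned = tree.copy()
            while True:
                leaves = [n for n in pruned
                          if pruned.degree(n) <= 1 and n not in terminals]
                if not leaves:
                    break
                pruned.remove_nodes_from(leaves)
            weight = sum(d["weight"] for _, _, d in pruned.edges(data=True))
            if best is None or weight < best:
                best = weight
    return best


class TestIntersectLayers:
    def make_inputs(self, series_factory):
        down = DownstreamResult(1.0, {"K0"}, {"PW1"}, {"TF0", "TF1"}, {"G1", "G2"})
        up = UpstreamResult(1.0, {"G2", "G3"}, {"TF1", "TF2"}, {"PW1"}, {"K0", "X"})
        logfc = np.array([[0.0, 1.0], [0.0, 0.0]])
        sig = np.array([[False, True], [False, False]])
        phospho = series_factory("phosphoprotein", ["K0", "Z"], [0, 1], logfc, sig)
        return down, up, phospho

    def test_layerwise_intersections(self, series_factory):
        down, up, phospho = self.make_inputs(series_factory)
        cs = intersect_layers(down, up, phospho)
        assert cs.proteins == {"K0"}
        assert cs.tfs == {"TF1"}
        assert cs.genes == {"G2"}

    def test_timepoint_mismatch_rejected(self, series_factory):
        down, up, phospho = self.make_inputs(series_factory)
        up.timepoint = 4.0
        with pytest.raises(ValidationError):
            intersect_layers(down, up, phospho)


class TestSteinerTree:
    def test_path_with_steiner_node(self):
        ppi = ppi_from_edges([("A", "B", 0.5), ("B", "C", 0.5)])
        tree, steiner = steiner_tree(ppi, {"A", "C"})
        assert sorted(map(tuple, map(sorted, tree.edges))) == [("A", "B"), ("B", "C")]
        assert steiner == {"B"}

    def test_single_terminal(self):
        ppi = ppi_from_edges([("A", "B", 0.5)])
        tree, steiner = steiner_tree(ppi, {"A"})
        assert set(tree.nodes) == {"A"} and not tree.edges and not steiner

    def test_four_cycle_lexicographic_tie_break(self):
        ppi = ppi_from_edges(
            [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5), ("D", "A", 0.5)]
        )
        tree, _ = steiner_tree(ppi, {"A", "C"})
        assert sorted(map(tuple, map(sorted, tree.edges))) == [("A", "B"), ("B", "C")]

    def test_disconnected_terminals_give_forest(self):
        graph = nx.Graph()
        for u, v in [("A", "B"), ("C", "D")]:
            graph.add_edge(u, v, score=0.9)
        ppi = PPINetwork.__new__(PPINetwork)  # bypass connectivity check
        ppi.graph = graph
        tree, _ = steiner_tree(ppi, {"A", "B", "C", "D"})
        assert nx.is_forest(tree)
        assert nx.number_connected_components(tree) == 2

    def test_missing_terminals_dropped_with_warning(self, caplog):
        ppi = ppi_from_edges([("A", "B", 0.5)])
        with caplog.at_level("WARNING"):
            tree, _ = steiner_tree(ppi, {"A", "ZZ"})
        assert "ZZ" in caplog.text
        assert set(tree.nodes) == {"A"}
        empty, steiner = steiner_tree(ppi, {"ZZ"})
        assert not empty.nodes and not steiner

    def test_two_approximation_on_random_graphs(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 40:
            n = int(rng.integers(5, 13))
            graph = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            comp = max(nx.connected_components(graph), key=len)
            if len(comp) < 3:
                continue
            graph = nx.relabel_nodes(graph.subgraph(comp).copy(),
                                     {i: f"N{i:02d}" for i in graph.nodes})
            for u, v in graph.edges:
                score = float(rng.uniform(0.1, 0.99))
                graph[u][v]["score"] = score
                graph[u][v]["weight"] = 1 - score
            k = int(rng.integers(2, min(5, len(comp)) + 1))
            terminals = sorted(rng.choice(sorted(graph.nodes), size=k, replace=False))
            tree, _ = steiner_tree(PPINetwork(graph), terminals)
            weight = sum(1 - graph[u][v]["score"] for u, v in tree.edges)
            opt = exhaustive_steiner_weight(graph, terminals)
            assert all(t in tree for t in terminals)
            assert nx.is_forest(tree)
            assert weight <= 2 * (1 - 1 / k) * opt + 1e-9
            checked += 1


class TestBuildConsensusGraph:
    def make_kb(self):
        pathway = Pathway("PW1", "p", "t", {"K0", "TF0"})
        return KnowledgeBase(
            [pathway],
            TFTargetMap({"TF0": {"G1", "K0"}}),
            ppi_from_edges([("K0", "TF0", 0.9)]),
        )

    def test_composition(self):
        cs = ConsensusSet(1.0, {"K0"}, {"TF0"}, {"G1"})
        graph = build_consensus_graph(cs, self.make_kb())
        kinds = sorted(kind for _s, _t, kind in graph.edges)
        assert kinds == ["ppi_steiner", "tf_target"]
        assert (("TF0", "tf"), ("G1", "gene"), "tf_target") in graph.edges

    def test_feedback_edge_added(self):
        cs = ConsensusSet(1.0, {"K0"}, {"TF0"}, {"K0"})
        graph = build_consensus_graph(cs, self.make_kb())
        assert (("K0", "gene"), ("K0", "protein"), "feedback") in graph.edges

    def test_no_tf_target_edge_for_non_target(self):
        cs = ConsensusSet(1.0, {"K0"}, {"TF0"}, {"G9"})
        graph = build_consensus_graph(cs, self.make_kb())
        assert not [e for e in graph.edges if e[2] == "tf_target"]

    def test_deterministic(self):
        cs = ConsensusSet(1.0, {"K0"}, {"TF0"}, {"G1", "K0"})
        g1 = build_consensus_graph(cs, self.make_kb())
        g2 = build_consensus_graph(cs, self.make_kb())
        assert g1.nodes == g2.nodes and g1.edges == g2.edges

    def test_feedback_edges_well_formed_on_fixture(self, noiseless_bundle, noiseless_spec):
        kb, phospho, transcripts, _ = noiseless_bundle
        for t in (1.0, 8.0, 24.0):
            down = pw.run_downstream(phospho, kb, t)
            up = pw.run_upstream(transcripts, kb, t)
            cs = intersect_layers(down, up, phospho)
            graph = build_consensus_graph(cs, kb)
            for source, target, kind in graph.edges:
                if kind == "feedback":
                    assert source[0] == target[0]
                    assert (source[1], target[1]) == ("gene", "protein")
            # the ppi_steiner subgraph is acyclic per component
            sub = nx.Graph(
                (s[0], t[0]) for s, t, k in graph.edges if k == "ppi_steiner"
            )
            assert nx.is_forest(sub) or sub.number_of_nodes() == 0


class TestConsensusProfiles:
    def graph_at(self, t, nodes):
        return pw.ConsensusGraph(t, nodes, [], set())

    def test_presence_matrix(self):
        g1 = self.graph_at(1.0, [("G1", "gene")])
        g4 = self.graph_at(4.0, [("G1", "gene")])
        g8 = self.graph_at(8.0, [("V1", "steiner")])
        profiles = consensus_profiles([g1, g4, g8])
        assert profiles.loc[("G1", "gene")].tolist() == [True, True, False]
        assert profiles.loc[("V1", "steiner")].tolist() == [False, False, True]

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            consensus_profiles([self.graph_at(1.0, []), self.graph_at(1.0, [])])

    def test_empty_list_gives_empty_matrix(self):
        profiles = consensus_profiles([])
        assert profiles.shape == (0, 0)
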