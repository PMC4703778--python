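import numpy as np
import pytest

from pwconsensus.errors import ValidationError
from pwconsensus.knowledge_base import KnowledgeBase, Pathway, PPINetwork, TFTargetMap
from pwconsensus.layer_analysis import run_downstream, run_upstream, upstream_regulators

import networkx as nx


def _kb(pathways, tf_map, ppi_edges=(("A0", "A1", 0.9),)):
    graph = nx.Graph()
    for u, v, s in ppi_edges:
        graph.add_edge(u, v, score=s)
    return KnowledgeBase(pathways, TFTargetMap(tf_map), PPINetwork(graph))


def _series(molecules, significant_at_1h, layer="phosphoprotein"):
    logfc = np.zeros((len(molecules), 2))
    sig = np.zeros_like(logfc, dtype=bool)
    for i, m in enumerate(molecules):
        sig[i, 1] = m in significant_at_1h
    import pwconsensus as pw
    return pw.OmicsTimeSeries(layer, molecules, np.array([0.0, 1.0]), logfc, sig)


class TestDownstream:
    def test_hand_enumeration(self):
        kb = _kb(
            [Pathway("PW1", "p", "t", {"K0", "TF0", "X"})],
            {"TF0": {"G1", "G2"}, "TF9": {"G3"}},
        )
        result = run_downstream(_series(["K0", "Z"], {"K0"}), kb, 1.0)
        assert result.pathway_hits == {"PW1"}
        assert result.tfs == {"TF0"}
        assert result.target_genes == {"G1", "G2"}

    def test_no_significant_molecules(self):
        kb = _kb([Pathway("PW1", "p", "t", {"K0"})], {"TF0": {"G1"}})
        result = run_downstream(_series(["K0"], set()), kb, 1.0)
        assert not (result.phosphoproteins | result.pathway_hits
                    | result.tfs | result.target_genes)

    def test_significant_outside_all_pathways(self):
        kb = _kb([Pathway("PW1", "p", "t", {"K0"})], {"TF0": {"G1"}})
        result = run_downstream(_series(["Z"], {"Z"}), kb, 1.0)
        assert result.phosphoproteins == {"Z"}
        assert not (result.pathway_hits | result.tfs | result.target_genes)


class TestUpstreamRegulators:
    def test_traversal_depth_capped_at_order(self):
        # chain P12 -> P11 -> ... -> P1 -> TF0; order 10 reaches exactly P1..P10
        chain = [f"P{i}" for i in range(12, 0, -1)] + ["TF0"]
        edges = [(chain[i], chain[i + 1], "activation") for i in range(len(chain) - 1)]
        pathway = Pathway("PW", "p", "t", set(chain), edges)
        regs = upstream_regulators({"TF0"}, [pathway], order=10)
        assert regs == {f"P{i}" for i in range(1, 11)}

    def test_depth_one(self):
        pathway = Pathway("PW", "p", "t", {"X", "K0", "TF0"},
                          [("X", "K0", "activation"), ("K0", "TF0", "activation")])
        assert upstream_regulators({"TF0"}, [pathway], order=1) == {"K0"}

    def test_tf_absent_from_topology(self):
        pathway = Pathway("PW", "p", "t", {"A", "B"}, [("A", "B", "activation")])
        assert upstream_regulators({"TF0"}, [pathway], order=10) == set()

    def test_order_zero_rejected(self):
        with pytest.raises(ValidationError):
            upstream_regulators({"TF0"}, [], order=0)

    def test_unbounded_order_matches_transitive_closure(self):
        # oracle: boolean matrix powers give full ancestor sets
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            names = [f"N{i}" for i in range(n)]
            adj = rng.random((n, n)) < 0.3
            np.fill_diagonal(adj, False)
            edges = [(names[i], names[j], "activation")
                     for i in range(n) for j in range(n) if adj[i, j]]
            pathway = Pathway("PW", "p", "t", set(names), edges)
            reach = adj.copy()
            for _ in range(n):
                reach = reach | (reach @ adj)
            tf = names[0]
            expected = {names[i] for i in range(n) if reach[i, 0]} - {tf}
            assert upstream_regulators({tf}, [pathway], order=n + 5) == expected


class TestUpstream:
    def make_kb(self):
        pathway = Pathway("PW1", "p", "t", {"K0", "TF0", "X"},
                          [("X", "K0", "activation"), ("K0", "TF0", "activation")])
        return _kb([pathway], {"TF0": {"G1"}, "TF9": {"G9"}})

    def test_hand_enumeration(self):
        result = run_upstream(_series(["G1"], {"G1"}, "transcript"), self.make_kb(), 1.0)
        assert result.tfs == {"TF0"}
        assert result.pathway_hits == {"PW1"}
        assert result.regulators == {"K0", "X"}

    def test_min_tfs_threshold(self):
        result = run_upstream(
            _series(["G1"], {"G1"}, "transcript"), self.make_kb(), 1.0, min_tfs=2
        )
        assert result.tfs == {"TF0"}
        assert not result.pathway_hits and not result.regulators

    def test_no_significant_transcripts(self):
        result = run_upstream(_series(["G1"], set(), "transcript"), self.make_kb(), 1.0)
        assert not (result.transcripts | result.tfs | result.pathway_hits
                    | result.regulators)


class TestAgainstBruteForceOracle:
    """Randomized small knowledge bases vs. plain set comprehensions."""

    def random_kb(self, rng):
        genes = [f"G{i}" for i in range(20)]
        tfs = [f"TF{i}" for i in range(4)]
        pool = genes + tfs
        pathways = []
        for p in range(int(rng.integers(2, 10))):
            members = set(rng.choice(pool, size=int(rng.integers(2, 8)), replace=False))
            ordered = sorted(members)
            edges = [(a, b, "activation") for a, b in zip(ordered, ordered[1:])
                     if rng.random() < 0.7]
            pathways.append(Pathway(f"PW{p}", "p", "t", members, edges))
        tf_map = {
            tf: set(rng.choice(genes, size=int(rng.integers(1, 5)), replace=False))
            for tf in tfs
        }
        return _kb(pathways, tf_map), pool

    def test_downstream_and_upstream_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            kb, pool = self.random_kb(rng)
            sig = set(rng.choice(pool, size=int(rng.integers(0, 6)), replace=False))
            series = _series(sorted(pool), sig)

            down = run_downstream(series, kb, 1.0)
            hits = {p.pathway_id for p in kb.pathways if p.genes & sig}
            tfs = {g for pid in hits for g in kb.pathway(pid).genes if g in kb.tf_targets}
            targets = {t for tf in tfs for t in kb.tf_targets[tf]}
            assert (down.pathway_hits, down.tfs, down.target_genes) == (hits, tfs, targets)

            tseries = _series(sorted(pool), sig, "transcript")
            up = run_upstream(tseries, kb, 1.0, min_tfs=1, order=3)
            up_tfs = {tf for tf, tg in kb.tf_targets.items() if tg & sig}
            up_hits = {p.pathway_id for p in kb.pathways if len(p.genes & up_tfs) >= 1}
            regulators = set()
            for pid in up_hits:
                pathway = kb.pathway(pid)
                for tf in up_tfs & pathway.genes:
                    frontier, seen = {tf}, {tf}
                    for _depth in range(3):
                        frontier = {
                            s for s, t, _e in pathway.topology if t in frontier
                        } - seen
                        seen |= frontier
                    regulators |= seen - {tf}
            regulators -= up_tfs
            assert (up.tfs, up.pathway_hits, up.regulators) == (up_tfs, up_hits, regulators)

    def test_monotone_in_significant_set(self):
        rng = np.random.default_rng(9)
        kb, pool = self.random_kb(rng)
        small = set(rng.choice(pool, size=2, replace=False))
        large = small | set(rng.choice(pool, size=4, replace=False))
        d_small = run_downstream(_series(sorted(pool), small), kb, 1.0)
        d_large = run_downstream(_series(sorted(pool), large), kb, 1.0)
        assert d_small.pathway_hits <= d_large.pathway_hits
        assert d_small.tfs <= d_large.tfs
        assert d_small.target_genes <= d_large.target_genes
        u_small = run_upstream(_series(sorted(pool), small, "transcript"), kb, 1.0)
        u_large = run_upstream(_series(sorted(pool), large, "transcript"), kb, 1.0)
        assert u_small.tfs <= u_large.tfs
        assert u_small.pathway_hits <= u_large.pathway_hits
        # regulators grow too, except for molecules promoted to seed TFs
        assert u_small.regulators - u_large.tfs <= u_large.regulators
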