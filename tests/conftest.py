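import numpy as np
import pytest

import pwconsensus as pw
from pwconsensus.knowledge_base import KnowledgeBase, Pathway, PPINetwork, TFTargetMap

import networkx as nx


@pytest.fixture(scope="session")
def noiseless_spec():
    return pw.FixtureSpec(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_spec):
    kb = pw.make_knowledge_base(noiseless_spec)
    phospho, transcripts, proteome = pw.make_coupled_timecourses(kb, noiseless_spec)
    return kb, phospho, transcripts, proteome


@pytest.fixture()
def tiny_kb():
    """Hand-built knowledge base: one cascade pathway plus a decoy TF."""
    pw1 = Pathway(
        "PW1", "cascade", "test", {"X", "K0", "TF0"},
        [("X", "K0", "activation"), ("K0", "TF0", "activation")],
    )
    tf_targets = TFTargetMap({"TF0": {"G1", "G2"}, "TF9": {"G3"}})
    graph = nx.Graph()
    graph.add_edge("X", "K0", score=0.9)
    graph.add_edge("K0", "TF0", score=0.9)
    ppi = PPINetwork(graph)
    return KnowledgeBase([pw1], tf_targets, ppi)


def make_series(layer, molecules, timepoints, logfc, significant=None):
    return pw.OmicsTimeSeries(
        layer, list(molecules), np.asarray(timepoints, dtype=float),
        np.asarray(logfc, dtype=float), significant,
    )


@pytest.fixture()
def series_factory():
    return make_series
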