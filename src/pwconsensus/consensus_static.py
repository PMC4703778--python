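"""Static consensus networks: layer intersection, Steiner trees, profiles.

At each timepoint the downstream and upstream analyses are intersected per
cellular layer, yielding consensus proteins (P), consensus TFs (TF) and
consensus genes/transcripts (T).  Consensus proteins and TFs are mapped onto
the PPI network and connected with a shortest-paths Steiner-tree
2-approximation (metric closure -> MST -> path expansion -> MST -> leaf
pruning).  The graphs are completed with TF-target edges between consensus
TFs and consensus genes, and with feedback edges from a consensus gene to the
consensus protein of the same symbol.  Presence of molecules across the
per-timepoint graphs is summarized in a static consensus profile matrix.

Determinism: shortest-path ties are broken by the lexicographically smallest
node sequence and spanning-tree ties by sorted edge key, so identical inputs
always give identical graphs.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .knowledge_base import KnowledgeBase, PPINetwork
from .layer_analysis import DownstreamResult, UpstreamResult
from .omics_io import OmicsTimeSeries

logger = logging.getLogger(__name__)

Node = Tuple[str, str]  # (symbol, layer); layers: protein, tf, gene, steiner
Edge = Tuple[Node, Node, str]  # kinds: ppi_steiner, tf_target, feedback


@dataclass
class ConsensusSet:
    """Per-layer intersection of downstream and upstream results at one time."""

    timepoint: float
    proteins: Set[str]
    tfs: Set[str]
    genes: Set[str]


def intersect_layers(
    down: DownstreamResult, up: UpstreamResult, phospho: OmicsTimeSeries
) -> ConsensusSet:
    """Consensus molecules per layer (Fig. 3's "=" step).

    proteins: significant phosphoproteins that are also candidate upstream
    regulators; tfs: TFs found by both analyses; genes: downstream target
    genes that are also significant transcripts.
    """
    if down.timepoint != up.timepoint:
        raise ValidationError(
            f"timepoint mismatch: downstream {down.timepoint} vs upstream {up.timepoint}"
        )
    significant = phospho.significant_at(down.timepoint)
    return ConsensusSet(
        timepoint=down.timepoint,
        proteins=significant & up.regulators,
        tfs=down.tfs & up.tfs,
        genes=down.target_genes & up.transcripts,
    )


# ---------------------------------------------------------------------------
# Steiner tree approximation
# ---------------------------------------------------------------------------

def _lex_dijkstra(
    graph: nx.Graph, source: str, weight_of
) -> Dict[str, Tuple[float, Tuple[str, ...]]]:
    """Single-source shortest paths; equal-cost ties resolved to the
    lexicographically smallest node sequence."""
    best: Dict[str, Tuple[float, Tuple[str, ...]]] = {}
    heap: List[Tuple[float, Tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (dist, path)
        for neighbor in graph[node]:
            if neighbor in best:
                continue
            heapq.heappush(heap, (dist + weight_of(node, neighbor), path + (neighbor,)))
    return best


def _kruskal_mst(nodes: Iterable[str], edges: List[Tuple[float, str, str]]) -> List[Tuple[str, str]]:
    """Minimum spanning tree/forest; ties broken by sorted (weight, u, v) key."""
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    for w, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
    return chosen


def steiner_tree(
    ppi: PPINetwork, terminals: Iterable[str], weighted: bool = True
) -> Tuple[nx.Graph, Set[str]]:
    """Shortest-paths 2-approximation of the Steiner tree over the terminals.

    Edge weight is ``1 - score`` (higher-confidence interactions are shorter)
    or 1 for every edge when ``weighted=False``.  Terminals missing from the
    PPI are dropped with a warning; terminals in different PPI components
    yield a forest with one tree per component group.

    Returns the tree/forest (with ``weight`` edge attributes) and the set of
    Steiner nodes (non-terminal connectors).
    """
    graph = ppi.graph
    terminals = sorted(set(terminals))
    present = [t for t in terminals if t in graph]
    missing = sorted(set(terminals) - set(present))
    if missing:
        logger.warning("steiner: %d terminal(s) not in PPI, dropped: %s",
                       len(missing), ", ".join(missing))
    result = nx.Graph()
    if not present:
        logger.warning("steiner: no terminal maps to the PPI; returning empty graph")
        return result, set()

    if weighted:
        def weight_of(u: str, v: str) -> float:
            return 1.0 - graph[u][v]["score"]
    else:
        def weight_of(u: str, v: str) -> float:
            return 1.0

    # Group terminals by connected component (one tree per group).
    component_of: Dict[str, int] = {}
    for idx, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            component_of[node] = idx
    groups: Dict[int, List[str]] = {}
    for t in present:
        groups.setdefault(component_of[t], []).append(t)

    steiner_nodes: Set[str] = set()
    for group in (groups[k] for k in sorted(groups)):
        if len(group) == 1:
            result.add_node(group[0])
            continue
        # (1) metric closure between the group's terminals
        sp = {t: _lex_dijkstra(graph, t, weight_of) for t in group}
        closure_edges = [
            (sp[u][v][0], u, v) for i, u in enumerate(group) for v in group[i + 1:]
        ]
        # (2) MST of the closure, (3) expand closure edges into PPI paths
        expanded = nx.Graph()
        for u, v in _kruskal_mst(group, closure_edges):
            path = sp[min(u, v)][max(u, v)][1]
            for a, b in zip(path, path[1:]):
                expanded.add_edge(a, b, weight=weight_of(a, b))
        # (4) MST of the expanded subgraph
        mst_edges = _kruskal_mst(
            expanded.nodes,
            [(d["weight"], *sorted((a, b))) for a, b, d in expanded.edges(data=True)],
        )
        tree = nx.Graph()
        tree.add_nodes_from(group)
        for a, b in mst_edges:
            tree.add_edge(a, b, weight=expanded[a][b]["weight"])
        # (5) iteratively prune non-terminal leaves
        terminal_set = set(group)
        while True:
            leaves = [n for n in tree if tree.degree(n) <= 1 and n not in terminal_set]
            if not leaves:
                break
            tree.remove_nodes_from(leaves)
        steiner_nodes |= set(tree.nodes) - terminal_set
        result = nx.compose(result, tree)
    return result, steiner_nodes


# ---------------------------------------------------------------------------
# Consensus graph construction
# ---------------------------------------------------------------------------

@dataclass
class ConsensusGraph:
    """Typed per-timepoint network over consensus molecules.

    Node layers: ``protein``, ``tf``, ``gene``, ``steiner``.  Edge kinds:
    undirected ``ppi_steiner`` (stored with sorted endpoints), directed
    ``tf_target`` (tf -> gene) and directed ``feedback`` (gene -> protein of
    the same symbol).
    """

    timepoint: float
    nodes: List[Node]
    edges: List[Edge]
    steiner_nodes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for source, target, kind in self.edges:
            if source not in node_set or target not in node_set:
                raise ValidationError(f"edge {source}->{target} references unknown node")
            if kind == "tf_target" and (source[1] != "tf" or target[1] != "gene"):
                raise ValidationError(f"tf_target edge with wrong layers: {source}->{target}")
            if kind == "feedback" and (
                source[1] != "gene" or target[1] != "protein" or source[0] != target[0]
            ):
                raise ValidationError(f"malformed feedback edge: {source}->{target}")

    def symbols(self) -> Set[Node]:
        return set(self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(timepoint=self.timepoint)
        for symbol, layer in self.nodes:
            g.add_node(f"{layer}:{symbol}", symbol=symbol, layer=layer)
        for (s_sym, s_layer), (t_sym, t_layer), kind in self.edges:
            g.add_edge(f"{s_layer}:{s_sym}", f"{t_layer}:{t_sym}", kind=kind)
        return g


def build_consensus_graph(
    cs: ConsensusSet, kb: KnowledgeBase, weighted: bool = True
) -> ConsensusGraph:
    """Connect consensus proteins/TFs in the PPI, then complete the graph.

    Consensus proteins and TFs are the Steiner terminals.  A PPI node is
    labeled ``tf`` when the symbol is a consensus TF, ``protein`` when it is a
    consensus protein only, and ``steiner`` otherwise.  TF-target edges are
    added between consensus TFs and consensus genes listed in the TF-target
    table; feedback edges gene->protein are added whenever both nodes of one
    symbol ended up in the graph.
    """
    terminals = sorted(cs.proteins | cs.tfs)
    tree, steiner_syms = steiner_tree(kb.ppi, terminals, weighted=weighted)

    def ppi_layer(symbol: str) -> str:
        if symbol in cs.tfs:
            return "tf"
        if symbol in cs.proteins:
            return "protein"
        return "steiner"

    nodes: Set[Node] = {(s, ppi_layer(s)) for s in tree.nodes}
    edges: Set[Edge] = set()
    for a, b in tree.edges:
        u, v = sorted((a, b))
        edges.add(((u, ppi_layer(u)), (v, ppi_layer(v)), "ppi_steiner"))
    for tf in sorted(cs.tfs):
        if tf not in kb.tf_targets:
            continue
        for gene in sorted(cs.genes & kb.tf_targets[tf]):
            nodes.add((tf, "tf"))
            nodes.add((gene, "gene"))
            edges.add(((tf, "tf"), (gene, "gene"), "tf_target"))
    for symbol in sorted(cs.genes & cs.proteins):
        if (symbol, "gene") in nodes and (symbol, "protein") in nodes:
            edges.add(((symbol, "gene"), (symbol, "protein"), "feedback"))
    layer_order = {"protein": 0, "tf": 1, "gene": 2, "steiner": 3}
    sorted_nodes = sorted(nodes, key=lambda n: (layer_order[n[1]], n[0]))
    sorted_edges = sorted(edges, key=lambda e: (e[2], e[0], e[1]))
    return ConsensusGraph(cs.timepoint, sorted_nodes, sorted_edges, steiner_syms)


def consensus_profiles(graphs: Sequence[ConsensusGraph]) -> pd.DataFrame:
    """Boolean presence matrix of (symbol, layer) nodes across timepoints.

    Rows are sorted by layer then symbol; columns are the graphs' timepoints.
    Steiner nodes appear as layer ``steiner`` rows.
    """
    timepoints = [g.timepoint for g in graphs]
    if len(set(timepoints)) != len(timepoints):
        raise ValidationError("duplicate timepoints in consensus graph list")
    layer_order = {"protein": 0, "tf": 1, "gene": 2, "steiner": 3}
    all_nodes = sorted(
        {n for g in graphs for n in g.nodes}, key=lambda n: (layer_order[n[1]], n[0])
    )
    columns = sorted(timepoints)
    data = [
        [node in g.symbols() for g in sorted(graphs, key=lambda g: g.timepoint)]
        for node in all_nodes
    ]
    index = pd.MultiIndex.from_tuples(all_nodes, names=["symbol", "layer"]) if all_nodes \
        else pd.MultiIndex.from_arrays([[], []], names=["symbol", "layer"])
    return pd.DataFrame(data, index=index, columns=columns, dtype=bool)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_graphml(graph: ConsensusGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def write_sif(graph: ConsensusGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (s_sym, s_layer), (t_sym, t_layer), kind in graph.edges:
            fh.write(f"{s_layer}:{s_sym}\t{kind}\t{t_layer}:{t_sym}\n")


def write_profiles_tsv(profiles: pd.DataFrame, path) -> None:
    out = profiles.astype(int).copy()
    out.columns = [f"{c:g}" for c in out.columns]
    out.to_csv(path, sep="\t")
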