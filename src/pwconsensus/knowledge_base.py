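"""Prior-knowledge resources: pathways, TF targets, and the PPI network.

Three flat-file resources drive the pathway-based integration: pathway gene
sets with optional per-pathway directed topology, a transcription-factor to
target-gene table, and a confidence-scored protein-protein interaction (PPI)
network.  Everything is harmonized into a single uppercase gene-symbol
namespace at load time so that molecules measured on different platforms can
be intersected by symbol.

File formats
------------
* gene sets: GMT (``id<TAB>description<TAB>gene...``)
* topology:  4-column TSV ``pathway_id<TAB>source<TAB>interaction<TAB>target``
* TF targets: 2-column TSV ``tf<TAB>target``
* PPI: 3-column TSV ``node<TAB>node<TAB>score`` (scores either in (0, 1] or
  on the STRING 0-1000 scale, detected automatically)

All readers skip blank lines and ``#`` comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Allowed interaction effects in pathway topologies.
EFFECTS = ("activation", "inhibition", "unknown")

TopologyEdge = Tuple[str, str, str]  # (source, target, effect)


def harmonize_symbol(raw: str, alias_table: Optional[Mapping[str, str]] = None) -> str:
    """Map a raw identifier to the harmonized gene-symbol namespace.

    Harmonization is purely syntactic (strip whitespace, uppercase) unless an
    ``alias_table`` is supplied, in which case aliases are resolved
    case-insensitively after syntactic normalization.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or whitespace-only.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("empty or whitespace-only gene symbol")
    symbol = str(raw).strip().upper()
    if alias_table:
        normalized = {str(k).strip().upper(): v for k, v in alias_table.items()}
        if symbol in normalized:
            symbol = str(normalized[symbol]).strip().upper()
    return symbol


@dataclass
class Pathway:
    """A named gene set with optional directed signaling topology."""

    pathway_id: str
    name: str
    source_db: str
    genes: Set[str]
    topology: List[TopologyEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id!r}: empty gene set")
        seen = set()
        deduped: List[TopologyEdge] = []
        for edge in self.topology:
            if len(edge) != 3:
                raise ValidationError(f"pathway {self.pathway_id!r}: malformed edge {edge!r}")
            source, target, effect = edge
            if effect not in EFFECTS:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: unknown effect {effect!r}; "
                    f"allowed: {', '.join(EFFECTS)}"
                )
            if source not in self.genes or target not in self.genes:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: edge {source}->{target} has an "
                    "endpoint outside the gene set"
                )
            if edge not in seen:
                seen.add(edge)
                deduped.append(edge)
        self.topology = deduped

    def digraph(self) -> nx.DiGraph:
        """Directed topology as a graph with an ``effect`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.genes))
        for source, target, effect in self.topology:
            g.add_edge(source, target, effect=effect)
        return g


class TFTargetMap:
    """Mapping from transcription-factor symbol to its target-gene set."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: Dict[str, Set[str]] = {}
        for tf, targets in mapping.items():
            targets = set(targets)
            if not targets:
                raise ValidationError(f"TF {tf!r} has no targets")
            self._map[tf] = targets

    def __contains__(self, tf: str) -> bool:
        return tf in self._map

    def __getitem__(self, tf: str) -> Set[str]:
        return set(self._map[tf])

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TFTargetMap) and self._map == other._map

    @property
    def tfs(self) -> Set[str]:
        return set(self._map)

    def targets_of(self, tfs: Iterable[str]) -> Set[str]:
        """Union of target sets over the given TFs (unknown TFs ignored)."""
        out: Set[str] = set()
        for tf in tfs:
            out |= self._map.get(tf, set())
        return out

    def items(self):
        return self._map.items()


class PPINetwork:
    """Connected, undirected PPI graph with per-edge confidence in (0, 1]."""

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValidationError("PPI network is empty")
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValidationError(f"PPI self-loop at {u!r}")
            score = data.get("score")
            if score is None or not (0 < score <= 1):
                raise ValidationError(f"PPI edge {u}-{v}: score {score!r} outside (0, 1]")
        if not nx.is_connected(graph):
            raise ValidationError("PPI network is not connected")
        self.graph = graph

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)


@dataclass
class KnowledgeBase:
    """Bundle of the three prior-knowledge resources on one symbol namespace."""

    pathways: List[Pathway]
    tf_targets: TFTargetMap
    ppi: PPINetwork

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate pathway ids in knowledge base")
        self._by_id = {p.pathway_id: p for p in self.pathways}

    def pathway(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> Iterable[Tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_gene_sets(
    path,
    source_db: str = "user",
    alias_table: Optional[Mapping[str, str]] = None,
) -> List[Pathway]:
    """Read pathways from a GMT file (topology left empty).

    Each line must carry at least ``id``, ``description`` and one gene.
    Genes are harmonized and deduplicated; duplicate pathway ids are an error.
    """
    path = Path(path)
    pathways: List[Pathway] = []
    seen_ids: Set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3")
        pathway_id, name = fields[0].strip(), fields[1].strip()
        if pathway_id in seen_ids:
            raise ParseError(f"{path}:{lineno}: duplicate pathway id {pathway_id!r}")
        seen_ids.add(pathway_id)
        genes = {harmonize_symbol(g, alias_table) for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(f"{path}:{lineno}: pathway {pathway_id!r} has no genes")
        pathways.append(Pathway(pathway_id, name, source_db, genes))
    return pathways


def write_gene_sets(pathways: Sequence[Pathway], path) -> None:
    """Write pathways as GMT (inverse of :func:`load_gene_sets`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name] + sorted(p.genes)) + "\n")


def load_topology(
    path,
    pathways: Sequence[Pathway],
    alias_table: Optional[Mapping[str, str]] = None,
) -> List[Pathway]:
    """Attach directed edges from a 4-column TSV to the named pathways.

    Endpoints missing from a pathway's gene set are added to it with a logged
    warning.  Unknown pathway ids and unknown interaction tokens are errors.
    """
    path = Path(path)
    by_id = {p.pathway_id: p for p in pathways}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if fields[:4] == ["pathway_id", "source", "interaction", "target"]:
            continue  # header
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: topology row has {len(fields)} fields, expected 4")
        pathway_id, source, interaction, target = fields[:4]
        if pathway_id not in by_id:
            raise ParseError(f"{path}:{lineno}: unknown pathway id {pathway_id!r}")
        if interaction not in EFFECTS:
            raise ParseError(
                f"{path}:{lineno}: unknown interaction {interaction!r}; "
                f"allowed: {', '.join(EFFECTS)}"
            )
        pw = by_id[pathway_id]
        source = harmonize_symbol(source, alias_table)
        target = harmonize_symbol(target, alias_table)
        for endpoint in (source, target):
            if endpoint not in pw.genes:
                logger.warning(
                    "topology endpoint %s not in gene set of pathway %s; adding it",
                    endpoint, pathway_id,
                )
                pw.genes.add(endpoint)
        edge = (source, target, interaction)
        if edge not in pw.topology:
            pw.topology.append(edge)
    return list(pathways)


def write_topology(pathways: Sequence[Pathway], path) -> None:
    """Write all pathway topologies as one 4-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tsource\tinteraction\ttarget\n")
        for p in pathways:
            for source, target, effect in sorted(p.topology):
                fh.write(f"{p.pathway_id}\t{source}\t{effect}\t{target}\n")


def load_tf_targets(path, alias_table: Optional[Mapping[str, str]] = None) -> TFTargetMap:
    """Read a 2-column ``tf<TAB>target`` TSV into a :class:`TFTargetMap`."""
    path = Path(path)
    mapping: Dict[str, Set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: TF-target row has {len(fields)} fields, expected 2")
        tf = harmonize_symbol(fields[0], alias_table)
        target = harmonize_symbol(fields[1], alias_table)
        mapping.setdefault(tf, set()).add(target)
    if not mapping:
        raise ParseError(f"{path}: TF-target table is empty")
    return TFTargetMap(mapping)


def write_tf_targets(tf_targets: TFTargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, targets in sorted(tf_targets.items()):
            for target in sorted(targets):
                fh.write(f"{tf}\t{target}\n")


def load_ppi(
    path,
    min_score: float = 0.4,
    alias_table: Optional[Mapping[str, str]] = None,
) -> PPINetwork:
    """Read a scored edge list and return its largest connected component.

    Scores on the STRING 0-1000 scale (any score > 1) are divided by 1000.
    Edges below ``min_score`` and self-loops are dropped.  The number of nodes
    outside the largest component is logged.
    """
    path = Path(path)
    raw_edges: List[Tuple[str, str, float]] = []
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: PPI row has {len(fields)} fields, expected 3")
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from exc
        raw_edges.append(
            (harmonize_symbol(fields[0], alias_table), harmonize_symbol(fields[1], alias_table), score)
        )
    if any(score > 1 for _, _, score in raw_edges):
        raw_edges = [(u, v, score / 1000.0) for u, v, score in raw_edges]
    graph = nx.Graph()
    for u, v, score in raw_edges:
        if u == v or score < min_score:
            continue
        graph.add_edge(u, v, score=score)
    if graph.number_of_nodes() == 0:
        raise ValidationError(f"{path}: PPI graph empty after filtering at min_score={min_score}")
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    largest = components[0]
    dropped = graph.number_of_nodes() - len(largest)
    if dropped:
        logger.info("PPI: dropped %d node(s) outside the largest connected component", dropped)
    return PPINetwork(graph.subgraph(largest).copy())


def write_ppi(ppi: PPINetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{u}\t{v}\t{ppi.graph[u][v]['score']:.6g}\n")
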