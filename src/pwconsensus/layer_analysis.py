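"""Per-timepoint downstream and upstream layer analyses.

The downstream analysis starts from significant phosphoproteins and walks
down the regulatory hierarchy: pathways containing them, transcription
factors (TFs) inside those pathways, and the TFs' target genes.  The
upstream analysis starts from significant transcripts and walks up: TFs with
a significant target, pathways containing those TFs, and candidate protein
regulators reached by traversing pathway topology edges against their
direction (default 10 orders of neighbors).

TF identity is defined by membership among the keys of the TF-target table.
Traversal is per pathway with results unioned; edge signs are ignored for
reachability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

from .errors import ValidationError
from .knowledge_base import KnowledgeBase, Pathway
from .omics_io import OmicsTimeSeries


@dataclass
class DownstreamResult:
    """Phosphoprotein-anchored downstream mapping at one timepoint."""

    timepoint: float
    phosphoproteins: Set[str]
    pathway_hits: Set[str]
    tfs: Set[str]
    target_genes: Set[str]


@dataclass
class UpstreamResult:
    """Transcript-anchored upstream mapping at one timepoint."""

    timepoint: float
    transcripts: Set[str]
    tfs: Set[str]
    pathway_hits: Set[str]
    regulators: Set[str]


def run_downstream(
    phospho: OmicsTimeSeries, kb: KnowledgeBase, timepoint: float
) -> DownstreamResult:
    """Map significant phosphoproteins to pathways, TFs and target genes."""
    significant = phospho.significant_at(timepoint)
    pathway_hits = {p.pathway_id for p in kb.pathways if p.genes & significant}
    tfs: Set[str] = set()
    for pid in pathway_hits:
        tfs |= kb.pathway(pid).genes & kb.tf_targets.tfs
    target_genes = kb.tf_targets.targets_of(tfs)
    return DownstreamResult(timepoint, significant, pathway_hits, tfs, target_genes)


def upstream_regulators(
    tfs: Iterable[str], pathways: Sequence[Pathway], order: int = 10
) -> Set[str]:
    """Proteins within ``order`` steps upstream of the TFs in pathway topology.

    Per pathway, a breadth-first traversal against edge direction starts at
    every given TF that is a member of that pathway; results are unioned over
    pathways and the seed TFs themselves are excluded.
    """
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    tfs = set(tfs)
    regulators: Set[str] = set()
    for pathway in pathways:
        parents: Dict[str, Set[str]] = {}
        for source, target, _effect in pathway.topology:
            parents.setdefault(target, set()).add(source)
        for tf in tfs & pathway.genes:
            frontier = {tf}
            seen = {tf}
            for _ in range(order):
                frontier = {p for node in frontier for p in parents.get(node, ())} - seen
                if not frontier:
                    break
                seen |= frontier
                regulators |= frontier
    return regulators - tfs


def run_upstream(
    transcripts_series: OmicsTimeSeries,
    kb: KnowledgeBase,
    timepoint: float,
    min_tfs: int = 1,
    order: int = 10,
) -> UpstreamResult:
    """Map significant transcripts to TFs, pathways and upstream regulators."""
    if min_tfs < 1:
        raise ValidationError(f"min_tfs must be >= 1, got {min_tfs}")
    transcripts = transcripts_series.significant_at(timepoint)
    tfs = {tf for tf, targets in kb.tf_targets.items() if targets & transcripts}
    hit_pathways = [p for p in kb.pathways if len(p.genes & tfs) >= min_tfs]
    regulators = upstream_regulators(tfs, hit_pathways, order) if hit_pathways else set()
    return UpstreamResult(
        timepoint, transcripts, tfs, {p.pathway_id for p in hit_pathways}, regulators
    )


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

_DOWN_ROLES = (
    ("phosphoprotein", "phosphoproteins"),
    ("tf", "tfs"),
    ("target_gene", "target_genes"),
)
_UP_ROLES = (
    ("transcript", "transcripts"),
    ("tf", "tfs"),
    ("regulator", "regulators"),
)


def _result_rows(result, roles, kb: KnowledgeBase) -> List[Dict[str, str]]:
    rows = []
    by_symbol_pw = {
        pid: kb.pathway(pid).genes for pid in sorted(result.pathway_hits)
    }
    for role, attr in roles:
        for symbol in sorted(getattr(result, attr)):
            pids = sorted(pid for pid, genes in by_symbol_pw.items() if symbol in genes)
            rows.append(
                {
                    "timepoint": f"{result.timepoint:g}",
                    "role": role,
                    "symbol": symbol,
                    "pathway_ids": ";".join(pids),
                }
            )
    return rows


def export_result_tsv(result, kb: KnowledgeBase, path) -> None:
    """One row per molecule: timepoint, layer role, symbol, pathway ids."""
    roles = _DOWN_ROLES if isinstance(result, DownstreamResult) else _UP_ROLES
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("timepoint\trole\tsymbol\tpathway_ids\n")
        for row in _result_rows(result, roles, kb):
            fh.write("\t".join(row.values()) + "\n")


def export_result_json(result, path) -> None:
    payload = {
        key: sorted(value) if isinstance(value, set) else value
        for key, value in vars(result).items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
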