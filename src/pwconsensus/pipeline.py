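"""Pipeline orchestration: config, stage execution, artifact manifest.

The pipeline wires the stages end to end: per-timepoint downstream/upstream
analyses -> consensus sets and static consensus graphs -> spline-densified
dynamic network inference -> fuzzy time-profile clustering ->
phosphoprotein-anchored time-course integration.  Every artifact is written
under the configured output directory together with a JSON manifest (input
hashes, parameters, artifact list); identical configs and seeds give
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .clustering_integration import (
    fuzzy_cmeans, integrate_time_courses, select_cluster_count,
    write_centroids_tsv, write_clustering_json, write_integration_tsv,
    write_membership_tsv,
)
from .consensus_dynamic import (
    densify, infer_network, write_dense_tsv, write_network_sif,
)
from .consensus_static import (
    ConsensusGraph, ConsensusSet, build_consensus_graph, consensus_profiles,
    intersect_layers, write_graphml, write_profiles_tsv, write_sif,
)
from .errors import PwConsensusError, ValidationError
from .knowledge_base import (
    KnowledgeBase, load_gene_sets, load_ppi, load_tf_targets, load_topology,
)
from .layer_analysis import (
    DownstreamResult, UpstreamResult, export_result_json, export_result_tsv,
    run_downstream, run_upstream,
)
from .omics_io import (
    OmicsTimeSeries, call_significant_fc, ensure_significance, load_omics_table,
)
from .synthetic_fixtures import standardize_rows

logger = logging.getLogger(__name__)

_REQUIRED_INPUTS = ("gene_sets", "tf_targets", "ppi", "phospho", "transcripts", "proteome")
_OPTIONAL_INPUTS = ("topology",)


class StageError(PwConsensusError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline inputs and parameters.

    Defaults follow the analysis conventions: at least one TF per pathway
    (``min_tfs=1``), 10 orders of upstream neighbors, 1.5-fold significance,
    chance-edge probability 0.15, 4 co-regulation clusters.
    """

    inputs: Dict[str, str]
    output_dir: str = "pwconsensus_out"
    min_tfs: int = 1
    order: int = 10
    fold_threshold: float = 1.5
    min_score: float = 0.4
    n_grid: int = 50
    hidden_dim: Optional[int] = None  # None = auto (Hankel rule)
    max_hidden_dim: int = 5
    alpha: float = 0.15
    n_clusters: Optional[int] = 4  # None = auto (centroid-distance rule)
    fuzzifier: float = 2.0
    seed: int = 0
    weighted_steiner: bool = True
    phospho_scale: str = "log2fc"
    transcript_scale: str = "log2fc"
    proteome_scale: str = "log2fc"

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - set(_REQUIRED_INPUTS) - set(_OPTIONAL_INPUTS)
        if unknown:
            raise ValidationError(f"unknown input keys: {', '.join(sorted(unknown))}")
        missing = [k for k in _REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise ValidationError(f"missing required inputs: {', '.join(missing)}")
        if self.min_tfs < 1:
            raise ValidationError("min_tfs must be >= 1")
        if self.order < 1:
            raise ValidationError("order must be >= 1")
        if not self.fold_threshold > 1:
            raise ValidationError("fold_threshold must be > 1")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if not self.fuzzifier > 1:
            raise ValidationError("fuzzifier must be > 1")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1 or null for auto")
        if self.hidden_dim is not None and self.hidden_dim < 0:
            raise ValidationError("hidden_dim must be >= 0 or null for auto")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "inputs"}
        params = dict(raw.get("parameters", {}))
        unknown = set(params) - known
        if unknown:
            raise ValidationError(f"{path}: unknown parameter keys: {', '.join(sorted(unknown))}")
        for key in ("hidden_dim", "n_clusters"):
            if params.get(key) == "auto":
                params[key] = None
        inputs = {
            k: str((path.parent / v).resolve()) for k, v in dict(raw.get("inputs", {})).items()
        }
        output_dir = raw.get("output_dir", "pwconsensus_out")
        if not Path(output_dir).is_absolute():
            output_dir = str((path.parent / output_dir).resolve())
        extra = set(raw) - {"inputs", "parameters", "output_dir"}
        if extra:
            raise ValidationError(f"{path}: unknown config sections: {', '.join(sorted(extra))}")
        return cls(inputs=inputs, output_dir=output_dir, **params)


# ---------------------------------------------------------------------------
# Stage computations (pure; writers separate so subcommands compose)
# ---------------------------------------------------------------------------

@dataclass
class LoadedData:
    kb: KnowledgeBase
    phospho: OmicsTimeSeries
    transcripts: OmicsTimeSeries
    proteome: OmicsTimeSeries

    @property
    def analysis_timepoints(self) -> List[float]:
        return [t for t in self.phospho.timepoints if t > 0]


def load_inputs(config: PipelineConfig) -> LoadedData:
    """Load and harmonize all inputs; apply significance conventions and
    restrict all layers to their common time grid."""
    inp = config.inputs
    pathways = load_gene_sets(inp["gene_sets"])
    if "topology" in inp:
        pathways = load_topology(inp["topology"], pathways)
    kb = KnowledgeBase(
        pathways,
        load_tf_targets(inp["tf_targets"]),
        load_ppi(inp["ppi"], min_score=config.min_score),
    )
    phospho = load_omics_table(inp["phospho"], "phosphoprotein", config.phospho_scale)
    transcripts = load_omics_table(inp["transcripts"], "transcript", config.transcript_scale)
    proteome = load_omics_table(inp["proteome"], "protein", config.proteome_scale)
    phospho = call_significant_fc(phospho, config.fold_threshold)
    proteome = call_significant_fc(proteome, config.fold_threshold)
    transcripts = ensure_significance(transcripts, config.fold_threshold)

    common = sorted(
        set(phospho.timepoints) & set(transcripts.timepoints) & set(proteome.timepoints)
    )
    if len(common) < 2:
        raise ValidationError("layers share no timepoints beyond the baseline")

    def restrict(series: OmicsTimeSeries) -> OmicsTimeSeries:
        cols = [series.timepoint_index(t) for t in common]
        return OmicsTimeSeries(
            series.layer, list(series.molecules), np.array(common),
            series.logfc[:, cols], series.significant[:, cols],
        )

    return LoadedData(kb, restrict(phospho), restrict(transcripts), restrict(proteome))


def compute_layers(
    config: PipelineConfig, data: LoadedData
) -> Dict[float, Tuple[DownstreamResult, UpstreamResult]]:
    out = {}
    for t in data.analysis_timepoints:
        down = run_downstream(data.phospho, data.kb, t)
        up = run_upstream(data.transcripts, data.kb, t, config.min_tfs, config.order)
        logger.info(
            "t=%g h: %d phosphoproteins, %d pathways down / %d up, %d regulators",
            t, len(down.phosphoproteins), len(down.pathway_hits),
            len(up.pathway_hits), len(up.regulators),
        )
        out[t] = (down, up)
    return out


def compute_consensus(
    config: PipelineConfig,
    data: LoadedData,
    layers: Dict[float, Tuple[DownstreamResult, UpstreamResult]],
) -> Dict[float, Tuple[ConsensusSet, ConsensusGraph]]:
    out = {}
    for t, (down, up) in layers.items():
        cs = intersect_layers(down, up, data.phospho)
        graph = build_consensus_graph(cs, data.kb, weighted=config.weighted_steiner)
        logger.info(
            "t=%g h consensus: %d proteins, %d TFs, %d genes, %d steiner nodes",
            t, len(cs.proteins), len(cs.tfs), len(cs.genes), len(graph.steiner_nodes),
        )
        out[t] = (cs, graph)
    return out


def dynamic_molecules(
    data: LoadedData, consensus: Dict[float, Tuple[ConsensusSet, ConsensusGraph]]
) -> Tuple[List[Tuple[str, str]], np.ndarray]:
    """Consensus proteins and genes (any timepoint) with their measured series.

    Protein-layer rows come from the phospho series (consensus proteins plus
    consensus TFs that were measured on the phospho layer); gene-layer rows
    from the transcript series.
    """
    proteins: set = set()
    genes: set = set()
    for cs, _graph in consensus.values():
        proteins |= cs.proteins | (cs.tfs & set(data.phospho.molecules))
        genes |= cs.genes
    molecules: List[Tuple[str, str]] = []
    rows: List[np.ndarray] = []
    for symbol in sorted(proteins):
        if symbol in data.phospho.molecules:
            molecules.append((symbol, "protein"))
            rows.append(data.phospho.profile(symbol))
        else:
            logger.warning("consensus protein %s has no phospho series; skipped", symbol)
    for symbol in sorted(genes):
        if symbol in data.transcripts.molecules:
            molecules.append((symbol, "gene"))
            rows.append(data.transcripts.profile(symbol))
        else:
            logger.warning("consensus gene %s has no transcript series; skipped", symbol)
    values = np.vstack(rows) if rows else np.zeros((0, len(data.phospho.timepoints)))
    return molecules, values


# ---------------------------------------------------------------------------
# run_pipeline
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_json(payload, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    only_stage: Optional[str] = None,
    only_timepoint: Optional[float] = None,
) -> Dict:
    """Execute the pipeline and write artifacts plus ``manifest.json``.

    With ``only_stage`` set (one of downstream, upstream, consensus, dynamic,
    cluster, integrate) the prerequisites are recomputed but only that
    stage's artifacts are written, so manually composed stage runs reproduce
    a full ``run`` byte for byte; the manifest is then omitted.
    ``only_timepoint`` restricts per-timepoint artifacts to one timepoint.
    Returns the manifest dictionary.  Any stage failure is re-raised as a
    :class:`StageError` naming the stage.
    """
    valid_stages = (None, "downstream", "upstream", "consensus", "dynamic",
                    "cluster", "integrate")
    if only_stage not in valid_stages:
        raise ValidationError(f"unknown stage {only_stage!r}")

    def active(*stages: str) -> bool:
        return only_stage is None or only_stage in stages

    def keep_timepoint(t: float) -> bool:
        return only_timepoint is None or t == only_timepoint

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []

    def record(path: Path) -> Path:
        artifacts.append(str(path.relative_to(outdir)))
        return path

    def run_stage(name: str, fn):
        try:
            return fn()
        except PwConsensusError as exc:
            raise StageError(name, exc) from exc

    data = run_stage("load", lambda: load_inputs(config))
    layers = run_stage("layer_analysis", lambda: compute_layers(config, data))

    def write_layers():
        for t, (down, up) in layers.items():
            if not keep_timepoint(t):
                continue
            if active("downstream"):
                export_result_tsv(down, data.kb, record(outdir / f"downstream_{t:g}h.tsv"))
                export_result_json(down, record(outdir / f"downstream_{t:g}h.json"))
            if active("upstream"):
                export_result_tsv(up, data.kb, record(outdir / f"upstream_{t:g}h.tsv"))
                export_result_json(up, record(outdir / f"upstream_{t:g}h.json"))
    if active("downstream", "upstream"):
        run_stage("layer_analysis", write_layers)
    if only_stage in ("downstream", "upstream"):
        return {"artifacts": sorted(artifacts)}

    consensus = run_stage("consensus_static", lambda: compute_consensus(config, data, layers))

    def write_consensus():
        for t, (cs, graph) in consensus.items():
            if not keep_timepoint(t):
                continue
            _write_json(
                {
                    "timepoint": t,
                    "proteins": sorted(cs.proteins),
                    "tfs": sorted(cs.tfs),
                    "genes": sorted(cs.genes),
                    "steiner_nodes": sorted(graph.steiner_nodes),
                },
                record(outdir / f"consensus_{t:g}h.json"),
            )
            write_graphml(graph, record(outdir / f"consensus_{t:g}h.graphml"))
            write_sif(graph, record(outdir / f"consensus_{t:g}h.sif"))
        if only_timepoint is None:
            profiles = consensus_profiles([g for _cs, g in consensus.values()])
            write_profiles_tsv(profiles, record(outdir / "consensus_profiles.tsv"))
    if active("consensus"):
        run_stage("consensus_static", write_consensus)
    if only_stage == "consensus":
        return {"artifacts": sorted(artifacts)}

    def run_dynamic():
        molecules, values = dynamic_molecules(data, consensus)
        summary_path = record(outdir / "dynamic_summary.json")
        if len(molecules) < 2:
            logger.warning("dynamic stage skipped: %d consensus molecule(s)", len(molecules))
            _write_json({"skipped": True, "n_molecules": len(molecules)}, summary_path)
            return None
        dense = densify(
            data.phospho.timepoints, values, molecules, n_grid=config.n_grid
        )
        result = infer_network(
            dense, K=config.hidden_dim, alpha=config.alpha, seed=config.seed,
            max_K=config.max_hidden_dim,
        )
        write_dense_tsv(dense, record(outdir / "dense_series.tsv"))
        write_network_sif(result, record(outdir / "dynamic_network.sif"))
        import networkx as nx
        nx.write_graphml(result.to_networkx(), record(outdir / "dynamic_network.graphml"))
        _write_json(
            {
                "skipped": False,
                "n_molecules": len(molecules),
                "K": result.fit.K,
                "iterations": result.fit.iterations,
                "converged": bool(result.fit.converged),
                "alpha": result.alpha,
                "n_edges": len(result.adjacency),
            },
            summary_path,
        )
        return result
    if active("dynamic"):
        run_stage("consensus_dynamic", run_dynamic)
    if only_stage == "dynamic":
        return {"artifacts": sorted(artifacts)}

    def run_cluster():
        molecules, values = dynamic_molecules(data, consensus)
        if len(molecules) < 2:
            logger.warning("clustering skipped: %d consensus molecule(s)", len(molecules))
            _write_json({"skipped": True}, record(outdir / "clustering.json"))
            return None
        X = standardize_rows(values)
        if config.n_clusters is None:
            c = select_cluster_count(
                X, range(2, min(8, len(molecules) - 1) + 1),
                m=config.fuzzifier, seed=config.seed,
            )
        else:
            c = min(config.n_clusters, len(molecules))
        clustering = fuzzy_cmeans(X, c, m=config.fuzzifier, seed=config.seed)
        write_membership_tsv(clustering, molecules, record(outdir / "cluster_membership.tsv"))
        write_centroids_tsv(
            clustering, data.phospho.timepoints, record(outdir / "cluster_centroids.tsv")
        )
        write_clustering_json(clustering, record(outdir / "clustering.json"))
        return clustering
    if active("cluster"):
        run_stage("clustering", run_cluster)
    if only_stage == "cluster":
        return {"artifacts": sorted(artifacts)}

    def run_integration():
        result = integrate_time_courses(
            data.phospho,
            {t: down for t, (down, _up) in layers.items()},
            {t: cs for t, (cs, _g) in consensus.items()},
            data.proteome,
            data.transcripts,
            data.kb,
        )
        write_integration_tsv(result, record(outdir / "integration.tsv"))
        return result
    if active("integrate"):
        run_stage("integration", run_integration)
    if only_stage == "integrate":
        return {"artifacts": sorted(artifacts)}

    manifest = {
        "version": __version__,
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in sorted(config.inputs.items())},
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("inputs", "output_dir")
        },
        "artifacts": sorted(artifacts),
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
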