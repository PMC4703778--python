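"""Synthetic knowledge bases and coupled time courses with planted structure.

The generator emulates the qualitative biology of a growth-factor
stimulation experiment: a phosphorylation cascade (upstream regulator X0 ->
kinase K0 -> transcription factor TF0) drives waves of target-gene
transcription -- immediate targets switch on at 1 h, delayed targets at 8 h
-- and the corresponding proteins follow the transcripts with a fixed lag.
Response curves are piecewise-smooth (logistic rise times exponential
decay), so spline densification is well posed; all other molecules carry
i.i.d. Gaussian noise on the log2 fold-change scale and no planted signal.

Because the planted cascade is the only signal, the noiseless (noise_sd=0)
fixtures have an exactly known answer at every stage: the per-layer
consensus sets equal the planted molecules active at each timepoint
(:func:`planted_truth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .errors import ValidationError
from .knowledge_base import (
    KnowledgeBase, Pathway, PPINetwork, TFTargetMap,
    write_gene_sets, write_ppi, write_tf_targets, write_topology,
)
from .omics_io import OmicsTimeSeries, call_significant_fc, write_omics_table

#: Default measured grid (hours): baseline plus six post-stimulation points.
DEFAULT_TIMEPOINTS = (0.0, 1.0, 4.0, 8.0, 13.0, 18.0, 24.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study (knowledge base + planted cascade)."""

    n_pathways: int = 8
    genes_per_pathway: int = 10
    n_tfs: int = 5
    targets_per_tf: int = 8
    ppi_extra_edge_prob: float = 0.05
    timepoints: Tuple[float, ...] = DEFAULT_TIMEPOINTS
    noise_sd: float = 0.2
    seed: int = 0
    # planted cascade
    kinase: str = "K0"
    tf: str = "TF0"
    upstream: str = "X0"
    immediate_targets: Tuple[str, ...] = ("GI1", "GI2")
    delayed_targets: Tuple[str, ...] = ("GD1", "GD2")
    immediate_onset: float = 1.0
    delayed_onset: float = 8.0
    protein_lag: float = 4.0
    amplitude: float = 1.5  # peak |log2FC| of planted targets
    kinase_amplitude: float = 2.0
    decay_tau: float = 40.0  # hours; slow decay keeps late points significant

    def __post_init__(self) -> None:
        for name in ("n_pathways", "genes_per_pathway", "n_tfs", "targets_per_tf"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0 <= self.ppi_extra_edge_prob <= 1:
            raise ValidationError("ppi_extra_edge_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if 0.0 not in self.timepoints:
            raise ValidationError("timepoints must include the baseline 0")

    @property
    def planted_targets(self) -> Tuple[str, ...]:
        return self.immediate_targets + self.delayed_targets


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------

def _rise(t: np.ndarray, onset: float, width: float = 0.2) -> np.ndarray:
    """Logistic switch centred slightly before the onset hour."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - (onset - 0.5)) / width))


def _response(t: np.ndarray, onset: float, amplitude: float, tau: float) -> np.ndarray:
    """Logistic rise at ``onset`` followed by slow exponential decay."""
    t = np.asarray(t, dtype=float)
    decay = np.exp(-np.maximum(t - onset, 0.0) / tau)
    return amplitude * _rise(t, onset) * decay


def _target_curve(spec: FixtureSpec, symbol: str, t: np.ndarray) -> np.ndarray:
    """Planted transcript curve; the sign alternates within each onset group."""
    if symbol in spec.immediate_targets:
        onset, rank = spec.immediate_onset, spec.immediate_targets.index(symbol)
    else:
        onset, rank = spec.delayed_onset, spec.delayed_targets.index(symbol)
    sign = 1.0 if rank % 2 == 0 else -1.0
    return sign * _response(t, onset, spec.amplitude, spec.decay_tau)


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

def make_knowledge_base(spec: FixtureSpec) -> KnowledgeBase:
    """Pathways, TF targets and a PPI graph containing the planted cascade.

    Pathway ``P0`` holds the cascade with topology ``X0 -> K0 -> TF0``; the
    remaining pathways draw random genes (and one decoy TF each) from pools
    disjoint from the planted symbols.  The PPI always contains the path
    ``X0 - K0 - TF0`` plus random edges at ``ppi_extra_edge_prob``; the
    component containing the planted cascade is retained.
    """
    rng = np.random.default_rng([spec.seed, 0])
    gene_pool = [f"RG{i:03d}" for i in range(spec.n_pathways * spec.genes_per_pathway)]
    transcript_pool = [f"RT{i:03d}" for i in range((spec.n_tfs) * spec.targets_per_tf)]

    planted = Pathway(
        "P0", "planted cascade", "synthetic",
        {spec.upstream, spec.kinase, spec.tf},
        [(spec.upstream, spec.kinase, "activation"), (spec.kinase, spec.tf, "activation")],
    )
    pathways = [planted]
    decoy_tfs = [f"TF{i}" for i in range(1, spec.n_tfs)]
    for p in range(1, spec.n_pathways):
        genes = set(rng.choice(gene_pool, size=spec.genes_per_pathway, replace=False))
        if decoy_tfs:
            genes.add(decoy_tfs[(p - 1) % len(decoy_tfs)])
        ordered = sorted(genes)
        topology = [
            (ordered[i], ordered[i + 1], "activation") for i in range(len(ordered) - 1)
        ]
        pathways.append(Pathway(f"P{p}", f"random pathway {p}", "synthetic", genes, topology))

    mapping: Dict[str, Set[str]] = {spec.tf: set(spec.planted_targets)}
    for tf in decoy_tfs:
        mapping[tf] = set(rng.choice(transcript_pool, size=spec.targets_per_tf, replace=False))

    graph = nx.Graph()
    graph.add_edge(spec.upstream, spec.kinase, score=0.9)
    graph.add_edge(spec.kinase, spec.tf, score=0.9)
    all_symbols = sorted(
        {spec.upstream, spec.kinase, spec.tf}
        | set(gene_pool) | set(transcript_pool) | set(decoy_tfs) | set(spec.planted_targets)
    )
    if spec.ppi_extra_edge_prob > 0:
        for i, u in enumerate(all_symbols):
            draws = rng.random(len(all_symbols) - i - 1)
            scores = rng.uniform(0.4, 0.99, len(draws))
            for offset, (draw, score) in enumerate(zip(draws, scores)):
                v = all_symbols[i + 1 + offset]
                if draw < spec.ppi_extra_edge_prob and not graph.has_edge(u, v):
                    graph.add_edge(u, v, score=float(round(score, 6)))
    component = nx.node_connected_component(graph, spec.kinase)
    ppi = PPINetwork(graph.subgraph(component).copy())
    return KnowledgeBase(pathways, TFTargetMap(mapping), ppi)


# ---------------------------------------------------------------------------
# Coupled time courses
# ---------------------------------------------------------------------------

def make_coupled_timecourses(
    kb: KnowledgeBase, spec: FixtureSpec
) -> Tuple[OmicsTimeSeries, OmicsTimeSeries, OmicsTimeSeries]:
    """Phosphoprotein, transcript and protein layers with the planted signal.

    The kinase's phospho course crosses the 1.5-fold threshold from the first
    post-baseline timepoint on; planted transcripts switch on at their onset
    and planted proteins follow them shifted by ``protein_lag``.  All other
    molecules are Gaussian noise.  Significance flags come from the
    fold-change rule on all layers.
    """
    for symbol in (spec.kinase, spec.tf, spec.upstream):
        if symbol not in kb.ppi and all(symbol not in p.genes for p in kb.pathways):
            raise ValidationError(f"planted molecule {symbol!r} missing from knowledge base")
    rng = np.random.default_rng([spec.seed, 1])
    t = np.asarray(sorted(spec.timepoints), dtype=float)

    def finish(layer: str, molecules: List[str], signal: np.ndarray) -> OmicsTimeSeries:
        noise = rng.normal(0.0, spec.noise_sd, signal.shape) if spec.noise_sd > 0 \
            else np.zeros_like(signal)
        values = signal + noise
        values[:, 0] = 0.0
        series = OmicsTimeSeries(layer, molecules, t, values)
        return call_significant_fc(series)

    gene_pool = sorted(
        {g for p in kb.pathways for g in p.genes if g.startswith("RG")}
    )
    phospho_noise = gene_pool[: 9] if len(gene_pool) >= 9 else gene_pool
    phospho_mols = [spec.kinase] + phospho_noise
    phospho_signal = np.zeros((len(phospho_mols), len(t)))
    phospho_signal[0] = _response(t, spec.immediate_onset, spec.kinase_amplitude, spec.decay_tau)
    phospho = finish("phosphoprotein", phospho_mols, phospho_signal)

    decoy_targets = sorted(kb.tf_targets.targets_of(kb.tf_targets.tfs - {spec.tf}))
    transcript_mols = list(spec.planted_targets) + decoy_targets
    transcript_signal = np.zeros((len(transcript_mols), len(t)))
    for i, symbol in enumerate(spec.planted_targets):
        transcript_signal[i] = _target_curve(spec, symbol, t)
    transcripts = finish("transcript", transcript_mols, transcript_signal)

    protein_mols = list(spec.planted_targets) + decoy_targets
    protein_signal = np.zeros((len(protein_mols), len(t)))
    for i, symbol in enumerate(spec.planted_targets):
        protein_signal[i] = _target_curve(spec, symbol, t - spec.protein_lag)
    proteome = finish("protein", protein_mols, protein_signal)

    return phospho, transcripts, proteome


def planted_truth(spec: FixtureSpec) -> Dict[float, Dict[str, Set[str]]]:
    """Expected per-layer consensus sets at each post-baseline timepoint for
    the noiseless fixture (threshold on the noiseless curves)."""
    cut = np.log2(1.5)
    truth: Dict[float, Dict[str, Set[str]]] = {}
    for t in sorted(spec.timepoints):
        if t == 0:
            continue
        t_arr = np.array([t])
        genes = {
            s for s in spec.planted_targets
            if abs(_target_curve(spec, s, t_arr)[0]) >= cut
        }
        kinase_sig = abs(
            _response(t_arr, spec.immediate_onset, spec.kinase_amplitude, spec.decay_tau)[0]
        ) >= cut
        truth[t] = {
            "proteins": {spec.kinase} if (kinase_sig and genes) else set(),
            "tfs": {spec.tf} if (kinase_sig and genes) else set(),
            "genes": genes if kinase_sig else set(),
        }
    return truth


# ---------------------------------------------------------------------------
# Co-regulation profiles for clustering
# ---------------------------------------------------------------------------

#: Archetype grid and labels: sign x onset.
ARCHETYPES = ("up_immediate", "up_delayed", "down_immediate", "down_delayed")


def make_coregulation_profiles(
    n_per_pattern: int,
    noise_sd: float = 0.2,
    seed: int = 0,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profiles drawn from the four sign-by-onset archetypes plus noise.

    Returns ``(X, labels, grid)`` where ``labels[i]`` indexes
    :data:`ARCHETYPES`.
    """
    if n_per_pattern < 1:
        raise ValidationError("n_per_pattern must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(timepoints), dtype=float)
    templates = np.stack([
        _response(grid, 1.0, 1.5, 40.0),
        _response(grid, 8.0, 1.5, 40.0),
        -_response(grid, 1.0, 1.5, 40.0),
        -_response(grid, 8.0, 1.5, 40.0),
    ])
    rows = []
    labels = []
    for k in range(4):
        block = np.tile(templates[k], (n_per_pattern, 1))
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, block.shape)
        rows.append(block)
        labels.extend([k] * n_per_pattern)
    return np.vstack(rows), np.asarray(labels), grid


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rows (the clustering input convention)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValidationError("cannot standardize a constant profile")
    return (X - X.mean(axis=1, keepdims=True)) / sd


# ---------------------------------------------------------------------------
# Writers: emit the exact flat files the loaders read
# ---------------------------------------------------------------------------

def write_fixture_files(
    kb: KnowledgeBase,
    phospho: OmicsTimeSeries,
    transcripts: OmicsTimeSeries,
    proteome: OmicsTimeSeries,
    outdir,
) -> Dict[str, Path]:
    """Write a complete input set (GMT/TSV) and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_sets": outdir / "pathways.gmt",
        "topology": outdir / "topology.tsv",
        "tf_targets": outdir / "tf_targets.tsv",
        "ppi": outdir / "ppi.tsv",
        "phospho": outdir / "phospho.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "proteome": outdir / "proteome.tsv",
    }
    write_gene_sets(kb.pathways, paths["gene_sets"])
    write_topology(kb.pathways, paths["topology"])
    write_tf_targets(kb.tf_targets, paths["tf_targets"])
    write_ppi(kb.ppi, paths["ppi"])
    write_omics_table(phospho, paths["phospho"])
    write_omics_table(transcripts, paths["transcripts"])
    write_omics_table(proteome, paths["proteome"])
    return paths
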