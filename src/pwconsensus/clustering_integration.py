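"""Fuzzy c-means time-profile clustering and phosphoprotein-anchored
transcript/protein time-course integration.

Clustering groups consensus proteins and transcripts by the shape of their
log2 fold-change time profiles (rows standardized so shape, not magnitude,
drives clusters).  The soft assignment uses the classic fuzzy c-means
updates with fuzzifier ``m`` (default 2); the cluster count can be chosen
with a minimum-centroid-distance rule.

Integration determines, per measured phosphoprotein, its downstream
consensus transcripts and maps them to proteins that are significantly
differentially abundant at any timepoint, attaching both fold-change series
for side-by-side inspection of transcript-to-protein lag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .consensus_static import ConsensusSet
from .errors import ValidationError
from .knowledge_base import KnowledgeBase
from .layer_analysis import DownstreamResult
from .omics_io import OmicsTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class FuzzyClustering:
    """Soft partition of time profiles: memberships, centroids, diagnostics."""

    membership: np.ndarray  # rows x c, rows sum to 1
    centroids: np.ndarray  # c x timepoints
    m: float
    c: int
    objective_trace: List[float]
    seed: int

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.c:
            raise ValidationError("centroid count does not equal c")
        if np.any(np.abs(self.membership.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("membership rows must sum to 1")

    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)


def _fcm_single(X: np.ndarray, c: int, m: float, tol: float, max_iter: int,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=c, replace=False)].copy()
    U = np.full((n, c), 1.0 / c)
    trace: List[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        U_new = np.empty_like(U)
        exponent = 1.0 / (m - 1.0)
        with np.errstate(divide="ignore"):
            inv = d2 ** -exponent
        for i in range(n):
            if zero[i].any():
                U_new[i] = 0.0  # coincides with a centroid: hard-assign
                U_new[i, np.argmax(zero[i])] = 1.0
            else:
                U_new[i] = inv[i] / inv[i].sum()
        um = U_new ** m
        weights = um.sum(axis=0)
        fresh = (um.T @ X)
        # a cluster starved of membership keeps its previous centroid
        alive = weights > 1e-300
        centroids[alive] = fresh[alive] / weights[alive, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    return U, centroids, trace


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    restarts: int = 10,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means with seeded random restarts (best final objective wins).

    ``X`` rows are profiles (standardize them beforehand to cluster by
    shape).  ``c=1`` returns the trivial partition with the column-mean
    centroid.
    """
    X = np.asarray(X, dtype=float)
    if c < 1:
        raise ValidationError(f"c must be >= 1, got {c}")
    if c > X.shape[0]:
        raise ValidationError(f"c={c} exceeds the number of profiles ({X.shape[0]})")
    if not m > 1:
        raise ValidationError(f"fuzzifier m must be > 1, got {m}")
    if c == 1:
        U = np.ones((X.shape[0], 1))
        centroid = X.mean(axis=0, keepdims=True)
        obj = float(((X - centroid) ** 2).sum())
        return FuzzyClustering(U, centroid, m, c, [obj], seed)
    best = None
    for restart in range(restarts):
        rng = np.random.default_rng([seed, restart])
        U, centroids, trace = _fcm_single(X, c, m, tol, max_iter, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (U, centroids, trace)
    return FuzzyClustering(best[0], best[1], m, c, best[2], seed)


def select_cluster_count(
    X: np.ndarray,
    c_range: Sequence[int] = range(2, 9),
    m: float = 2.0,
    seed: int = 0,
    restarts: int = 5,
    collapse_frac: float = 0.5,
) -> int:
    """Choose the cluster count from the minimum-centroid-distance curve.

    For each candidate ``c`` the minimum pairwise centroid distance d_min(c)
    is computed.  While ``c`` is at or below the number of genuinely
    distinct profile shapes the centroids stay well separated; one step
    beyond it two centroids split the same group and d_min collapses.  The
    rule returns the last candidate before the first collapse, a relative
    drop of d_min by more than ``collapse_frac`` from one candidate to the
    next (the largest candidate if no collapse occurs).
    """
    X = np.asarray(X, dtype=float)
    candidates = sorted(set(int(c) for c in c_range))
    if not candidates or candidates[0] < 2 or candidates[-1] > X.shape[0] - 1:
        raise ValidationError(
            f"c_range must lie within [2, {X.shape[0] - 1}], got {candidates!r}"
        )
    dmin: Dict[int, float] = {}
    for c in candidates:
        centroids = fuzzy_cmeans(X, c, m=m, seed=seed, restarts=restarts).centroids
        dists = [
            float(np.linalg.norm(centroids[i] - centroids[j]))
            for i in range(c) for j in range(i + 1, c)
        ]
        dmin[c] = min(dists)
    for c, c_next in zip(candidates, candidates[1:]):
        if dmin[c] <= 0 or (dmin[c] - dmin[c_next]) / dmin[c] > collapse_frac:
            return c
    return candidates[-1]


# ---------------------------------------------------------------------------
# Time-course integration
# ---------------------------------------------------------------------------

@dataclass
class MatchedPair:
    """A downstream consensus transcript matched to a differentially abundant
    protein of the same symbol, with both log2 fold-change series."""

    symbol: str
    transcript_logfc: np.ndarray
    protein_logfc: np.ndarray
    correlation: float


@dataclass
class AnchorIntegration:
    anchor: str  # phosphoprotein symbol
    downstream_transcripts: Set[str]
    matched: List[MatchedPair]
    unmatched: Set[str]


@dataclass
class IntegrationResult:
    timepoints: np.ndarray
    anchors: Dict[str, AnchorIntegration] = field(default_factory=dict)


def integrate_time_courses(
    phospho: OmicsTimeSeries,
    down_results: Mapping[float, DownstreamResult],
    consensus: Mapping[float, ConsensusSet],
    proteome: OmicsTimeSeries,
    transcripts: OmicsTimeSeries,
    kb: KnowledgeBase,
) -> IntegrationResult:
    """Anchor the integration on each measured phosphoprotein.

    Per phosphoprotein p and timepoint t (where p is part of the downstream
    analysis), the pathways containing p give its TFs and their targets;
    intersecting with the consensus genes at t yields the downstream
    consensus transcripts T(p).  Those significant on the proteome layer at
    any timepoint become matched transcript/protein pairs.
    """
    proteome_hits = {
        symbol for symbol in proteome.molecules
        if proteome.significant[proteome.molecule_index(symbol)].any()
    }
    result = IntegrationResult(timepoints=phospho.timepoints.copy())
    for anchor in phospho.molecules:
        downstream: Set[str] = set()
        for t, down in down_results.items():
            if t not in consensus or anchor not in down.phosphoproteins:
                continue
            pathways_p = [
                kb.pathway(pid) for pid in down.pathway_hits
                if anchor in kb.pathway(pid).genes
            ]
            tfs_p: Set[str] = set()
            for pw in pathways_p:
                tfs_p |= pw.genes & kb.tf_targets.tfs
            targets_p = kb.tf_targets.targets_of(tfs_p & down.tfs)
            downstream |= consensus[t].genes & targets_p
        matched_syms = {
            g for g in downstream if g in proteome_hits and g in transcripts.molecules
        }
        matched = []
        for symbol in sorted(matched_syms):
            t_series = transcripts.profile(symbol)
            p_series = proteome.profile(symbol)
            corr = float(np.corrcoef(t_series, p_series)[0, 1]) if (
                t_series.std() > 0 and p_series.std() > 0
            ) else float("nan")
            matched.append(MatchedPair(symbol, t_series, p_series, corr))
        result.anchors[anchor] = AnchorIntegration(
            anchor, downstream, matched, downstream - matched_syms
        )
    return result


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_membership_tsv(clust: FuzzyClustering, row_labels: Sequence, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tlayer\t" + "\t".join(f"cluster_{k+1}" for k in range(clust.c)) + "\n")
        for label, row in zip(row_labels, clust.membership):
            symbol, layer = label if isinstance(label, tuple) else (label, "")
            fh.write(f"{symbol}\t{layer}\t" + "\t".join(f"{u:.6f}" for u in row) + "\n")


def write_centroids_tsv(clust: FuzzyClustering, timepoints: Sequence[float], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\t" + "\t".join(f"{t:g}" for t in timepoints) + "\n")
        for k, row in enumerate(clust.centroids):
            fh.write(f"{k+1}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def write_clustering_json(clust: FuzzyClustering, path) -> None:
    payload = {
        "c": clust.c,
        "m": clust.m,
        "seed": clust.seed,
        "iterations": len(clust.objective_trace),
        "final_objective": clust.objective_trace[-1] if clust.objective_trace else None,
        "cluster_sizes": np.bincount(clust.hard_labels(), minlength=clust.c).tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_integration_tsv(result: IntegrationResult, path) -> None:
    """Long format: anchor, symbol, layer, time, logFC, matched flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("anchor\tsymbol\tlayer\ttime\tlogfc\tmatched\n")
        for anchor in sorted(result.anchors):
            rec = result.anchors[anchor]
            for pair in rec.matched:
                for layer, series in (
                    ("transcript", pair.transcript_logfc),
                    ("protein", pair.protein_logfc),
                ):
                    for t, value in zip(result.timepoints, series):
                        fh.write(
                            f"{anchor}\t{pair.symbol}\t{layer}\t{t:g}\t{value:.12g}\t1\n"
                        )
            for symbol in sorted(rec.unmatched):
                fh.write(f"{anchor}\t{symbol}\ttranscript\t\t\t0\n")
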