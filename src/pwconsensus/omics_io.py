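"""Per-layer omics time courses and significance calling.

A layer (phosphoprotein, protein or transcript) is a molecule-by-timepoint
matrix of log2 fold changes versus the pre-stimulation baseline (time 0 h),
paired with a boolean significance matrix.  Proteome-style layers call
significance with a fold-change threshold (default 1.5-fold, two-sided);
transcript layers normally ship precomputed significance flags from an
upstream differential-expression pipeline and the fold-change rule is only a
fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .knowledge_base import harmonize_symbol

logger = logging.getLogger(__name__)

LAYERS = ("phosphoprotein", "protein", "transcript")


@dataclass
class OmicsTimeSeries:
    """Log2 fold-change time courses of one measurement layer.

    The baseline (0 h) column is identically zero in ``logfc`` and identically
    False in ``significant``: every value is a contrast against it.
    """

    layer: str
    molecules: List[str]
    timepoints: np.ndarray  # hours, strictly increasing, includes 0
    logfc: np.ndarray  # molecules x timepoints
    significant: np.ndarray = field(default=None)  # same shape, bool

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; allowed: {', '.join(LAYERS)}")
        if len(set(self.molecules)) != len(self.molecules):
            dupes = sorted({m for m in self.molecules if self.molecules.count(m) > 1})
            raise ValidationError(f"duplicate molecule symbols: {', '.join(dupes)}")
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.ndim != 1 or np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if self.timepoints[0] != 0:
            raise ValidationError("timepoints must include the baseline 0 h as first entry")
        self.logfc = np.asarray(self.logfc, dtype=float)
        if self.significant is None:
            self.significant = np.zeros_like(self.logfc, dtype=bool)
        self.significant = np.asarray(self.significant, dtype=bool)
        shape = (len(self.molecules), len(self.timepoints))
        if self.logfc.shape != shape or self.significant.shape != shape:
            raise ValidationError(
                f"matrix shape mismatch: expected {shape}, got logfc {self.logfc.shape}, "
                f"significant {self.significant.shape}"
            )
        if not np.all(np.isfinite(self.logfc)):
            raise ValidationError("logfc contains non-finite values")
        if np.any(self.logfc[:, 0] != 0):
            raise ValidationError("baseline logfc column must be all zeros")
        if np.any(self.significant[:, 0]):
            raise ValidationError("baseline significance column must be all False")

    # -- accessors ---------------------------------------------------------

    def timepoint_index(self, timepoint: float) -> int:
        matches = np.nonzero(np.isclose(self.timepoints, timepoint))[0]
        if matches.size == 0:
            raise ValidationError(f"timepoint {timepoint} h not in {self.layer} series")
        return int(matches[0])

    def molecule_index(self, symbol: str) -> int:
        try:
            return self.molecules.index(symbol)
        except ValueError as exc:
            raise ValidationError(f"molecule {symbol!r} not in {self.layer} series") from exc

    def significant_at(self, timepoint: float) -> Set[str]:
        """Symbols flagged significant at the given timepoint."""
        col = self.timepoint_index(timepoint)
        return {self.molecules[i] for i in np.nonzero(self.significant[:, col])[0]}

    def profile(self, symbol: str) -> np.ndarray:
        """Log2 fold-change series of one molecule (copy)."""
        return self.logfc[self.molecule_index(symbol)].copy()

    def copy(self) -> "OmicsTimeSeries":
        return OmicsTimeSeries(
            self.layer, list(self.molecules), self.timepoints.copy(),
            self.logfc.copy(), self.significant.copy(),
        )


def load_omics_table(path, layer: str, scale: str = "log2fc") -> OmicsTimeSeries:
    """Read a layer table: ``symbol`` column, one column per timepoint (hours),
    optional parallel ``sig_<t>`` flag columns.

    ``scale='ratio'`` applies log2 elementwise; a baseline 0 h column is
    inserted (as zeros) if absent.
    """
    if scale not in ("log2fc", "ratio"):
        raise ValidationError(f"unknown scale {scale!r}; allowed: log2fc, ratio")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise ParseError(f"{path}: {exc}") from exc
    if frame.columns[0] != "symbol":
        raise ParseError(f"{path}: first column must be 'symbol', got {frame.columns[0]!r}")
    value_cols = [c for c in frame.columns[1:] if not c.startswith("sig_")]
    sig_cols = [c for c in frame.columns[1:] if c.startswith("sig_")]
    try:
        times = [float(c) for c in value_cols]
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric timepoint column name: {exc}") from exc

    symbols = [harmonize_symbol(s) for s in frame["symbol"]]
    values = np.empty((len(symbols), len(value_cols)))
    for j, col in enumerate(value_cols):
        for i, cell in enumerate(frame[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {symbols[i]!r}, column {col!r}"
                ) from exc
    if scale == "ratio":
        if np.any(values <= 0):
            raise ValidationError(f"{path}: ratios must be positive to take log2")
        values = np.log2(values)

    sig = None
    if sig_cols:
        sig_times = {float(c[len("sig_"):]): c for c in sig_cols}
        sig = np.zeros_like(values, dtype=bool)
        for j, t in enumerate(times):
            if t in sig_times:
                sig[:, j] = frame[sig_times[t]].astype(float).astype(bool).to_numpy()

    order = np.argsort(times)
    times_sorted = [times[k] for k in order]
    values = values[:, order]
    if sig is not None:
        sig = sig[:, order]
    if not times_sorted or times_sorted[0] != 0.0:
        times_sorted = [0.0] + times_sorted
        values = np.hstack([np.zeros((values.shape[0], 1)), values])
        if sig is not None:
            sig = np.hstack([np.zeros((sig.shape[0], 1), dtype=bool), sig])
    return OmicsTimeSeries(layer, symbols, np.array(times_sorted), values, sig)


def write_omics_table(series: OmicsTimeSeries, path, with_flags: bool = True) -> None:
    """Write a layer table in the format :func:`load_omics_table` reads.

    Values are written with 12 significant digits, enough for a bit-stable
    round trip at the stated precision.
    """

    def fmt_time(t: float) -> str:
        return f"{t:g}"

    with open(path, "w", encoding="utf-8") as fh:
        header = ["symbol"] + [fmt_time(t) for t in series.timepoints]
        if with_flags:
            header += [f"sig_{fmt_time(t)}" for t in series.timepoints]
        fh.write("\t".join(header) + "\n")
        for i, symbol in enumerate(series.molecules):
            row = [symbol] + [f"{v:.12g}" for v in series.logfc[i]]
            if with_flags:
                row += [str(int(f)) for f in series.significant[i]]
            fh.write("\t".join(row) + "\n")


def call_significant_fc(series: OmicsTimeSeries, fold_threshold: float = 1.5) -> OmicsTimeSeries:
    """Two-sided fold-change significance: |log2FC| >= log2(threshold).

    Applies the proteome convention (>=1.5-fold up or down) at every
    post-baseline timepoint, replacing any pre-existing flags.
    """
    if not fold_threshold > 1:
        raise ValidationError(f"fold_threshold must be > 1, got {fold_threshold}")
    cut = math.log2(fold_threshold)
    out = series.copy()
    out.significant = np.abs(out.logfc) >= cut
    out.significant[:, 0] = False
    return out


def restrict_to_common_timepoints(
    a: OmicsTimeSeries, b: OmicsTimeSeries
) -> Tuple[OmicsTimeSeries, OmicsTimeSeries]:
    """Restrict both series to the sorted intersection of their time grids."""
    common = sorted(set(a.timepoints.tolist()) & set(b.timepoints.tolist()))
    if len(common) < 2:
        raise ValidationError(
            "series share no timepoints beyond the baseline; cannot couple layers"
        )

    def restrict(series: OmicsTimeSeries) -> OmicsTimeSeries:
        cols = [series.timepoint_index(t) for t in common]
        return OmicsTimeSeries(
            series.layer, list(series.molecules), np.array(common),
            series.logfc[:, cols], series.significant[:, cols],
        )

    return restrict(a), restrict(b)


def ensure_significance(
    series: OmicsTimeSeries, fold_threshold: float = 1.5
) -> OmicsTimeSeries:
    """Use shipped significance flags if any are set; otherwise fall back to
    the fold-change rule with a logged warning (transcript-layer convention).
    """
    if series.significant.any():
        return series
    logger.warning(
        "%s layer carries no significance flags; falling back to the "
        ">=%.3g-fold rule", series.layer, fold_threshold,
    )
    return call_significant_fc(series, fold_threshold)
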