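"""Per-gene agreement between predicted and empirical change profiles.

For matched matrices of predicted and empirically measured expression
changes (molecules x genes), the Pearson correlation coefficient r is
computed per gene across molecules.  The distribution of r over the
universe summarizes predictor accuracy gene by gene; both the mean and the
distribution peak (histogram mode) are reported, alongside the maximum.

Genes with zero variance in either matrix have undefined r and are recorded
as missing (excluded from the summary, with a logged count).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProfilePair",
    "CorrelationReport",
    "per_gene_correlation",
    "summarize_distribution",
    "write_correlation_report",
]


@dataclass
class ProfilePair:
    """Predicted and empirical change matrices on a shared index.

    Both are molecules x genes DataFrames with identical row and column
    indices and finite entries.
    """

    predicted: pd.DataFrame
    empirical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.predicted.shape != self.empirical.shape:
            raise ValueError(
                f"shape mismatch: predicted {self.predicted.shape} vs "
                f"empirical {self.empirical.shape}"
            )
        if not self.predicted.index.equals(self.empirical.index):
            raise ValueError("molecule indices differ between matrices")
        if not self.predicted.columns.equals(self.empirical.columns):
            raise ValueError("gene indices differ between matrices")
        for label, df in (("predicted", self.predicted), ("empirical", self.empirical)):
            if not np.isfinite(df.to_numpy(dtype=float)).all():
                raise ValueError(f"{label} matrix contains non-finite entries")

    @property
    def n_molecules(self) -> int:
        return self.predicted.shape[0]

    @property
    def n_genes(self) -> int:
        return self.predicted.shape[1]


@dataclass
class CorrelationReport:
    """Per-gene Pearson r and its distribution summary."""

    r_per_gene: pd.Series  # indexed by gene id; NaN = undefined (zero variance)
    mean_r: float
    peak_r: float
    n_genes: int
    n_molecules: int
    n_missing: int


def per_gene_correlation(pair: ProfilePair) -> CorrelationReport:
    """Pearson r per gene across molecules.

    Requires at least 3 molecules.  Zero-variance genes (in either matrix)
    yield NaN and are excluded from the mean and peak.
    """
    if pair.n_molecules < 3:
        raise ValueError(
            f"need at least 3 molecules to correlate, got {pair.n_molecules}"
        )
    x = pair.predicted.to_numpy(dtype=float)
    y = pair.empirical.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    r = np.clip(r, -1.0, 1.0)
    r_series = pd.Series(r, index=pair.predicted.columns, name="r")
    finite = r_series.dropna()
    n_missing = int(r_series.isna().sum())
    if n_missing:
        logger.info("%d of %d genes have undefined r (zero variance)",
                    n_missing, pair.n_genes)
    if finite.empty:
        raise ValueError("no gene has defined correlation (all zero variance)")
    return CorrelationReport(
        r_per_gene=r_series,
        mean_r=float(finite.mean()),
        peak_r=_histogram_mode(finite.to_numpy()),
        n_genes=pair.n_genes,
        n_molecules=pair.n_molecules,
        n_missing=n_missing,
    )


# spread below which an r vector is treated as a point mass (its binned
# mode would be off by up to half a bin width)
_CONSTANT_TOL = 1e-9

# resolution guard: 1024 bins over [-1, 1] is a mode resolution of ~0.002
_MAX_BINS = 1024


def _bin_count(values: np.ndarray, n_bins: int | str = "auto") -> int:
    """Number of bins over [-1, 1]: Freedman–Diaconis width on the data."""
    if n_bins != "auto":
        k = int(n_bins)
        if k <= 0:
            raise ValueError(f"n_bins must be positive, got {n_bins}")
        return k
    if np.ptp(values) < _CONSTANT_TOL:
        return 1
    edges = np.histogram_bin_edges(values, bins="fd")
    width = edges[1] - edges[0] if len(edges) > 1 else 0.0
    if width <= 0:
        return 1
    return int(min(_MAX_BINS, max(1, np.ceil(2.0 / width))))


def _histogram_mode(values: np.ndarray, n_bins: int | str = "auto") -> float:
    """Midpoint of the tallest histogram bin over [-1, 1].

    A (numerically) constant vector short-circuits to its median.  Ties go
    to the leftmost tallest bin.
    """
    if values.size == 0:
        raise ValueError("empty correlation vector")
    if np.ptp(values) < _CONSTANT_TOL:
        return float(np.median(values))
    k = _bin_count(values, n_bins)
    counts, edges = np.histogram(values, bins=k, range=(-1.0, 1.0))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def summarize_distribution(
    report: CorrelationReport, n_bins: int | str = "auto"
) -> dict:
    """Mean, median, histogram mode (peak), max and bin counts over [-1, 1]."""
    finite = report.r_per_gene.dropna().to_numpy()
    if finite.size == 0:
        raise ValueError("empty correlation vector")
    counts, edges = np.histogram(
        finite, bins=_bin_count(finite, n_bins), range=(-1.0, 1.0)
    )
    return {
        "mean": float(np.mean(finite)),
        "median": float(np.median(finite)),
        "mode": _histogram_mode(finite, n_bins),
        "max": float(np.max(finite)),
        "n_genes": report.n_genes,
        "n_molecules": report.n_molecules,
        "n_missing": report.n_missing,
        "bin_edges": [float(e) for e in edges],
        "counts": [int(c) for c in counts],
    }


def write_correlation_report(
    report: CorrelationReport,
    r_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the per-gene r table (TSV) and optional JSON summary."""
    frame = report.r_per_gene.rename_axis("gene_id").reset_index()
    frame.to_csv(r_path, sep="\t", index=False)
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps(summarize_distribution(report), indent=2) + "\n"
        )
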