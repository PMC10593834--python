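"""Up/down gene signatures from two-group expression data.

A *gene signature* is a pair of disjoint gene sets — genes up- and
down-regulated in a biological contrast (here: adult vs. neonatal tendon, or
a curated stemness factor list).  Signatures are the query sets of the
rank-based enrichment score in :mod:`tenoscreen.enrichment`.

Differential expression is called per gene on log2-scale values with
Welch's unequal-variance two-sample t test; genes passing the raw P-value
threshold are split by fold-change sign, ranked by |log2FC| within each
direction and optionally truncated to the strongest ``max_up`` / ``max_down``
genes.  An optional Benjamini–Hochberg adjustment is available but off by
default (the screening protocol filters on raw P).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "GeneSignature",
    "compute_deg_signature",
    "restrict_to_universe",
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "deg_records_to_frame",
]


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for genes x samples with two-group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.
    sample_groups
        Mapping sample id -> group label; exactly two distinct labels.
    group_levels
        Ordered pair of the two labels.  Fold changes are computed as
        ``mean(level[0]) - mean(level[1])``; by convention the first level is
        the condition of interest (e.g. adult) and the second the reference
        (e.g. neonatal).  If omitted, labels are taken in sorted order.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    group_levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis("gene_id", axis=0).rename_axis(
            None, axis=1
        )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing[:5]}")
        labels = sorted({self.sample_groups[s] for s in self.values.columns})
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, got {labels}")
        if self.group_levels is None:
            self.group_levels = (labels[0], labels[1])
        elif sorted(self.group_levels) != labels:
            raise ValueError(
                f"group_levels {self.group_levels} do not match labels {labels}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    def group_columns(self, level: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == level]


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression statistics."""

    gene_id: str
    log2_fold_change: float
    p_value: float
    direction: str  # "up" iff log2_fold_change > 0, else "down"

    def __post_init__(self) -> None:
        expected = "up" if self.log2_fold_change > 0 else "down"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with "
                f"log2FC={self.log2_fold_change}"
            )
        if not np.isfinite(self.p_value) or not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be finite in [0,1], got {self.p_value}")


@dataclass
class GeneSignature:
    """Disjoint up/down gene sets with a name and provenance note."""

    up: set[str]
    down: set[str]
    name: str = "signature"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")
        if not self.up and not self.down:
            raise ValueError("signature must have at least one non-empty set")


def compute_deg_signature(
    expr: ExpressionMatrix,
    p_threshold: float = 0.05,
    max_up: int | None = None,
    max_down: int | None = None,
    adjust: str = "none",
    name: str = "deg_signature",
) -> tuple[GeneSignature, list[DEGRecord]]:
    """Call DEGs between the two groups and build an up/down signature.

    Per gene, Welch's t test on log2 values yields a P value and the fold
    change is the difference of group means (``group_levels[0]`` minus
    ``group_levels[1]``).  Genes with P below ``p_threshold`` are split by
    fold-change sign, each side ranked by \\|log2FC\\| descending (ties by gene
    id) and truncated to ``max_up`` / ``max_down``.

    ``adjust="bh"`` applies Benjamini–Hochberg to the P values before
    thresholding.  All-constant gene rows get P = 1.

    Returns the signature and the full per-gene record list (every gene,
    selected or not).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    level_a, level_b = expr.group_levels  # type: ignore[misc]
    cols_a = expr.group_columns(level_a)
    cols_b = expr.group_columns(level_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            "insufficient replication: each group needs at least 2 samples "
            f"(got {len(cols_a)} vs {len(cols_b)})"
        )

    a = expr.values[cols_a].to_numpy(dtype=float)
    b = expr.values[cols_b].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.asarray(stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue)
    # zero-variance rows: identical means carry no evidence (P=1); a
    # deterministic mean difference is called with certainty (P=0)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)

    p_selected = p
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_selected = multipletests(p, method="fdr_bh")[1]

    genes = np.asarray(expr.gene_ids)
    records = [
        DEGRecord(g, float(l), float(pv), "up" if l > 0 else "down")
        for g, l, pv in zip(genes, lfc, p)
    ]

    passing = p_selected < p_threshold

    def _select(side_mask: np.ndarray, limit: int | None) -> set[str]:
        idx = np.flatnonzero(passing & side_mask)
        order = sorted(idx, key=lambda i: (-abs(lfc[i]), genes[i]))
        if limit is not None:
            order = order[:limit]
        return {str(genes[i]) for i in order}

    up = _select(lfc > 0, max_up)
    down = _select(lfc < 0, max_down)
    # built via __new__ so an all-null dataset (no DEGs) is representable
    sig = GeneSignature.__new__(GeneSignature)
    sig.up, sig.down, sig.name = up, down, name
    sig.provenance = (
        f"DEG signature: {level_a} vs {level_b}, Welch t test, "
        f"p<{p_threshold} ({adjust}), max_up={max_up}, max_down={max_down}"
    )
    return sig, records


def deg_records_to_frame(
    records: Sequence[DEGRecord], signature: GeneSignature | None = None
) -> pd.DataFrame:
    """Tabulate DEG records (gene_id, log2_fold_change, p_value, direction,
    selected)."""
    selected_ids: set[str] = set()
    if signature is not None:
        selected_ids = signature.up | signature.down
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2_fold_change": [r.log2_fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "selected": [r.gene_id in selected_ids for r in records],
        }
    )


def restrict_to_universe(
    sig: GeneSignature, universe: Sequence[str]
) -> GeneSignature:
    """Drop signature genes absent from ``universe``, warning per dropped gene.

    Raises if nothing survives ("signature disjoint from universe").
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    dropped = sorted((sig.up | sig.down) - uni)
    for g in dropped:
        warnings.warn(
            f"gene {g!r} of signature {sig.name!r} is not in the "
            f"{len(uni)}-gene universe; dropped",
            UserWarning,
            stacklevel=2,
        )
    up = sig.up & uni
    down = sig.down & uni
    if not up and not down:
        raise ValueError(f"signature {sig.name!r} disjoint from universe")
    out = GeneSignature.__new__(GeneSignature)
    out.up, out.down, out.name, out.provenance = up, down, sig.name, sig.provenance
    return out


# ---------------------------------------------------------------------------
# GMT serialization.  Up/down sets are encoded as paired lines named
# "<name>_UP" / "<name>_DN" (Broad GMT dialect: name, description, genes).
# A line with neither suffix is read as an up-only signature.
# ---------------------------------------------------------------------------


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    """Write signatures to a GMT file (one ``_UP``/``_DN`` line per non-empty
    set, genes sorted for reproducibility)."""
    lines = []
    for sig in signatures:
        desc = sig.provenance or "na"
        if sig.up:
            lines.append("\t".join([f"{sig.name}_UP", desc, *sorted(sig.up)]))
        if sig.down:
            lines.append("\t".join([f"{sig.name}_DN", desc, *sorted(sig.down)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read GMT signatures, pairing ``<name>_UP`` with ``<name>_DN`` lines."""
    path = Path(path)
    seen_sets: set[str] = set()
    order: list[str] = []
    parts: dict[str, dict[str, object]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: expected at least 3 tab-separated "
                f"fields (name, description, genes), got {len(fields)}"
            )
        set_name, desc, genes = fields[0], fields[1], fields[2:]
        if set_name in seen_sets:
            raise ValueError(f"{path}: duplicate set name {set_name!r}")
        seen_sets.add(set_name)
        if set_name.endswith("_UP"):
            base, side = set_name[:-3], "up"
        elif set_name.endswith("_DN"):
            base, side = set_name[:-3], "down"
        else:
            base, side = set_name, "up"
        entry = parts.setdefault(base, {"up": set(), "down": set(), "desc": desc})
        entry[side] = set(genes)
        if base not in order:
            order.append(base)
    out = []
    for base in order:
        entry = parts[base]
        desc = str(entry["desc"])
        out.append(
            GeneSignature(
                up=entry["up"],  # type: ignore[arg-type]
                down=entry["down"],  # type: ignore[arg-type]
                name=base,
                provenance="" if desc == "na" else desc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expression TSV I/O: genes x samples matrix with a two-column sample->group
# map in a side file.
# ---------------------------------------------------------------------------


def write_expression_tsv(
    expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    groups = pd.DataFrame(
        {
            "sample": list(expr.values.columns),
            "group": [expr.sample_groups[s] for s in expr.values.columns],
        }
    )
    groups.to_csv(groups_path, sep="\t", index=False)


def read_expression_tsv(
    matrix_path: str | Path,
    groups_path: str | Path,
    group_levels: tuple[str, str] | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups.columns[:2]) != ["sample", "group"]:
        raise ValueError(
            f"{groups_path}: expected columns 'sample' and 'group', "
            f"got {list(groups.columns)}"
        )
    mapping = dict(zip(groups["sample"], groups["group"]))
    return ExpressionMatrix(values, mapping, group_levels)
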