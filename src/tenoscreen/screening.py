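"""Dual-signature screening of compound change-profile libraries.

A library holds one change profile per compound over a shared gene
universe.  Each compound is scored on two independent axes:

* a **stemness** axis — by default the enrichment (mimic) score of an
  up-only stemness factor signature, rewarding compounds predicted to
  induce those genes;
* a **tendon** axis — by default the reversal of the adult-vs-neonatal
  tendon signature (the enrichment score of the signature with its up and
  down sets swapped), rewarding compounds predicted to push the adult
  expression state back toward the neonatal one.  Both axes therefore live
  on the same [0, 2) scale with higher = better.

Compounds are dense-ranked on each axis (rank 1 = highest score; ties
broken by compound id, ascending) and the screen selects the intersection
of the per-axis top-K sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import ChangeProfile, combine_ks, enrichment_score, rank_profile
from .signatures import GeneSignature, restrict_to_universe

__all__ = [
    "CompoundLibrary",
    "SCREEN_COLUMNS",
    "score_library",
    "dual_score_screen",
    "write_screen_table",
    "read_screen_table",
    "read_library_tsv",
    "write_library_tsv",
]

#: Fixed column order of a screen table TSV.
SCREEN_COLUMNS = [
    "compound_id",
    "name",
    "stemness_score",
    "tendon_score",
    "stemness_rank",
    "tendon_rank",
    "selected",
]

ORIENTATIONS = ("mimic", "reverse")


@dataclass
class CompoundLibrary:
    """Compounds x genes matrix of predicted expression changes.

    ``profiles`` is indexed by compound id with one column per universe
    gene; ``metadata`` (optional) carries ``name`` and ``source_library``
    per compound.
    """

    profiles: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.profiles = self.profiles.rename_axis("compound_id", axis=0).rename_axis(
            None, axis=1
        )
        if self.profiles.index.duplicated().any():
            raise ValueError("duplicate compound ids in library")
        if self.profiles.columns.duplicated().any():
            raise ValueError("duplicate gene ids in library universe")
        vals = self.profiles.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            rows = self.profiles.index[~np.isfinite(vals).all(axis=1)]
            raise ValueError(f"non-finite deltas for compounds {list(rows[:5])}")
        if self.metadata is not None:
            missing = self.profiles.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing for compounds {list(missing[:5])}")

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[ChangeProfile],
        metadata: pd.DataFrame | None = None,
    ) -> "CompoundLibrary":
        """Assemble a library from per-compound profiles, which must all
        share the identical ordered gene universe."""
        if not profiles:
            raise ValueError("cannot build a library from zero profiles")
        reference = list(profiles[0].genes)
        for p in profiles[1:]:
            if list(p.genes) != reference:
                raise ValueError(
                    f"universe mismatch: profile {p.compound_id!r} does not "
                    f"share the universe of {profiles[0].compound_id!r}"
                )
        frame = pd.DataFrame(
            np.vstack([p.delta for p in profiles]),
            index=[p.compound_id for p in profiles],
            columns=reference,
        )
        return cls(frame, metadata)

    @property
    def universe(self) -> list[str]:
        return [str(g) for g in self.profiles.columns]

    @property
    def compound_ids(self) -> list[str]:
        return [str(c) for c in self.profiles.index]

    def __len__(self) -> int:
        return len(self.profiles)

    def profile(self, compound_id: str) -> ChangeProfile:
        row = self.profiles.loc[compound_id]
        return ChangeProfile(
            compound_id=str(compound_id),
            genes=np.asarray(self.universe, dtype=object),
            delta=row.to_numpy(dtype=float),
        )

    def name_of(self, compound_id: str) -> str:
        if self.metadata is not None and "name" in self.metadata.columns:
            return str(self.metadata.loc[compound_id, "name"])
        return str(compound_id)


def _rank_matrix(lib: CompoundLibrary) -> tuple[np.ndarray, dict[str, int]]:
    """1-based descending rank of every gene in every profile.

    Columns are pre-sorted by gene id so a stable argsort on -delta breaks
    ties by gene id ascending, matching :func:`enrichment.rank_profile`.
    """
    cols = sorted(lib.universe)
    m = lib.profiles[cols].to_numpy(dtype=float)
    order = np.argsort(-m, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(m.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, m.shape[1] + 1)
    return ranks, {g: i for i, g in enumerate(cols)}


def _ks_columns(
    ranks: np.ndarray, col_of: dict[str, int], genes: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (a, b) statistics of one gene set across all compounds."""
    idx = [col_of[g] for g in sorted(genes)]
    v = np.sort(ranks[:, idx].astype(float), axis=1)
    t = v.shape[1]
    n = ranks.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n, axis=1)
    b = -np.max((v - 1.0) / n - (j - 1.0) / t, axis=1)
    return a, b


def _swap_signature(sig: GeneSignature) -> GeneSignature:
    """Reverse a signature by exchanging its up and down query sets.

    Scoring the swapped signature against a profile is identical (up to
    rank-tie discretization) to scoring the original signature against the
    sign-negated profile: it asks how strongly the compound pushes the
    up genes *down* and the down genes *up*.  Unlike negating the combined
    score — which is bounded above by 0 and saturates there for every
    strong reverser — the swapped-signature score spreads reversers out on
    the same (0, 2) scale that the mimic score uses for mimics.
    """
    out = GeneSignature.__new__(GeneSignature)
    out.up, out.down = set(sig.down), set(sig.up)
    out.name, out.provenance = sig.name, sig.provenance
    return out


def score_library(
    lib: CompoundLibrary, sig: GeneSignature, orientation: str = "mimic"
) -> pd.Series:
    """Score every compound against one signature; higher is always better.

    ``orientation="mimic"`` rewards compounds predicted to induce the
    signature (enrichment score); ``"reverse"`` rewards compounds predicted
    to oppose it (enrichment of the up/down-swapped signature, see
    :func:`_swap_signature`).  The signature is restricted to the library
    universe first (dropped genes are warned about).  Output preserves
    library order.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    if len(lib) == 0:
        return pd.Series(dtype=float, name=f"{orientation}:{sig.name}")
    sig = restrict_to_universe(sig, lib.universe)
    if orientation == "reverse":
        sig = _swap_signature(sig)
    ranks, col_of = _rank_matrix(lib)
    a = np.zeros(len(lib))
    b = np.zeros(len(lib))
    if sig.up:
        a, _ = _ks_columns(ranks, col_of, sig.up)
    if sig.down:
        _, b = _ks_columns(ranks, col_of, sig.down)
    scores = np.array(
        [combine_ks(ai, bi, len(sig.up), len(sig.down)) for ai, bi in zip(a, b)]
    )
    return pd.Series(scores, index=lib.profiles.index, name=f"{orientation}:{sig.name}")


def score_profile(
    profile: ChangeProfile, sig: GeneSignature, orientation: str = "mimic"
) -> float:
    """Single-profile counterpart of :func:`score_library` (same conventions)."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    sig = restrict_to_universe(sig, [str(g) for g in profile.genes])
    if orientation == "reverse":
        sig = _swap_signature(sig)
    return enrichment_score(rank_profile(profile), sig).score


def _dense_rank_desc(scores: pd.Series) -> pd.Series:
    """1..N ranks, highest score first, ties by compound id ascending."""
    ids = scores.index.to_numpy(dtype=object)
    order = np.lexsort((ids, -scores.to_numpy(dtype=float)))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return pd.Series(ranks, index=scores.index)


def dual_score_screen(
    lib: CompoundLibrary,
    stemness_sig: GeneSignature,
    tendon_sig: GeneSignature,
    top_k_stemness: int | None = None,
    top_k_tendon: int | None = None,
    orientations: tuple[str, str] = ("mimic", "reverse"),
) -> pd.DataFrame:
    """Screen a library on the stemness and tendon axes.

    Each ``top_k`` defaults to the top 5% of the library (rounded up).
    Returns a DataFrame with :data:`SCREEN_COLUMNS`; ``selected`` flags
    compounds ranked in the top-K on *both* axes.
    """
    if top_k_stemness is None:
        top_k_stemness = max(1, math.ceil(0.05 * len(lib)))
    if top_k_tendon is None:
        top_k_tendon = max(1, math.ceil(0.05 * len(lib)))
    for k, label in ((top_k_stemness, "stemness"), (top_k_tendon, "tendon")):
        if k <= 0:
            raise ValueError(f"top_k_{label} must be positive, got {k}")
        if k > len(lib):
            raise ValueError(
                f"top_k_{label}={k} exceeds library size {len(lib)}"
            )
    stem_scores = score_library(lib, stemness_sig, orientations[0])
    tendon_scores = score_library(lib, tendon_sig, orientations[1])
    stem_rank = _dense_rank_desc(stem_scores)
    tendon_rank = _dense_rank_desc(tendon_scores)
    selected = (stem_rank <= top_k_stemness) & (tendon_rank <= top_k_tendon)
    return pd.DataFrame(
        {
            "compound_id": lib.compound_ids,
            "name": [lib.name_of(c) for c in lib.compound_ids],
            "stemness_score": stem_scores.to_numpy(),
            "tendon_score": tendon_scores.to_numpy(),
            "stemness_rank": stem_rank.to_numpy(),
            "tendon_rank": tendon_rank.to_numpy(),
            "selected": selected.to_numpy(),
        }
    )


def write_screen_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen table missing columns {missing}")
    try:
        table[SCREEN_COLUMNS].to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write screen table to {path}: {exc}") from exc


def read_screen_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str})
    except OSError as exc:
        raise OSError(f"cannot read screen table from {path}: {exc}") from exc
    df["selected"] = df["selected"].astype(bool)
    return df[SCREEN_COLUMNS]


def read_library_tsv(
    path: str | Path, metadata_path: str | Path | None = None
) -> CompoundLibrary:
    """Read a compounds x genes TSV (first column compound id, header =
    gene universe), plus an optional metadata TSV."""
    profiles = pd.read_csv(path, sep="\t", index_col=0)
    profiles.index = profiles.index.astype(str)
    profiles.columns = profiles.columns.astype(str)
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        metadata.index = metadata.index.astype(str)
    return CompoundLibrary(profiles, metadata)


def write_library_tsv(
    lib: CompoundLibrary,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    lib.profiles.to_csv(path, sep="\t", index_label="compound_id")
    if metadata_path is not None and lib.metadata is not None:
        lib.metadata.to_csv(metadata_path, sep="\t", index_label="compound_id")
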