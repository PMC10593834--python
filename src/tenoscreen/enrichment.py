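"""Rank-based Kolmogorov–Smirnov enrichment of gene sets in change profiles.

A compound's predicted change of transcriptional profile (CTP) assigns each
of the *n* universe genes a real-valued expression change.  Genes are ranked
in descending order of change (rank 1 = most upregulated; ties broken by
gene id, ascending).  For a query set of *t* genes with sorted ranks
``V(1) < ... < V(t)``, the connectivity-map-style KS statistics are the
closed-form maxima of the running-sum deviation::

    a =  max_{j=1..t} [ j/t - V(j)/n ]          (up-set statistic,   0 <= a < 1)
    b = -max_{j=1..t} [ (V(j)-1)/n - (j-1)/t ]  (down-set statistic, -1 < b <= 0)

The combined enrichment score for a two-sided signature is::

    Score = a - b   when a * b < 0
    Score = 0       otherwise

Since a >= 0 and b <= 0 by construction, ``a * b > 0`` can never occur; the
``otherwise`` branch fires only when either statistic is exactly zero (no
coherent deviation).  An up-only (or down-only) signature bypasses the sign
condition and scores ``a`` (or ``-b``) directly — this is the path taken by
the up-only Yamanaka stemness factor set.

The *reversal score* is the negation ``-(a - b)``, equivalently ``b - a``:
it ranks compounds whose induced changes oppose the signature, the quantity
maximized when screening for disease-signature reversers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "ChangeProfile",
    "RankedProfile",
    "EnrichmentResult",
    "rank_profile",
    "ks_up",
    "ks_down",
    "enrichment_score",
    "reversal_score",
    "read_rnk",
    "write_rnk",
    "result_to_json",
]


@dataclass
class ChangeProfile:
    """Per-gene predicted expression change for one compound."""

    compound_id: str
    genes: np.ndarray  # ordered gene universe
    delta: np.ndarray  # same length, finite

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.genes.shape != self.delta.shape:
            raise ValueError(
                f"profile {self.compound_id!r}: {len(self.genes)} genes but "
                f"{len(self.delta)} deltas"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"profile {self.compound_id!r}: duplicate gene ids")
        bad = ~np.isfinite(self.delta)
        if bad.any():
            first = self.genes[bad][0]
            raise ValueError(
                f"profile {self.compound_id!r}: non-finite delta for gene {first!r}"
            )

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class RankedProfile:
    """Descending ranking of a change profile: gene -> rank in 1..n."""

    compound_id: str
    rank_of: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.rank_of)

    def ranks(self, genes: Iterable[str]) -> np.ndarray:
        """Sorted ranks of a query gene set; raises on genes outside the
        universe (restrict the signature first)."""
        try:
            v = np.array([self.rank_of[g] for g in genes], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"gene {exc.args[0]!r} not in the ranked universe of "
                f"{self.compound_id!r}; restrict the signature to the universe"
            ) from None
        v.sort()
        return v


@dataclass(frozen=True)
class EnrichmentResult:
    """KS statistics for one profile x one signature."""

    compound_id: str
    a: float
    b: float
    score: float
    reversal_score: float
    t_up: int
    t_down: int


def rank_profile(profile: ChangeProfile) -> RankedProfile:
    """Rank genes by delta descending, ties by gene id ascending, 1-based."""
    # lexsort: primary key -delta (descending delta), secondary gene id
    order = np.lexsort((profile.genes, -profile.delta))
    rank_of = {str(profile.genes[i]): int(pos + 1) for pos, i in enumerate(order)}
    return RankedProfile(profile.compound_id, rank_of)


def ks_up(ranked: RankedProfile, genes: Iterable[str]) -> float:
    """Up-set statistic a = max_j [ j/t - V(j)/n ]."""
    v = ranked.ranks(genes)
    t = len(v)
    if t == 0:
        raise ValueError("empty query set")
    n = ranked.n
    j = np.arange(1, t + 1, dtype=float)
    return float(np.max(j / t - v / n))


def ks_down(ranked: RankedProfile, genes: Iterable[str]) -> float:
    """Down-set statistic b = -max_j [ (V(j)-1)/n - (j-1)/t ]."""
    v = ranked.ranks(genes)
    t = len(v)
    if t == 0:
        raise ValueError("empty query set")
    n = ranked.n
    j = np.arange(1, t + 1, dtype=float)
    return float(-np.max((v - 1.0) / n - (j - 1.0) / t))


def combine_ks(a: float, b: float, t_up: int, t_down: int) -> float:
    """Piecewise combination of the up/down statistics into one score.

    Two-sided signatures use the printed condition (``a - b`` when
    ``a*b < 0``, else 0, covering the unreachable ``a*b > 0`` branch and the
    degenerate ``a*b == 0`` case); one-sided signatures score their single
    statistic directly.
    """
    if t_up > 0 and t_down > 0:
        return a - b if a * b < 0 else 0.0
    if t_up > 0:
        return a
    if t_down > 0:
        return -b
    raise ValueError("signature has no genes on either side")


def enrichment_score(ranked: RankedProfile, sig: GeneSignature) -> EnrichmentResult:
    """Score one ranked profile against an up/down signature.

    The signature must already be restricted to the profile's universe
    (see :func:`tenoscreen.signatures.restrict_to_universe`).
    """
    a = ks_up(ranked, sig.up) if sig.up else 0.0
    b = ks_down(ranked, sig.down) if sig.down else 0.0
    score = combine_ks(a, b, len(sig.up), len(sig.down))
    return EnrichmentResult(
        compound_id=ranked.compound_id,
        a=a,
        b=b,
        score=score,
        reversal_score=-score,
        t_up=len(sig.up),
        t_down=len(sig.down),
    )


def reversal_score(ranked: RankedProfile, sig: GeneSignature) -> float:
    """Negated enrichment score: positive when the profile opposes the
    signature (up-genes pushed down and vice versa)."""
    return enrichment_score(ranked, sig).reversal_score


# ---------------------------------------------------------------------------
# I/O: two-column RNK-style TSV (gene_id <tab> delta, no header) and JSON
# serialization of results.
# ---------------------------------------------------------------------------


def write_rnk(profile: ChangeProfile, path: str | Path) -> None:
    pd.DataFrame({"gene_id": profile.genes, "delta": profile.delta}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_rnk(path: str | Path, compound_id: str | None = None) -> ChangeProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "delta"])
    return ChangeProfile(
        compound_id=compound_id or path.stem,
        genes=df["gene_id"].astype(str).to_numpy(),
        delta=df["delta"].to_numpy(dtype=float),
    )


def result_to_json(result: EnrichmentResult, path: str | Path | None = None) -> str:
    payload: Mapping[str, object] = {
        "compound_id": result.compound_id,
        "a": result.a,
        "b": result.b,
        "score": result.score,
        "reversal_score": result.reversal_score,
        "t_up": result.t_up,
        "t_down": result.t_down,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
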