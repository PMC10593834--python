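from __future__ import annotations

import numpy as np
import pytest

from tenoscreen.enrichment import ChangeProfile, RankedProfile, rank_profile


def gene_ids(n: int) -> np.ndarray:
    return np.array([f"g{i:04d}" for i in range(1, n + 1)], dtype=object)


def profile_from_ranks(rank_assignment: dict[str, int], compound_id: str = "cpd") -> ChangeProfile:
    """Build a profile whose descending-delta ranking realizes the given
    gene -> rank mapping exactly (delta = n - rank, all distinct)."""
    n = len(rank_assignment)
    genes = np.array(sorted(rank_assignment), dtype=object)
    delta = np.array([float(n - rank_assignment[g]) for g in genes])
    return ChangeProfile(compound_id, genes, delta)


def ranked_with_query_at(n: int, query_ranks: list[int]) -> tuple[RankedProfile, set[str]]:
    """A ranked n-gene profile with a query set planted at the given ranks."""
    genes = gene_ids(n)
    assignment = {str(g): i + 1 for i, g in enumerate(genes)}
    ranked = rank_profile(profile_from_ranks(assignment))
    inverse = {rank: g for g, rank in ranked.rank_of.items()}
    query = {inverse[r] for r in query_ranks}
    return ranked, query


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
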