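"""Synthetic datasets with known ground truth for the screening pipeline.

Every generator here emulates the *shape* of one pipeline input — not the
biology behind it — so that recovery can be checked against planted truth:

* two-group log2 expression matrices with planted differentially expressed
  genes (adult vs. neonatal tendon contrast),
* compound libraries of per-gene change profiles with planted
  signature-mimicking / signature-reversing hits,
* paired predicted/empirical profile matrices with a controlled per-gene
  correlation, standing in for a trained transcriptional-change predictor
  and its held-out measurements,
* footprint/grip measurement tables for the functional indices.

All noise is Gaussian on the log2 (or change) scale.  Each generator is a
pure function of its configuration and seed: a single global seed fans out
to fixed per-generator substreams, so rerunning any one generator with the
same config is byte-identical.

Defaults mirror the screening study design: a 12,328-gene universe, a
3,680-compound library, 6 vs. 6 samples, 100/150 planted up/down genes at
|log2FC| = 2 over noise SD 0.5, and 20 hits per category at 3 noise-SD
reversal strength.  ``SimulationConfig.test_scale()`` shrinks the universe
and library to 2,000 x 2,000 for fast runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluation import ProfilePair
from .screening import CompoundLibrary
from .signatures import ExpressionMatrix, GeneSignature

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "gene_universe",
    "simulate_expression",
    "simulate_ctp_library",
    "simulate_paired_profiles",
    "simulate_footprints",
    "random_signature",
    "draw_rho_beta",
]

# fixed substream tags so each generator draws independently of the others
_STREAM_EXPRESSION = 1
_STREAM_LIBRARY = 2
_STREAM_PAIRED = 3
_STREAM_FOOTPRINT = 4
_STREAM_SIGNATURE = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters shared by the generators.

    Counts and effect sizes default to the screening study conditions; see
    the module docstring.  ``effect_size`` is in log2 fold-change units,
    ``noise_sd`` in log2 units, ``reversal_strength`` in multiples of
    ``noise_sd``.
    """

    n_genes: int = 12328
    n_compounds: int = 3680
    n_molecules: int = 3000
    group_sizes: tuple[int, int] = (6, 6)
    n_up: int = 100
    n_down: int = 150
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_stemness_hits: int = 20
    n_tendon_hits: int = 20
    n_dual_hits: int = 20
    reversal_strength: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_compounds", "n_molecules", "n_up", "n_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0 or self.reversal_strength < 0:
            raise ValueError("noise_sd and reversal_strength must be non-negative")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError(
                f"planted DEG count {self.n_up + self.n_down} exceeds "
                f"n_genes={self.n_genes}"
            )
        total_hits = self.n_stemness_hits + self.n_tendon_hits + self.n_dual_hits
        if total_hits > self.n_compounds:
            raise ValueError(
                f"planted hit count {total_hits} exceeds n_compounds={self.n_compounds}"
            )

    @classmethod
    def test_scale(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Reduced-size preset (2,000 genes / 2,000 compounds / 500 paired
        molecules) for fast test runs; all other conditions unchanged."""
        params = dict(n_genes=2000, n_compounds=2000, n_molecules=500, seed=seed)
        params.update(overrides)
        return cls(**params)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        return d


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    planted_up: list[str] = field(default_factory=list)
    planted_down: list[str] = field(default_factory=list)
    stemness_hits: list[str] = field(default_factory=list)
    tendon_hits: list[str] = field(default_factory=list)
    dual_hits: list[str] = field(default_factory=list)
    rho: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def gene_universe(n: int) -> list[str]:
    """Synthetic gene ids G000001.. (zero-padded: lexicographic == numeric)."""
    return [f"G{i:06d}" for i in range(1, n + 1)]


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-group log2 expression with planted up/down DEGs.

    Per-gene baselines are drawn once (N(8, 2), log2 scale); the adult group
    mean is shifted by +effect_size on planted up genes and -effect_size on
    planted down genes relative to the neonatal group; i.i.d. N(0, noise_sd)
    noise is added everywhere.  Fold changes are taken adult - neonatal, so
    planted "up" genes come out up.
    """
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    genes = gene_universe(cfg.n_genes)
    n_a, n_b = cfg.group_sizes
    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)

    planted = rng.choice(cfg.n_genes, size=cfg.n_up + cfg.n_down, replace=False)
    up_idx, down_idx = planted[: cfg.n_up], planted[cfg.n_up :]
    shift = np.zeros(cfg.n_genes)
    shift[up_idx] = cfg.effect_size
    shift[down_idx] = -cfg.effect_size

    adult = (baseline + shift)[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, n_a)
    )
    neonatal = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, n_b)
    )
    samples = [f"adult_{i+1}" for i in range(n_a)] + [
        f"neonatal_{i+1}" for i in range(n_b)
    ]
    values = pd.DataFrame(
        np.hstack([adult, neonatal]), index=genes, columns=samples
    )
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    expr = ExpressionMatrix(values, groups, group_levels=("adult", "neonatal"))
    truth = PlantedTruth(
        planted_up=sorted(genes[i] for i in up_idx),
        planted_down=sorted(genes[i] for i in down_idx),
        extras={"seed": cfg.seed, "effect_size": cfg.effect_size,
                "noise_sd": cfg.noise_sd},
    )
    return expr, truth


def random_signature(
    universe: Sequence[str],
    n_up: int,
    n_down: int,
    name: str = "signature",
    seed: int = 0,
    exclude: set[str] | None = None,
) -> GeneSignature:
    """Draw a signature of random universe genes (for library simulations)."""
    rng = _rng(seed, _STREAM_SIGNATURE)
    pool = [g for g in universe if not exclude or g not in exclude]
    if n_up + n_down > len(pool):
        raise ValueError("signature larger than available universe")
    chosen = rng.choice(len(pool), size=n_up + n_down, replace=False)
    up = {pool[i] for i in chosen[:n_up]}
    down = {pool[i] for i in chosen[n_up:]}
    return GeneSignature(up, down, name, provenance=f"synthetic, seed={seed}")


def simulate_ctp_library(
    cfg: SimulationConfig,
    stemness_sig: GeneSignature,
    tendon_sig: GeneSignature,
) -> tuple[CompoundLibrary, PlantedTruth]:
    """Compound library of change profiles with planted hits.

    Null compounds have i.i.d. N(0, noise_sd) deltas over the universe.
    Stemness hits *mimic* the stemness signature (up genes shifted up, down
    genes shifted down by ``reversal_strength * noise_sd``); tendon hits
    *reverse* the tendon signature (up genes shifted down, down genes up);
    dual hits do both.  Signatures must already lie inside the universe.
    """
    genes = gene_universe(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sig in (stemness_sig, tendon_sig):
        outside = (sig.up | sig.down) - set(genes)
        if outside:
            raise ValueError(
                f"signature {sig.name!r} has genes outside the universe: "
                f"{sorted(outside)[:5]}"
            )
    rng = _rng(cfg.seed, _STREAM_LIBRARY)
    deltas = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_compounds, cfg.n_genes))

    total = cfg.n_dual_hits + cfg.n_stemness_hits + cfg.n_tendon_hits
    chosen = rng.choice(cfg.n_compounds, size=total, replace=False)
    dual = chosen[: cfg.n_dual_hits]
    stem_only = chosen[cfg.n_dual_hits : cfg.n_dual_hits + cfg.n_stemness_hits]
    tendon_only = chosen[cfg.n_dual_hits + cfg.n_stemness_hits :]

    bump = cfg.reversal_strength * cfg.noise_sd
    stem_up = [gene_pos[g] for g in sorted(stemness_sig.up)]
    stem_dn = [gene_pos[g] for g in sorted(stemness_sig.down)]
    tend_up = [gene_pos[g] for g in sorted(tendon_sig.up)]
    tend_dn = [gene_pos[g] for g in sorted(tendon_sig.down)]
    for rows in (dual, stem_only):
        if stem_up:
            deltas[np.ix_(rows, stem_up)] += bump
        if stem_dn:
            deltas[np.ix_(rows, stem_dn)] -= bump
    for rows in (dual, tendon_only):
        if tend_up:
            deltas[np.ix_(rows, tend_up)] -= bump
        if tend_dn:
            deltas[np.ix_(rows, tend_dn)] += bump

    width = len(str(cfg.n_compounds))
    ids = [f"C{i+1:0{width}d}" for i in range(cfg.n_compounds)]
    profiles = pd.DataFrame(deltas, index=ids, columns=genes)
    metadata = pd.DataFrame(
        {"name": [f"compound_{c}" for c in ids],
         "source_library": ["synthetic"] * len(ids)},
        index=pd.Index(ids, name="compound_id"),
    )
    truth = PlantedTruth(
        stemness_hits=sorted(ids[i] for i in stem_only),
        tendon_hits=sorted(ids[i] for i in tendon_only),
        dual_hits=sorted(ids[i] for i in dual),
        extras={"seed": cfg.seed, "reversal_strength": cfg.reversal_strength,
                "noise_sd": cfg.noise_sd},
    )
    return CompoundLibrary(profiles, metadata), truth


def draw_rho_beta(
    n_genes: int, mean: float = 0.74, concentration: float = 10.0, seed: int = 0
) -> np.ndarray:
    """Per-gene target correlations from Beta(mean*c, (1-mean)*c) on (0, 1).

    The default mean 0.74 with concentration 10 gives a right-skewed
    distribution peaking around 0.8, a plausible shape for a well-trained
    predictor evaluated gene by gene.
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    rng = _rng(seed, _STREAM_PAIRED + 100)
    rho = rng.beta(mean * concentration, (1 - mean) * concentration, size=n_genes)
    return np.clip(rho, -0.999999, 0.999999)


def simulate_paired_profiles(
    cfg: SimulationConfig,
    rho: float | Sequence[float] | Callable[[np.random.Generator, int], np.ndarray],
) -> tuple[ProfilePair, PlantedTruth]:
    """Paired predicted/empirical matrices with controlled per-gene r.

    Per gene g with target correlation rho_g, the predicted column is
    standard normal over molecules and the empirical column is
    ``rho_g * predicted + sqrt(1 - rho_g^2) * noise`` — a bivariate normal
    with exactly the target population correlation.
    """
    rng = _rng(cfg.seed, _STREAM_PAIRED)
    if callable(rho):
        rho_vec = np.asarray(rho(rng, cfg.n_genes), dtype=float)
    else:
        rho_vec = np.broadcast_to(
            np.asarray(rho, dtype=float), (cfg.n_genes,)
        ).copy()
    if np.any(np.abs(rho_vec) >= 1.0):
        raise ValueError("target correlations must lie strictly inside (-1, 1)")
    m, g = cfg.n_molecules, cfg.n_genes
    predicted = rng.standard_normal((m, g))
    noise = rng.standard_normal((m, g))
    empirical = rho_vec * predicted + np.sqrt(1.0 - rho_vec**2) * noise
    genes = gene_universe(g)
    molecules = [f"M{i+1:05d}" for i in range(m)]
    pair = ProfilePair(
        predicted=pd.DataFrame(predicted, index=molecules, columns=genes),
        empirical=pd.DataFrame(empirical, index=molecules, columns=genes),
    )
    truth = PlantedTruth(
        rho=dict(zip(genes, map(float, rho_vec))),
        extras={"seed": cfg.seed, "n_molecules": m},
    )
    return pair, truth


def simulate_footprints(
    n_animals: int = 10,
    injury_effect: float = 0.7,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Footprint and grip measurement table for ``n_animals`` rats.

    Normal-side lengths are drawn from rat-plausible ranges (PL 28-35 mm,
    TS 18-24 mm, IT 9-13 mm).  ``injury_effect`` f in (0, 1] scales the
    injured side: toe spreads shrink by f, print length stretches by 1/f
    (an injured paw drags), and grip readings scale by f; ``noise_sd`` is
    the fractional measurement noise.  f = 1 with no noise reproduces
    AFI = -5 exactly.
    """
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    if injury_effect <= 0:
        raise ValueError("injury_effect must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed, _STREAM_FOOTPRINT)
    f = injury_effect
    npl = rng.uniform(28.0, 35.0, n_animals)
    nts = rng.uniform(18.0, 24.0, n_animals)
    nit = rng.uniform(9.0, 13.0, n_animals)

    def jitter(shape):
        return 1.0 + rng.normal(0.0, noise_sd, shape)

    epl = npl / f * jitter(n_animals)
    ets = nts * f * jitter(n_animals)
    eit = nit * f * jitter(n_animals)
    grip_base = rng.uniform(700.0, 1100.0, n_animals) * f
    grips = grip_base[:, None] * jitter((n_animals, 5))
    bw = rng.uniform(350.0, 550.0, n_animals)

    table = pd.DataFrame(
        {
            "animal_id": [f"rat_{i+1:02d}" for i in range(n_animals)],
            "NPL": npl, "EPL": epl, "NTS": nts, "ETS": ets,
            "NIT": nit, "EIT": eit,
            **{f"grip_{j+1}": grips[:, j] for j in range(5)},
            "body_weight": bw,
        }
    )
    # noise-free factors are length-independent functions of f alone
    plf = f - 1.0
    tsf = f - 1.0
    itf = f - 1.0
    expected_afi = 74 * plf + 161 * tsf + 48 * itf - 5
    truth = PlantedTruth(
        extras={
            "seed": seed,
            "injury_effect": f,
            "noise_sd": noise_sd,
            "expected_afi_noise_free": expected_afi,
        }
    )
    return table, truth
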