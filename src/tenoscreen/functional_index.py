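"""Achilles functional index (AFI) and normalized grip strength.

The AFI is a gait score for rodent hindlimb function after Achilles tendon
injury.  Three footprint dimensions are measured on the injured
(experimental, E) and contralateral uninjured (normal, N) hind paw:

* ``PL`` — print length,
* ``TS`` — toe spread, the distance between the first and fifth toes,
* ``IT`` — intermediary toe spread, between the second and fourth toes.

Three dimensionless factors are formed from the normal/experimental
difference::

    PLF = (NPL - EPL) / EPL
    TSF = (ETS - NTS) / NTS
    ITF = (EIT - NIT) / NIT

and combined linearly into the index::

    AFI = 74 * PLF + 161 * TSF + 48 * ITF - 5

A more negative AFI indicates more severe hypomotility; an uninjured paw
(E == N) scores exactly -5.  Lengths are conventionally recorded in mm, but
the factors are ratios, so the unit cancels.

Grip strength is measured as five sequential pull tests on a dynamometer;
the index is the mean of the three middle readings (min and max discarded)
normalized by body weight (g/BW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AFI_COEFFICIENTS",
    "FootprintMeasure",
    "AFIResult",
    "footprint_factors",
    "afi",
    "grip_index",
    "evaluate_footprint_table",
    "evaluate_grip_table",
    "FOOTPRINT_COLUMNS",
    "GRIP_COLUMNS",
]

#: Linear weights (PLF, TSF, ITF) and intercept of the AFI equation.
AFI_COEFFICIENTS = (74.0, 161.0, 48.0, -5.0)

#: Required columns of a footprint measurement table.
FOOTPRINT_COLUMNS = ["NPL", "EPL", "NTS", "ETS", "NIT", "EIT"]

#: Required columns of a grip measurement table.
GRIP_COLUMNS = ["grip_1", "grip_2", "grip_3", "grip_4", "grip_5", "body_weight"]


@dataclass(frozen=True)
class FootprintMeasure:
    """One hind-paw footprint: print length and two toe spreads (mm)."""

    PL: float
    TS: float
    IT: float

    def __post_init__(self) -> None:
        for field in ("PL", "TS", "IT"):
            v = getattr(self, field)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"footprint measure {field} must be finite and positive, got {v!r}"
                )


@dataclass(frozen=True)
class AFIResult:
    """Footprint factors and the derived Achilles functional index."""

    PLF: float
    TSF: float
    ITF: float
    AFI: float


def footprint_factors(
    normal: FootprintMeasure, experimental: FootprintMeasure
) -> tuple[float, float, float]:
    """Compute (PLF, TSF, ITF) from paired normal/experimental footprints.

    PLF is normalized by the experimental print length; TSF and ITF by the
    normal toe spreads.
    """
    plf = (normal.PL - experimental.PL) / experimental.PL
    tsf = (experimental.TS - normal.TS) / normal.TS
    itf = (experimental.IT - normal.IT) / normal.IT
    return plf, tsf, itf


def afi(plf: float, tsf: float, itf: float) -> float:
    """Evaluate the AFI linear form 74*PLF + 161*TSF + 48*ITF - 5."""
    for name, v in (("PLF", plf), ("TSF", tsf), ("ITF", itf)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    w_pl, w_ts, w_it, intercept = AFI_COEFFICIENTS
    return w_pl * plf + w_ts * tsf + w_it * itf + intercept


def afi_from_measures(
    normal: FootprintMeasure, experimental: FootprintMeasure
) -> AFIResult:
    """Convenience wrapper: factors plus AFI from two footprint measures."""
    plf, tsf, itf = footprint_factors(normal, experimental)
    return AFIResult(plf, tsf, itf, afi(plf, tsf, itf))


def grip_index(readings: Sequence[float] | Iterable[float], body_weight: float) -> float:
    """Normalized grip strength from five sequential pull tests.

    The five readings (grams) are sorted, the minimum and maximum discarded,
    and the mean of the middle three is divided by body weight, giving the
    dimensionless g/BW index.
    """
    vals = [float(v) for v in readings]
    if len(vals) != 5:
        raise ValueError(f"grip test requires exactly 5 readings, got {len(vals)}")
    for v in vals:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"grip readings must be finite and positive, got {v!r}")
    if not math.isfinite(body_weight) or body_weight <= 0:
        raise ValueError(f"body weight must be finite and positive, got {body_weight!r}")
    middle = sorted(vals)[1:4]
    return (sum(middle) / 3.0) / body_weight


def evaluate_footprint_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append PLF, TSF, ITF and AFI columns to a footprint table.

    The table must contain the six length columns NPL, EPL, NTS, ETS, NIT,
    EIT (one row per animal/timepoint).  Returns a copy.
    """
    missing = [c for c in FOOTPRINT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"footprint table is missing columns: {missing}")
    out = table.copy()
    results = []
    for _, row in table.iterrows():
        normal = FootprintMeasure(row["NPL"], row["NTS"], row["NIT"])
        experimental = FootprintMeasure(row["EPL"], row["ETS"], row["EIT"])
        results.append(afi_from_measures(normal, experimental))
    out["PLF"] = [r.PLF for r in results]
    out["TSF"] = [r.TSF for r in results]
    out["ITF"] = [r.ITF for r in results]
    out["AFI"] = [r.AFI for r in results]
    return out


def evaluate_grip_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append the g/BW grip index column to a grip measurement table.

    Expects five reading columns ``grip_1``..``grip_5`` and ``body_weight``
    (all in grams).  Returns a copy with a ``g_per_bw`` column.
    """
    missing = [c for c in GRIP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"grip table is missing columns: {missing}")
    out = table.copy()
    out["g_per_bw"] = [
        grip_index([row[f"grip_{i}"] for i in range(1, 6)], row["body_weight"])
        for _, row in table.iterrows()
    ]
    return out
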