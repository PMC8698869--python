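"""Derived quantities used by the prioritisation analysis.

From each species' ordinal scores the analysis derives:

* **cost** — the currency mid-point of the RM cost band (1 = under £50k,
  2 = £50-200k, 3 = £200k-1M, 4 = £1-10M, 5 = £10M+);
* **benefit** — the potential impact removed by eradication, the product
  of the RA spread and impact scores (1-25);
* **tie-break keys** — geometric means of component scores, used to order
  species whose overall scores tie;
* **combined** — the sum of overall risk (1-3) and overall feasibility of
  eradication (1-5), ranging 2-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import gmean

from .data_io import SpeciesRecord

__all__ = [
    "DEFAULT_COST_MIDPOINTS",
    "DerivedScores",
    "validate_band_map",
    "cost_midpoint",
    "benefit_score",
    "geometric_mean",
    "derive_scores",
]

#: Default cost-band mid-points in GBP.  Band 1 ("< £50k") is treated as
#: 0-50k; band 5 ("£10M+") as 10-100M, consistent with published per-species
#: costs of £25,000 and £55,000,000 for those bands.
DEFAULT_COST_MIDPOINTS: Mapping[int, float] = {
    1: 25_000.0,
    2: 125_000.0,
    3: 600_000.0,
    4: 5_500_000.0,
    5: 55_000_000.0,
}


def validate_band_map(band_map: Mapping[int, float]) -> None:
    """Check a cost-band map: keys 1..5, positive, strictly increasing."""
    if sorted(band_map) != [1, 2, 3, 4, 5]:
        raise ValueError("cost band map must have exactly the keys 1..5")
    values = [band_map[k] for k in range(1, 6)]
    if any(v <= 0 for v in values):
        raise ValueError("cost band mid-points must be positive")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("cost band mid-points must be strictly increasing")


def cost_midpoint(
    cost_score: int, band_map: Mapping[int, float] = DEFAULT_COST_MIDPOINTS
) -> float:
    """Currency mid-point (GBP) of an RM cost band score (1-5)."""
    if cost_score not in (1, 2, 3, 4, 5):
        raise ValueError(f"cost score must be in 1..5, got {cost_score!r}")
    validate_band_map(band_map)
    return float(band_map[cost_score])


def benefit_score(spread: int, impact: int) -> int:
    """Potential impact removed: the product of spread and impact (1-25)."""
    for label, value in (("spread", spread), ("impact", impact)):
        if not isinstance(value, int) or not 1 <= value <= 5:
            raise ValueError(f"{label} must be an integer in 1..5, got {value!r}")
    return spread * impact


def geometric_mean(scores: Sequence[float]) -> float:
    """Geometric mean of positive values: (prod scores)^(1/k)."""
    if len(scores) == 0:
        raise ValueError("geometric mean of an empty sequence is undefined")
    if any(s <= 0 for s in scores):
        raise ValueError("geometric mean requires strictly positive values")
    return float(gmean(scores))


@dataclass(frozen=True)
class DerivedScores:
    """All derived quantities for one species."""

    cost: float
    benefit: int
    ra_tiebreak: float
    rm_tiebreak: float
    combined: int
    combined_tiebreak: float


def derive_scores(
    record: SpeciesRecord,
    band_map: Mapping[int, float] = DEFAULT_COST_MIDPOINTS,
    invert_cost_in_tiebreak: bool = False,
) -> DerivedScores:
    """Compute cost, benefit, tie-break keys and the combined score.

    The RA tie-break is the geometric mean of entry, establishment, spread
    and impact.  The RM tie-break is the geometric mean of effectiveness,
    practicality, cost, impact and acceptability (reinvasion and window are
    excluded).  Because a *high* cost band means *more expensive*, the cost
    component arguably points the wrong way inside a feasibility tie-break;
    ``invert_cost_in_tiebreak`` replaces it with ``6 - rm_cost``.  The
    default keeps the literal component score.
    """
    cost = cost_midpoint(record.rm_cost, band_map)
    benefit = benefit_score(record.ra_spread, record.ra_impact)
    ra_tiebreak = geometric_mean(
        [record.ra_entry, record.ra_establishment, record.ra_spread, record.ra_impact]
    )
    cost_component = 6 - record.rm_cost if invert_cost_in_tiebreak else record.rm_cost
    rm_tiebreak = geometric_mean(
        [
            record.rm_effectiveness,
            record.rm_practicality,
            cost_component,
            record.rm_impact,
            record.rm_acceptability,
        ]
    )
    combined = record.ra_overall + record.rm_overall
    if not 2 <= combined <= 8:  # pragma: no cover - guaranteed by record validation
        raise ValueError(f"combined score {combined} outside 2..8")
    return DerivedScores(
        cost=cost,
        benefit=benefit,
        ra_tiebreak=ra_tiebreak,
        rm_tiebreak=rm_tiebreak,
        combined=combined,
        combined_tiebreak=ra_tiebreak + rm_tiebreak,
    )
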