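"""Rank species under the three prioritisation methods.

* ``ra`` — overall risk (3 high ... 1 low), ties by the geometric mean of
  the four RA component scores;
* ``rm`` — overall feasibility of eradication (5 ... 1), ties by the
  geometric mean of five RM component scores;
* ``ra+rm`` — the sum of the two overall scores (8 ... 2), ties by the sum
  of the two geometric means.

Residual ties (identical primary and tie-break keys) break alphabetically
by species name so that rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .data_io import SpeciesTable
from .scoring import DEFAULT_COST_MIDPOINTS, cost_midpoint, derive_scores

__all__ = ["METHODS", "PrioritisedList", "prioritise", "top_k_cost", "matrix_label"]

METHODS = ("ra", "rm", "ra+rm")

_METHOD_ALIASES = {
    "ra": "ra",
    "rm": "rm",
    "ra+rm": "ra+rm",
    "ra_rm": "ra+rm",
    "rarm": "ra+rm",
}


def _canonical_method(method: str) -> str:
    try:
        return _METHOD_ALIASES[str(method).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown prioritisation method {method!r}; expected one of {METHODS}"
        ) from None


@dataclass(frozen=True)
class PrioritisedList:
    """Species in rank order under one method, with the sort keys used.

    ``keys`` maps each species name to ``(primary_key, tiebreak_key)``; the
    final residual tie-break is the name itself (ascending).
    """

    method: str
    ranked: tuple[str, ...]
    keys: Mapping[str, tuple[float, float]]

    def __len__(self) -> int:
        return len(self.ranked)


def prioritise(
    table: SpeciesTable,
    method: str,
    band_map: Mapping[int, float] = DEFAULT_COST_MIDPOINTS,
    invert_cost_in_tiebreak: bool = False,
) -> PrioritisedList:
    """Rank all species of ``table`` under one prioritisation method.

    Sorts descending on the method's primary key (overall risk, overall
    feasibility, or their sum), then descending on its tie-break key
    (geometric means compared at full floating precision), then ascending
    by name.
    """
    method = _canonical_method(method)
    keys: dict[str, tuple[float, float]] = {}
    for rec in table:
        derived = derive_scores(rec, band_map, invert_cost_in_tiebreak)
        if method == "ra":
            keys[rec.name] = (float(rec.ra_overall), derived.ra_tiebreak)
        elif method == "rm":
            keys[rec.name] = (float(rec.rm_overall), derived.rm_tiebreak)
        else:
            keys[rec.name] = (float(derived.combined), derived.combined_tiebreak)
    ranked = sorted(keys, key=lambda name: (-keys[name][0], -keys[name][1], name))
    return PrioritisedList(method=method, ranked=tuple(ranked), keys=keys)


def top_k_cost(
    ranked: PrioritisedList,
    table: SpeciesTable,
    k: int,
    band_map: Mapping[int, float] = DEFAULT_COST_MIDPOINTS,
) -> float:
    """Cumulative eradication cost (GBP) of the first ``k`` ranked species."""
    if not isinstance(k, int) or isinstance(k, bool) or k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if k > len(ranked.ranked):
        raise ValueError(f"k = {k} exceeds the {len(ranked.ranked)} ranked species")
    return float(
        sum(cost_midpoint(table.get(name).rm_cost, band_map) for name in ranked.ranked[:k])
    )


def matrix_label(
    ra_overall: int,
    rm_overall: int,
    matrix: Optional[Mapping[int, Mapping[int, str]]] = None,
) -> str:
    """Look up a display label for a (risk, feasibility) pair.

    Published summaries label the combined priority on a five-point VL-VH
    scale via a risk-by-feasibility matrix.  That matrix is not derivable
    from the numeric sum, so it must be supplied by the user as a nested
    mapping ``matrix[ra_overall][rm_overall] -> label``.  Ranking always
    uses the numeric sum; labels are presentation only.
    """
    if matrix is None:
        raise ValueError("priority label matrix not configured")
    if ra_overall not in (1, 2, 3):
        raise ValueError(f"ra_overall must be in 1..3, got {ra_overall!r}")
    if rm_overall not in (1, 2, 3, 4, 5):
        raise ValueError(f"rm_overall must be in 1..5, got {rm_overall!r}")
    try:
        return matrix[ra_overall][rm_overall]
    except KeyError:
        raise ValueError(
            f"priority label matrix has no entry for ({ra_overall}, {rm_overall})"
        ) from None
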