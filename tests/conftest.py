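"""Shared fixtures: handmade and randomly generated species tables."""

from __future__ import annotations

import numpy as np
import pytest

from priocost.data_io import SpeciesRecord, SpeciesTable


def make_record(name: str, **overrides) -> SpeciesRecord:
    """A valid record with mid-scale scores, selectively overridden."""
    fields = dict(
        ra_entry=3,
        ra_establishment=3,
        ra_spread=3,
        ra_impact=3,
        ra_overall=2,
        rm_effectiveness=3,
        rm_practicality=3,
        rm_cost=3,
        rm_impact=3,
        rm_acceptability=3,
        rm_reinvasion=3,
        rm_window=3,
        rm_overall=3,
    )
    fields.update(overrides)
    return SpeciesRecord(name=name, **fields)


def random_table(rng: np.random.Generator, n: int) -> SpeciesTable:
    """A table of n species with independently uniform ordinal scores."""
    records = []
    for i in range(n):
        records.append(
            SpeciesRecord(
                name=f"sp{i:02d}",
                ra_entry=int(rng.integers(1, 6)),
                ra_establishment=int(rng.integers(1, 6)),
                ra_spread=int(rng.integers(1, 6)),
                ra_impact=int(rng.integers(1, 6)),
                ra_overall=int(rng.integers(1, 4)),
                rm_effectiveness=int(rng.integers(1, 6)),
                rm_practicality=int(rng.integers(1, 6)),
                rm_cost=int(rng.integers(1, 6)),
                rm_impact=int(rng.integers(1, 6)),
                rm_acceptability=int(rng.integers(1, 6)),
                rm_reinvasion=int(rng.integers(1, 6)),
                rm_window=int(rng.integers(1, 6)),
                rm_overall=int(rng.integers(1, 6)),
            )
        )
    return SpeciesTable(records)


@pytest.fixture
def mid_table() -> SpeciesTable:
    """Three species with distinct overall scores and component profiles."""
    return SpeciesTable(
        [
            make_record("alpha", ra_overall=3, rm_overall=1, rm_cost=5),
            make_record("bravo", ra_overall=1, rm_overall=5, rm_cost=1),
            make_record("charlie", ra_overall=2, rm_overall=3, rm_cost=3),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
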