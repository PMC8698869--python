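"""Synthetic species score tables with the structure the analysis assumes.

The generator draws, per species, a latent (risk severity, manageability)
pair from a Gaussian copula with a configurable correlation.  Ordinal
component scores are the latent value plus independent Gaussian noise,
discretised to 1-5 by equal-probability thresholds; overall scores are
tercile/quintile summaries of the component means.  The RM cost band is
drawn from a configurable band distribution and pulled toward the band
implied by (lack of) manageability, so that a negative risk-manageability
correlation makes the riskiest species the most expensive to eradicate —
the structure under which feasibility-aware prioritisation pays off.

``table1_fixture`` reconstructs the published top-ten summary table of the
26-species Great Britain eradication study: species names, cost bands and
the printed overall labels.  Fields the table does not print are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .data_io import SpeciesRecord, SpeciesTable
from .scoring import DEFAULT_COST_MIDPOINTS

__all__ = [
    "SyntheticConfig",
    "generate_table",
    "Table1Entry",
    "Table1Fixture",
    "table1_fixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic score-table generator.

    ``rho_risk_feasibility`` is the Gaussian-copula correlation between the
    latent risk severity and latent manageability; the study system shows a
    clear negative association (high-risk species tend to be hard and
    costly to eradicate), hence the negative default.
    ``component_noise_sd`` is the sd of the independent noise added to the
    latent before discretising each component score.
    """

    n_species: int = 26
    rho_risk_feasibility: float = -0.6
    cost_band_probs: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    component_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not -1.0 <= self.rho_risk_feasibility <= 1.0:
            raise ValueError("rho_risk_feasibility must be in [-1, 1]")
        probs = np.asarray(self.cost_band_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("cost_band_probs must be 5 non-negative values summing to 1")
        if self.component_noise_sd < 0:
            raise ValueError("component_noise_sd must be non-negative")


def _discretise_5(latent: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Latent + noise -> 1..5 by equal-probability thresholds of the marginal."""
    noisy = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    scale = np.sqrt(1.0 + noise_sd**2)
    thresholds = norm.ppf([0.2, 0.4, 0.6, 0.8]) * scale
    return np.searchsorted(thresholds, noisy) + 1


def _bin_mean(means: np.ndarray, n_bins: int) -> np.ndarray:
    """Map component means (in [1,5]) to 1..n_bins by equal-width bins."""
    edges = np.linspace(1.0, 5.0, n_bins + 1)[1:-1]
    return np.searchsorted(edges, means, side="right") + 1


def generate_table(config: SyntheticConfig) -> SpeciesTable:
    """Generate a validated species table; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    rho = config.rho_risk_feasibility
    # Explicit Cholesky factorisation of the 2x2 copula correlation; exact
    # at rho = +/-1 where the covariance is singular.
    risk = rng.standard_normal(n)
    manageability = rho * risk + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)

    sd = config.component_noise_sd
    ra_components = {
        f: _discretise_5(risk, sd, rng)
        for f in ("ra_entry", "ra_establishment", "ra_spread", "ra_impact")
    }
    ra_mean = np.mean([ra_components[f] for f in ra_components], axis=0)
    ra_overall = _bin_mean(ra_mean, 3)

    rm_components = {
        f: _discretise_5(manageability, sd, rng)
        for f in (
            "rm_effectiveness",
            "rm_practicality",
            "rm_impact",
            "rm_acceptability",
            "rm_reinvasion",
            "rm_window",
        )
    }

    # Cost band: categorical draw, pulled toward the band implied by the
    # manageability tercile with strength |rho|.  Terciles map onto the ends
    # of the band scale (most manageable -> band 1, least -> band 5): in the
    # study system the easily eradicated species sit in the cheapest bands
    # while the intractable ones occupy the £5.5M-£55M bands, a spread of
    # nearly two orders of magnitude.
    base = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.cost_band_probs, float))
    man_tercile = np.searchsorted(norm.ppf([1 / 3, 2 / 3]), manageability) + 1
    target = 7 - 2 * man_tercile
    rm_cost = np.clip(
        np.floor(base + abs(rho) * (target - base) + 0.5).astype(int), 1, 5
    )

    rm_mean = np.mean(
        [
            rm_components["rm_effectiveness"],
            rm_components["rm_practicality"],
            6 - rm_cost,
            rm_components["rm_impact"],
            rm_components["rm_acceptability"],
        ],
        axis=0,
    )
    rm_overall = _bin_mean(rm_mean, 5)

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            SpeciesRecord(
                name=f"species_{i + 1:0{width}d}",
                ra_overall=int(ra_overall[i]),
                rm_cost=int(rm_cost[i]),
                rm_overall=int(rm_overall[i]),
                **{f: int(v[i]) for f, v in ra_components.items()},
                **{f: int(v[i]) for f, v in rm_components.items()},
            )
        )
    return SpeciesTable(
        records,
        provenance=(
            f"synthetic: n={n}, rho={rho}, noise_sd={sd}, seed={config.seed}"
        ),
    )


# ---------------------------------------------------------------------------
# Published top-ten summary table (partial reconstruction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Entry:
    """One printed row: species, cost band, and the printed overall labels.

    Labels are the printed ordinals (RA on L/M/H; RM and combined on
    VL/L/M/H/VH); ``None`` where the published row is blank.
    """

    name: str
    cost_band: int
    ra_rm_label: Optional[str]
    rm_label: Optional[str]
    ra_label: Optional[str]

    @property
    def cost_gbp(self) -> float:
        return float(DEFAULT_COST_MIDPOINTS[self.cost_band])


@dataclass(frozen=True)
class Table1Fixture:
    """The three published top-ten lists (RM, RA, RA+RM), in printed order."""

    rm_top10: tuple[Table1Entry, ...]
    ra_top10: tuple[Table1Entry, ...]
    ra_rm_top10: tuple[Table1Entry, ...]

    @property
    def species_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for block in (self.rm_top10, self.ra_top10, self.ra_rm_top10):
            for entry in block:
                seen.setdefault(entry.name, None)
        return tuple(seen)

    def block(self, method: str) -> tuple[Table1Entry, ...]:
        return {"rm": self.rm_top10, "ra": self.ra_top10, "ra+rm": self.ra_rm_top10}[
            method
        ]


def _rows(raw: list[tuple]) -> tuple[Table1Entry, ...]:
    return tuple(Table1Entry(*row) for row in raw)


def table1_fixture() -> Table1Fixture:
    """Partial reconstruction of the study's published top-ten table.

    Costs are stored as cost bands (the inverse of the default mid-point
    map applied to the printed per-species costs); component scores are not
    printed and so are absent from this fixture.
    """
    rm = [
        ("Tamias sibiricus", 1, "VH", "VH", "M"),
        ("Procyon lotor", 1, "VH", "VH", "M"),
        ("Corvus splendens", 1, "VH", "VH", "M"),
        ("Procambarus acutus", 2, "H", "VH", "L"),
        ("Threskiornis aethiopicus", 1, "VH", "VH", "M"),
        ("Lacerta bilineata", 3, "H", "VH", "L"),
        ("Nyctereutes procyonoides", 2, "H", "H", "M"),
        ("Sarracenia purpurea", 2, "H", "H", "M"),
        ("Orconectes limosus", 3, "H", "H", "M"),
        ("Vespa velutina", 3, None, None, None),
    ]
    ra = [
        ("Corbicula fluminalis", 4, "M", "L", "H"),
        ("Hemigrapsus sanguineus", 4, "L", "VL", "H"),
        ("Mnemiopsis leidyi", 5, "L", "VL", "H"),
        ("Lysichiton americanus", 5, "M", "L", "H"),
        ("Dreissena bugensis", 5, "L", "VL", "H"),
        ("Rapana venosa", 4, "M", "L", "H"),
        ("Procambarus clarkii", 4, "M", "L", "H"),
        ("Ichthyosaura alpestris", 4, "H", "M", "H"),
        ("Homarus americanus", 3, "M", "L", "M"),
        ("Vespa velutina", 3, "H", "M", "M"),
    ]
    ra_rm = [
        ("Procyon lotor", 1, "VH", "VH", "M"),
        ("Threskiornis aethiopicus", 1, "VH", "VH", "M"),
        ("Tamias sibiricus", 1, "VH", "VH", "M"),
        ("Corvus splendens", 1, "VH", "VH", "M"),
        ("Sarracenia purpurea", 2, "H", "H", "M"),
        ("Ichthyosaura alpestris", 4, "H", "M", "H"),
        ("Lacerta bilineata", 3, "H", "VH", "L"),
        ("Nyctereutes procyonoides", 2, "H", "H", "M"),
        ("Procambarus acutus", 2, "H", "VH", "L"),
        ("Orconectes limosus", 3, "H", "H", "M"),
    ]
    return Table1Fixture(rm_top10=_rows(rm), ra_top10=_rows(ra), ra_rm_top10=_rows(ra_rm))
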