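"""Species score tables: the tabular input of the prioritisation analysis.

A table holds one row per invasive alien species with its risk-assessment
(RA) component scores, overall risk, risk-management (RM) component scores
and overall feasibility of eradication, all on ordinal scales.  Scores may
be written as integers or as the ordinal labels used in published summary
tables (VL/L/M/H/VH on the five-point scales, L/M/H on the three-point
overall-risk scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SpeciesRecord",
    "SpeciesTable",
    "SchemaError",
    "ValidationError",
    "read_species_table",
    "write_species_table",
    "ORDINAL_RANGES",
    "SCORE_COLUMNS",
    "METADATA_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A field value violates the scoring schema."""


#: Inclusive (low, high) bounds for every ordinal score field.
ORDINAL_RANGES: Mapping[str, tuple[int, int]] = {
    "ra_entry": (1, 5),
    "ra_establishment": (1, 5),
    "ra_spread": (1, 5),
    "ra_impact": (1, 5),
    "ra_overall": (1, 3),
    "rm_effectiveness": (1, 5),
    "rm_practicality": (1, 5),
    "rm_cost": (1, 5),
    "rm_impact": (1, 5),
    "rm_acceptability": (1, 5),
    "rm_reinvasion": (1, 5),
    "rm_window": (1, 5),
    "rm_overall": (1, 5),
}

SCORE_COLUMNS: tuple[str, ...] = tuple(ORDINAL_RANGES)
METADATA_COLUMNS: tuple[str, ...] = ("status", "taxon_group", "environment")

_STATUS_VALUES = {"established", "horizon"}
_TAXON_VALUES = {"plant", "invertebrate", "vertebrate"}
_ENVIRONMENT_VALUES = {"marine", "freshwater", "terrestrial"}

# Ordinal label aliases, case-insensitive.  The three-point overall-risk
# scale reuses L/M/H with different numeric values, so it gets its own map.
_FIVE_POINT_LABELS = {"vl": 1, "l": 2, "m": 3, "h": 4, "vh": 5}
_THREE_POINT_LABELS = {"l": 1, "m": 2, "h": 3}


@dataclass(frozen=True)
class SpeciesRecord:
    """All ordinal scores for one species, plus optional descriptive metadata.

    RA components (entry, establishment, spread, impact) are scored 1-5,
    overall risk 1-3 (low-high).  RM components (effectiveness, practicality,
    cost, impact, acceptability, reinvasion, window) and the overall
    feasibility of eradication are scored 1-5.  The cost component is a cost
    band (1 = under £50k ... 5 = £10M+), not a feasibility judgement.
    """

    name: str
    ra_entry: int
    ra_establishment: int
    ra_spread: int
    ra_impact: int
    ra_overall: int
    rm_effectiveness: int
    rm_practicality: int
    rm_cost: int
    rm_impact: int
    rm_acceptability: int
    rm_reinvasion: int
    rm_window: int
    rm_overall: int
    status: Optional[str] = None
    taxon_group: Optional[str] = None
    environment: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.name, str) or not self.name.strip():
            raise ValidationError("species name must be a non-empty string")
        for fname, (lo, hi) in ORDINAL_RANGES.items():
            value = getattr(self, fname)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(
                    f"{self.name!r}: field {fname!r} must be an integer, got {value!r}"
                )
            if not lo <= value <= hi:
                raise ValidationError(
                    f"{self.name!r}: field {fname!r} = {value} outside range {lo}..{hi}"
                )
        for fname, allowed in (
            ("status", _STATUS_VALUES),
            ("taxon_group", _TAXON_VALUES),
            ("environment", _ENVIRONMENT_VALUES),
        ):
            value = getattr(self, fname)
            if value is not None and value not in allowed:
                raise ValidationError(
                    f"{self.name!r}: field {fname!r} = {value!r} not one of {sorted(allowed)}"
                )


@dataclass
class SpeciesTable:
    """An ordered, validated collection of species records."""

    records: Sequence[SpeciesRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if not self.records:
            raise ValidationError("a species table must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.name in seen:
                raise ValidationError(f"duplicate species name {rec.name!r}")
            seen.add(rec.name)
        self._by_name = {rec.name: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.records]

    def get(self, name: str) -> SpeciesRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["name", *METADATA_COLUMNS, *SCORE_COLUMNS]
        rows = [{c: getattr(rec, c) for c in cols} for rec in self.records]
        return pd.DataFrame(rows, columns=cols)


def _parse_ordinal(raw: object, fname: str, row_label: str) -> int:
    """Parse an integer or ordinal label into a score; range is checked later."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        raise ValidationError(f"row {row_label}: field {fname!r} is missing")
    text = str(raw).strip()
    if not text:
        raise ValidationError(f"row {row_label}: field {fname!r} is empty")
    try:
        return int(text)
    except ValueError:
        pass
    labels = _THREE_POINT_LABELS if fname == "ra_overall" else _FIVE_POINT_LABELS
    try:
        return labels[text.lower()]
    except KeyError:
        raise ValidationError(
            f"row {row_label}: field {fname!r} value {text!r} is neither an "
            f"integer nor one of {sorted(labels)}"
        ) from None


def _parse_metadata(raw: object) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip().lower()
    return text or None


def read_species_table(
    path: str | Path,
    strict: bool = True,
    column_map: Optional[Mapping[str, str]] = None,
) -> SpeciesTable:
    """Read and validate a species score table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns: ``name`` and the 13
        score columns (``ra_entry`` ... ``rm_overall``); the metadata columns
        ``status``, ``taxon_group``, ``environment`` are optional.
    strict
        When true, unrecognised columns raise :class:`SchemaError`; when
        false they are ignored.
    column_map
        Optional mapping from canonical column name to the name actually
        used in the file, for archives with different headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])

    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)

    required = ("name", *SCORE_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if strict:
        known = set(required) | set(METADATA_COLUMNS)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise SchemaError(f"unrecognised column(s): {', '.join(unknown)}")

    records: list[SpeciesRecord] = []
    for idx, row in df.iterrows():
        name = row["name"]
        if name is None or (isinstance(name, float) and pd.isna(name)) or not str(name).strip():
            raise ValidationError(f"row {idx + 2}: empty species name")
        name = str(name).strip()
        scores = {f: _parse_ordinal(row[f], f, f"{idx + 2} ({name})") for f in SCORE_COLUMNS}
        meta = {
            f: _parse_metadata(row[f]) if f in df.columns else None
            for f in METADATA_COLUMNS
        }
        records.append(SpeciesRecord(name=name, **scores, **meta))
    return SpeciesTable(records, provenance=str(path))


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    """Write a table as canonical numeric CSV (UTF-8, comma-separated).

    Round-trip stable: reading the written file yields records equal
    field-for-field to the originals.
    """
    if not isinstance(table, SpeciesTable):
        raise TypeError("write_species_table expects a SpeciesTable")
    df = table.to_dataframe()
    df.to_csv(path, index=False, encoding="utf-8")
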