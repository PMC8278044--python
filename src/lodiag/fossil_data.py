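"""Canonical data model and CSV I/O for fossil specimen, occurrence, stage and grouping tables.

All tables are plain UTF-8 comma-separated files with a mandatory header row.
Ages are in Ma (millions of years before present) as non-negative decimals;
``age_max_ma`` is always the *older* bound, following palaeontological
convention.

The specimen table is accepted in two layouts:

* **long** (canonical): one row per specimen-element, with columns
  ``specimen_id, taxon_name, taxon_rank, species_id, named, element_id``
  and an optional ``multiplicity`` column (defaulting to 1);
* **wide**: one row per specimen with one column per schema ``element_id``
  holding multiplicities (0 = absent).  Wide input is converted to the long
  representation on read.

Occurrence tables accept either canonical column names or the corresponding
Paleobiology Database (PBDB) download headers (``occurrence_no``,
``collection_no``, ``accepted_name``, ``accepted_rank``, ``abund_value``,
``max_ma``, ``min_ma``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SkeletalElement",
    "ElementSchema",
    "SpecimenRecord",
    "StageBin",
    "GroupAssignment",
    "ValidationError",
    "default_element_schema",
    "default_stage_table",
    "read_element_schema",
    "read_specimen_table",
    "read_occurrence_table",
    "read_stage_table",
    "read_grouping_table",
    "write_table",
    "specimens_to_frame",
    "occurrences_to_frame",
    "stages_to_frame",
    "groupings_to_frame",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SkeletalElement:
    """One entry of the element schema.

    Serial elements (teeth, vertebral series, phalanges ...) are collapsed to
    a single schema entry and flagged with ``is_series``.
    """

    element_id: str
    display_name: str
    region: str
    is_series: bool = False


class ElementSchema:
    """An ordered set of skeletal elements, each mapped to one skeletal region."""

    def __init__(self, elements: Sequence[SkeletalElement]):
        ids = [e.element_id for e in elements]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate element_id(s) in schema: {sorted(dup)}")
        self._elements = list(elements)
        self._by_id = {e.element_id: e for e in elements}

    def __len__(self) -> int:
        return len(self._elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    def __iter__(self):
        return iter(self._elements)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self._elements]

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self._elements:
            seen.setdefault(e.region, None)
        return list(seen)

    def region_of(self, element_id: str) -> str:
        return self._by_id[element_id].region

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": [e.element_id for e in self._elements],
                "display_name": [e.display_name for e in self._elements],
                "region": [e.region for e in self._elements],
                "is_series": [e.is_series for e in self._elements],
            }
        )


@dataclass
class SpecimenRecord:
    """One fossil specimen: its taxonomic assignment and preserved elements.

    ``elements`` maps element_id to a positive multiplicity; for
    presence/absence datasets every multiplicity is 1.  ``taxon_rank`` is
    ``"species"`` for material assigned to a (possibly unnamed) species and
    ``"higher"`` for indeterminate material identified only to a more
    inclusive taxon.
    """

    specimen_id: str
    taxon_name: str
    taxon_rank: str = "species"
    species_id: str | None = None
    named: bool = True
    elements: dict[str, int] = field(default_factory=dict)

    def validate(self, schema: ElementSchema) -> None:
        if self.taxon_rank not in ("species", "higher"):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: taxon_rank must be 'species' or "
                f"'higher', got {self.taxon_rank!r}"
            )
        if self.taxon_rank == "species" and not self.species_id:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: species-rank record lacks species_id"
            )
        if not self.elements:
            raise ValidationError(f"specimen {self.specimen_id!r} has no elements")
        unknown = sorted(set(self.elements) - set(schema.element_ids))
        if unknown:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: element_id(s) not in schema: {unknown}"
            )
        bad = sorted(e for e, m in self.elements.items() if int(m) < 1)
        if bad:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-positive multiplicity for {bad}"
            )


@dataclass(frozen=True)
class StageBin:
    """A geological stage with numeric bounds in Ma (``age_max_ma`` is older)."""

    stage_name: str
    age_max_ma: float
    age_min_ma: float

    def __post_init__(self):
        if not self.age_max_ma > self.age_min_ma >= 0:
            raise ValidationError(
                f"stage {self.stage_name!r}: need age_max_ma > age_min_ma >= 0"
            )

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.age_max_ma + self.age_min_ma)


@dataclass
class GroupAssignment:
    """Species-level grouping: subgroup, formations and stratigraphic range."""

    species_id: str
    subgroup: str
    formations: frozenset[str]
    age_max_ma: float
    age_min_ma: float

    def __post_init__(self):
        if not self.age_max_ma >= self.age_min_ma >= 0:
            raise ValidationError(
                f"species {self.species_id!r}: need age_max_ma >= age_min_ma >= 0"
            )


# ---------------------------------------------------------------------------
# packaged defaults


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("lodiag").joinpath("data", name)))


def default_element_schema() -> ElementSchema:
    """The packaged theropod-style element schema (editable CSV)."""
    return read_element_schema(_data_path("element_schema.csv"))


def default_stage_table() -> list[StageBin]:
    """Packaged Mesozoic stage bounds (ICS-style, replaceable)."""
    return read_stage_table(_data_path("mesozoic_stages.csv"))


# ---------------------------------------------------------------------------
# readers


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


_TRUE = {"true", "1", "yes", "t"}


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in _TRUE


def read_element_schema(path) -> ElementSchema:
    df = _read_csv(path)
    _require(df, ["element_id", "region"], path)
    elements = [
        SkeletalElement(
            element_id=row["element_id"],
            display_name=row.get("display_name", row["element_id"]) or row["element_id"],
            region=row["region"],
            is_series=_as_bool(row.get("is_series", False)),
        )
        for row in df.to_dict("records")
    ]
    return ElementSchema(elements)


def _require(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_specimen_table(path, schema: ElementSchema) -> list[SpecimenRecord]:
    """Read a specimen table (long or wide layout) and validate against *schema*.

    Raises :class:`ValidationError` listing every offending row for unknown
    element ids, and on duplicate (specimen_id, element_id) pairs in long
    layout.
    """
    df = _read_csv(path)
    if "element_id" in df.columns:
        return _specimens_from_long(df, schema, path)
    wide_cols = [c for c in df.columns if c in schema]
    if not wide_cols:
        raise ValidationError(
            f"{path}: neither an 'element_id' column (long layout) nor any "
            "schema element column (wide layout) found"
        )
    return _specimens_from_wide(df, schema, wide_cols, path)


def _specimen_meta(row: Mapping[str, str]) -> dict:
    rank = row.get("taxon_rank", "") or "species"
    species_id = row.get("species_id", "") or None
    if species_id is None and rank == "species":
        species_id = row.get("taxon_name") or None
    return {
        "taxon_name": row.get("taxon_name", "") or (species_id or ""),
        "taxon_rank": rank,
        "species_id": species_id if rank == "species" else None,
        "named": _as_bool(row.get("named", True)) if row.get("named", "") != "" else True,
    }


def _specimens_from_long(df, schema, path) -> list[SpecimenRecord]:
    _require(df, ["specimen_id", "element_id"], path)
    bad_rows = [
        f"row {i + 2}: element_id {row['element_id']!r}"
        for i, row in enumerate(df.to_dict("records"))
        if row["element_id"] not in schema
    ]
    if bad_rows:
        raise ValidationError(
            f"{path}: element_id(s) not in schema:\n  " + "\n  ".join(bad_rows)
        )
    dup = df.duplicated(subset=["specimen_id", "element_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["specimen_id", "element_id"]].drop_duplicates()
        raise ValidationError(
            f"{path}: duplicate (specimen_id, element_id) pairs: "
            + "; ".join(f"({a}, {b})" for a, b in pairs.itertuples(index=False))
        )
    records: dict[str, SpecimenRecord] = {}
    for row in df.to_dict("records"):
        sid = row["specimen_id"]
        rec = records.get(sid)
        if rec is None:
            rec = SpecimenRecord(specimen_id=sid, elements={}, **_specimen_meta(row))
            records[sid] = rec
        mult = row.get("multiplicity", "")
        rec.elements[row["element_id"]] = int(mult) if str(mult).strip() else 1
    out = list(records.values())
    for rec in out:
        rec.validate(schema)
    return out


def _specimens_from_wide(df, schema, wide_cols, path) -> list[SpecimenRecord]:
    _require(df, ["specimen_id"], path)
    out = []
    for row in df.to_dict("records"):
        elements = {}
        for c in wide_cols:
            v = str(row[c]).strip()
            mult = int(float(v)) if v else 0
            if mult > 0:
                elements[c] = mult
        rec = SpecimenRecord(
            specimen_id=row["specimen_id"], elements=elements, **_specimen_meta(row)
        )
        rec.validate(schema)
        out.append(rec)
    return out


_PBDB_ALIASES = {
    "occurrence_no": "occurrence_id",
    "collection_no": "collection_id",
    "accepted_name": "taxon_name",
    "identified_name": "taxon_name",
    "accepted_rank": "taxon_rank",
    "identified_rank": "taxon_rank",
    "abund_value": "n_individuals",
    "max_ma": "age_max_ma",
    "min_ma": "age_min_ma",
}

_SPECIES_RANKS = {"species", "subspecies"}


def read_occurrence_table(path) -> pd.DataFrame:
    """Read an occurrence table (canonical or PBDB-download column names).

    Returns a DataFrame with canonical columns: occurrence_id, collection_id,
    taxon_name, taxon_rank ('species'/'higher'), n_individuals (int, missing
    values treated as 1), formation, age_max_ma, age_min_ma.
    """
    df = _read_csv(path)
    df = df.rename(columns={k: v for k, v in _PBDB_ALIASES.items() if k in df.columns})
    _require(df, ["occurrence_id", "collection_id", "taxon_name", "age_max_ma", "age_min_ma"], path)
    out = pd.DataFrame(
        {
            "occurrence_id": df["occurrence_id"].astype(str),
            "collection_id": df["collection_id"].astype(str),
            "taxon_name": df["taxon_name"].astype(str),
        }
    )
    rank = df["taxon_rank"] if "taxon_rank" in df.columns else pd.Series("species", index=df.index)
    out["taxon_rank"] = [
        "species" if str(r).strip().lower() in _SPECIES_RANKS or str(r).strip() == "species" else "higher"
        for r in rank
    ]
    n_ind = df["n_individuals"] if "n_individuals" in df.columns else pd.Series("", index=df.index)
    out["n_individuals"] = [
        int(float(v)) if str(v).strip() else 1 for v in n_ind
    ]
    if (out["n_individuals"] < 1).any():
        bad = out.loc[out["n_individuals"] < 1, "occurrence_id"].tolist()
        raise ValidationError(f"{path}: non-positive n_individuals for occurrence(s) {bad}")
    out["formation"] = df["formation"] if "formation" in df.columns else ""
    out["age_max_ma"] = df["age_max_ma"].astype(float)
    out["age_min_ma"] = df["age_min_ma"].astype(float)
    bad = out[(out["age_max_ma"] < out["age_min_ma"]) | (out["age_min_ma"] < 0)]
    if len(bad):
        raise ValidationError(
            f"{path}: age bounds violate age_max_ma >= age_min_ma >= 0 for "
            f"occurrence(s) {bad['occurrence_id'].tolist()}"
        )
    return out


def read_stage_table(path) -> list[StageBin]:
    """Read stage bins and check that they are non-overlapping and ordered."""
    df = _read_csv(path)
    _require(df, ["stage_name", "age_max_ma", "age_min_ma"], path)
    stages = [
        StageBin(row["stage_name"], float(row["age_max_ma"]), float(row["age_min_ma"]))
        for row in df.to_dict("records")
    ]
    ordered = sorted(stages, key=lambda s: s.age_max_ma, reverse=True)
    for older, younger in zip(ordered, ordered[1:]):
        if younger.age_max_ma > older.age_min_ma:
            raise ValidationError(
                f"stages {older.stage_name!r} and {younger.stage_name!r} overlap"
            )
    return ordered


def read_grouping_table(path) -> list[GroupAssignment]:
    """Read species -> subgroup / formations / age-range assignments.

    The ``formations`` column holds a semicolon-separated set of formation
    names (a species can occur in several formations).
    """
    df = _read_csv(path)
    _require(df, ["species_id", "subgroup", "age_max_ma", "age_min_ma"], path)
    out = []
    for row in df.to_dict("records"):
        fm = row.get("formations", "") or ""
        formations = frozenset(f.strip() for f in fm.split(";") if f.strip())
        out.append(
            GroupAssignment(
                species_id=row["species_id"],
                subgroup=row["subgroup"],
                formations=formations,
                age_max_ma=float(row["age_max_ma"]),
                age_min_ma=float(row["age_min_ma"]),
            )
        )
    seen: set[str] = set()
    dup = sorted({g.species_id for g in out if g.species_id in seen or seen.add(g.species_id)})
    if dup:
        raise ValidationError(f"{path}: duplicate species_id(s) in grouping table: {dup}")
    return out


# ---------------------------------------------------------------------------
# writers (round-trip safe)


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for element_id, mult in rec.elements.items():
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "taxon_name": rec.taxon_name,
                    "taxon_rank": rec.taxon_rank,
                    "species_id": rec.species_id or "",
                    "named": rec.named,
                    "element_id": element_id,
                    "multiplicity": mult,
                }
            )
    cols = ["specimen_id", "taxon_name", "taxon_rank", "species_id", "named", "element_id", "multiplicity"]
    return pd.DataFrame(rows, columns=cols)


def occurrences_to_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.copy()


def stages_to_frame(stages: Iterable[StageBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage_name": [s.stage_name for s in stages],
            "age_max_ma": [s.age_max_ma for s in stages],
            "age_min_ma": [s.age_min_ma for s in stages],
        }
    )


def groupings_to_frame(groups: Iterable[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": [g.species_id for g in groups],
            "subgroup": [g.subgroup for g in groups],
            "formations": [";".join(sorted(g.formations)) for g in groups],
            "age_max_ma": [g.age_max_ma for g in groups],
            "age_min_ma": [g.age_min_ma for g in groups],
        }
    )


def write_table(records, path) -> None:
    """Write any canonical collection back to CSV (round-trip safe).

    Accepts a list of SpecimenRecord / StageBin / GroupAssignment, an
    occurrence DataFrame, an ElementSchema, or any plain DataFrame.
    """
    path = Path(path)
    if isinstance(records, ElementSchema):
        df = records.to_frame()
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and isinstance(records[0], SpecimenRecord):
            df = specimens_to_frame(records)
        elif records and isinstance(records[0], StageBin):
            df = stages_to_frame(records)
        elif records and isinstance(records[0], GroupAssignment):
            df = groupings_to_frame(records)
        elif not records:
            df = pd.DataFrame(columns=["specimen_id", "taxon_name", "taxon_rank",
                                       "species_id", "named", "element_id", "multiplicity"])
        else:
            raise TypeError(f"cannot serialize collection of {type(records[0]).__name__}")
    df.to_csv(path, index=False)
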