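"""Per-element diagnostic character weights from published-style taxonomic diagnoses.

Each species diagnosis is a list of characters.  A character either stands
alone as a full autapomorphy, or belongs to a *unique combination* — a set of
characters whose joint presence distinguishes the species.  A whole
combination is treated as equivalent to one autapomorphy, so each of its k
members carries weight 1/k (a four-character combination gives each member
25% of an autapomorphy).

Two classes of characters are excluded before weighting:

* diagnoses published in 1980 or earlier (autapomorphies were generally not
  explicit in diagnoses before then) — the species is flagged as having no
  quantifiable diagnosis;
* characters that cannot be assigned to a single skeletal element: entire
  body partitions (e.g. overall skull length), integument, fenestrae bounded
  by several elements, and associations/ratios between multiple elements.

Plesiomorphic, synapomorphic and differential statements are expected to be
absent from input tables: curators pre-filter them at data entry, and no
reserved ``kind`` value exists for them.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .fossil_data import ValidationError, _read_csv, _require

__all__ = [
    "EXCLUDED_TARGETS",
    "DiagnosisCharacter",
    "SpeciesDiagnosis",
    "CharacterWeightMap",
    "ExclusionReport",
    "apply_exclusion_filters",
    "character_weights",
    "read_diagnosis_table",
    "POST_YEAR_THRESHOLD",
]

#: category tags for characters that cannot be pinned to a single element
EXCLUDED_TARGETS = frozenset(
    {"body_partition", "integument", "multi_element_fenestra", "multi_element_association"}
)

#: diagnoses must post-date 1980, i.e. publication_year >= 1981
POST_YEAR_THRESHOLD = 1981


@dataclass(frozen=True)
class DiagnosisCharacter:
    """One diagnostic character: a standalone autapomorphy or a combination member."""

    species_id: str
    target: str  # element_id, or one of EXCLUDED_TARGETS
    kind: str = "standalone"  # standalone | combination_member
    combination_id: str | None = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in ("standalone", "combination_member"):
            raise ValidationError(f"unknown character kind {self.kind!r}")
        if self.kind == "combination_member" and not self.combination_id:
            raise ValidationError(
                f"combination_member character for {self.species_id!r} lacks combination_id"
            )


@dataclass
class SpeciesDiagnosis:
    """A species' formal diagnosis: publication year plus its characters."""

    species_id: str
    publication_year: int
    characters: list[DiagnosisCharacter] = field(default_factory=list)
    #: original member count per combination_id, recorded by the exclusion
    #: filter before any member is dropped (the weighting denominator).
    original_combination_sizes: dict[str, int] = field(default_factory=dict)
    quantifiable: bool = True

    def __post_init__(self):
        if self.publication_year <= 0:
            raise ValidationError(
                f"{self.species_id!r}: publication_year must be positive"
            )
        combos = defaultdict(set)
        for ch in self.characters:
            if ch.combination_id:
                combos[ch.combination_id].add(ch.species_id)
        for cid, owners in combos.items():
            if len(owners) > 1:
                raise ValidationError(
                    f"combination {cid!r} spans multiple species: {sorted(owners)}"
                )


@dataclass
class ExclusionReport:
    """Every removal performed by the exclusion filter, with its rule."""

    species_id: str
    no_quantifiable_diagnosis: bool = False
    removals: list[tuple[DiagnosisCharacter, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.removals)


@dataclass
class CharacterWeightMap:
    """Per-element character weight (Ch) for one species."""

    species_id: str
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.weights.values())


def apply_exclusion_filters(
    diag: SpeciesDiagnosis, year_threshold: int = POST_YEAR_THRESHOLD
) -> tuple[SpeciesDiagnosis, ExclusionReport]:
    """Apply the pre-1981 and unassignable-target exclusion rules.

    Returns a new, filtered :class:`SpeciesDiagnosis` (the input is not
    modified) together with an :class:`ExclusionReport` listing every removed
    character and the rule that removed it.  Filtering is idempotent: the
    recorded pre-exclusion combination sizes are preserved on refiltering.
    """
    report = ExclusionReport(species_id=diag.species_id)

    # denominator k = combination size before exclusion; reuse sizes recorded
    # by an earlier filter pass so filtering twice equals filtering once
    sizes = dict(diag.original_combination_sizes) or dict(
        Counter(ch.combination_id for ch in diag.characters if ch.combination_id)
    )

    if diag.publication_year < year_threshold:
        report.no_quantifiable_diagnosis = True
        for ch in diag.characters:
            report.removals.append((ch, f"pre-{year_threshold} diagnosis"))
        return (
            SpeciesDiagnosis(
                species_id=diag.species_id,
                publication_year=diag.publication_year,
                characters=[],
                original_combination_sizes=sizes,
                quantifiable=False,
            ),
            report,
        )

    kept = []
    for ch in diag.characters:
        if ch.target in EXCLUDED_TARGETS:
            report.removals.append((ch, f"unassignable target ({ch.target})"))
        else:
            kept.append(ch)
    return (
        SpeciesDiagnosis(
            species_id=diag.species_id,
            publication_year=diag.publication_year,
            characters=kept,
            original_combination_sizes=sizes,
            quantifiable=True,
        ),
        report,
    )


def character_weights(
    diag: SpeciesDiagnosis, combination_denominator: str = "pre_exclusion"
) -> CharacterWeightMap:
    """Aggregate a filtered diagnosis into per-element weights Ch.

    Each standalone character adds 1 to its element.  Each member of a
    k-character combination adds 1/k.  With the default
    ``combination_denominator="pre_exclusion"``, k is the combination's
    size before exclusion filtering and excluded members' shares are dropped
    (not redistributed onto the survivors); ``"post_exclusion"`` instead uses
    the surviving member count, so a partially excluded combination still
    contributes exactly 1 in total.
    """
    if combination_denominator not in ("pre_exclusion", "post_exclusion"):
        raise ValueError(f"unknown combination_denominator {combination_denominator!r}")
    weights: dict[str, float] = {}
    post_sizes = Counter(
        ch.combination_id for ch in diag.characters if ch.combination_id
    )
    for ch in diag.characters:
        if ch.target in EXCLUDED_TARGETS:
            raise ValidationError(
                f"{diag.species_id!r}: run apply_exclusion_filters before weighting "
                f"(found excluded target {ch.target!r})"
            )
        if ch.kind == "standalone":
            share = 1.0
        else:
            if combination_denominator == "pre_exclusion":
                k = diag.original_combination_sizes.get(
                    ch.combination_id, post_sizes[ch.combination_id]
                )
            else:
                k = post_sizes[ch.combination_id]
            share = 1.0 / k
        weights[ch.target] = weights.get(ch.target, 0.0) + share
    return CharacterWeightMap(species_id=diag.species_id, weights=weights)


def read_diagnosis_table(path) -> dict[str, SpeciesDiagnosis]:
    """Read a diagnosis CSV into per-species diagnoses.

    Expected columns: species_id, publication_year, target, kind,
    combination_id, description.  A species with a publication year but no
    character rows is represented by a row with an empty ``target``.
    """
    df = _read_csv(path)
    _require(df, ["species_id", "publication_year", "target"], path)
    out: dict[str, SpeciesDiagnosis] = {}
    chars: dict[str, list[DiagnosisCharacter]] = defaultdict(list)
    years: dict[str, int] = {}
    for row in df.to_dict("records"):
        sid = row["species_id"]
        year = int(row["publication_year"])
        if sid in years and years[sid] != year:
            raise ValidationError(
                f"{path}: conflicting publication years for species {sid!r}"
            )
        years[sid] = year
        target = str(row.get("target", "")).strip()
        if not target:
            continue
        chars[sid].append(
            DiagnosisCharacter(
                species_id=sid,
                target=target,
                kind=(row.get("kind", "") or "standalone").strip(),
                combination_id=(row.get("combination_id", "") or None),
                description=row.get("description", ""),
            )
        )
    for sid, year in years.items():
        out[sid] = SpeciesDiagnosis(
            species_id=sid, publication_year=year, characters=chars.get(sid, [])
        )
    return out


def diagnoses_to_frame(diagnoses: Iterable[SpeciesDiagnosis]) -> pd.DataFrame:
    rows = []
    for diag in diagnoses:
        if not diag.characters:
            rows.append(
                {"species_id": diag.species_id, "publication_year": diag.publication_year,
                 "target": "", "kind": "", "combination_id": "", "description": ""}
            )
        for ch in diag.characters:
            rows.append(
                {
                    "species_id": diag.species_id,
                    "publication_year": diag.publication_year,
                    "target": ch.target,
                    "kind": ch.kind,
                    "combination_id": ch.combination_id or "",
                    "description": ch.description,
                }
            )
    cols = ["species_id", "publication_year", "target", "kind", "combination_id", "description"]
    return pd.DataFrame(rows, columns=cols)


def write_diagnosis_table(diagnoses: Iterable[SpeciesDiagnosis], path) -> None:
    diagnoses_to_frame(diagnoses).to_csv(Path(path), index=False)
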