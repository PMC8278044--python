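"""The Likelihood of Diagnosis (LoD) score and its group- and region-level summaries.

For one species, LoD = sum over skeletal elements of Ch_e * PP_e, where Ch_e
is the diagnostic character weight assigned to element e and PP_e the
element's global preservation potential.  A species scores high when many
unique characters sit on commonly preserved bones.

Group summaries average log(LoD) over constituent species (logging first, so
means are not skewed by outliers); species with LoD = 0 or without a
quantifiable diagnosis are excluded from the mean and reported.  Region
summaries give, per skeletal region, the relative percentage of element
occurrences and of pooled character weight — the numbers behind radial
plots — plus the fraction of schema elements carrying any character
("skeletal coverage").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .diagnosis import CharacterWeightMap
from .fossil_data import ElementSchema, SpecimenRecord, ValidationError
from .preservation import PreservationTable, count_element_occurrences

__all__ = [
    "LoDScore",
    "GroupLoD",
    "RegionSummary",
    "compute_lod",
    "group_mean_log_lod",
    "region_summary",
    "lod_table",
]


@dataclass
class LoDScore:
    species_id: str
    lod: float
    n_characters_included: float
    quantifiable: bool = True


@dataclass
class GroupLoD:
    group_id: str
    mean_log_lod: float | None
    n_species_used: int
    n_species_excluded: int


@dataclass
class RegionSummary:
    group_id: str
    pct_occurrences: dict[str, float]
    pct_characters: dict[str, float]
    coverage: float
    defined: bool = True


def compute_lod(weights: CharacterWeightMap, pp: PreservationTable) -> LoDScore:
    """LoD = sum_e Ch_e * PP_e over the elements carrying character weight."""
    missing = sorted(set(weights.weights) - set(pp.pp))
    if missing:
        raise ValidationError(
            f"species {weights.species_id!r}: weight on element(s) absent from the "
            f"preservation table: {missing}"
        )
    lod = sum(w * pp.pp[e] for e, w in weights.weights.items())
    return LoDScore(
        species_id=weights.species_id,
        lod=lod,
        n_characters_included=weights.total,
    )


def group_mean_log_lod(
    group_id: str, scores: Iterable[LoDScore], base: float = 10.0
) -> GroupLoD:
    """Mean of log_base(LoD) over usable species in one group.

    Usable means quantifiable and LoD > 0; other species are counted in
    ``n_species_excluded``.  When no species is usable the mean is ``None``
    (flagged, never silently 0).
    """
    scores = list(scores)
    if not scores:
        raise ValidationError(f"group {group_id!r} is empty")
    usable = [s for s in scores if s.quantifiable and s.lod > 0]
    excluded = len(scores) - len(usable)
    if not usable:
        return GroupLoD(group_id, None, 0, excluded)
    log_base = math.log(base)
    mean = sum(math.log(s.lod) / log_base for s in usable) / len(usable)
    return GroupLoD(group_id, mean, len(usable), excluded)


def region_summary(
    group_id: str,
    specimens: Iterable[SpecimenRecord],
    weight_maps: Iterable[CharacterWeightMap],
    schema: ElementSchema,
    coverage_denominator: str = "schema",
) -> RegionSummary:
    """Relative percentage of element occurrences and character weight per region.

    ``coverage`` is the fraction of elements with pooled character weight > 0;
    by default the denominator is all schema elements (skeletal coverage),
    with ``coverage_denominator="observed"`` restricting it to elements
    observed in the group's specimens.
    """
    counts = count_element_occurrences(specimens, schema=schema)
    pooled: dict[str, float] = {e: 0.0 for e in schema.element_ids}
    for wm in weight_maps:
        for e, w in wm.weights.items():
            if e not in pooled:
                raise ValidationError(
                    f"weight map for {wm.species_id!r} references unknown element {e!r}"
                )
            pooled[e] += w

    occ_by_region: dict[str, float] = {r: 0.0 for r in schema.regions}
    chr_by_region: dict[str, float] = {r: 0.0 for r in schema.regions}
    for e in schema.element_ids:
        region = schema.region_of(e)
        occ_by_region[region] += counts.get(e, 0)
        chr_by_region[region] += pooled[e]

    total_occ = sum(occ_by_region.values())
    total_chr = sum(chr_by_region.values())
    defined = total_occ > 0
    pct_occ = (
        {r: 100.0 * v / total_occ for r, v in occ_by_region.items()}
        if total_occ > 0
        else {r: float("nan") for r in occ_by_region}
    )
    pct_chr = (
        {r: 100.0 * v / total_chr for r, v in chr_by_region.items()}
        if total_chr > 0
        else {r: float("nan") for r in chr_by_region}
    )
    if coverage_denominator == "observed":
        denom = [e for e, c in counts.items() if c > 0]
    else:
        denom = schema.element_ids
    coverage = (
        sum(1 for e in denom if pooled.get(e, 0) > 0) / len(denom) if denom else 0.0
    )
    return RegionSummary(group_id, pct_occ, pct_chr, coverage, defined=defined)


def lod_table(scores: Iterable[LoDScore]) -> pd.DataFrame:
    """Species LoD scores as a tidy frame (one row per species)."""
    scores = list(scores)
    return pd.DataFrame(
        {
            "species_id": [s.species_id for s in scores],
            "lod": [s.lod for s in scores],
            "n_characters_included": [s.n_characters_included for s in scores],
            "quantifiable": [s.quantifiable for s in scores],
        }
    )


def region_summary_table(summaries: Iterable[RegionSummary]) -> pd.DataFrame:
    """Long-format region summary (group_id, region, pct_occ, pct_chars) for radial plots."""
    rows = []
    for s in summaries:
        for region in s.pct_occurrences:
            rows.append(
                {
                    "group_id": s.group_id,
                    "region": region,
                    "pct_occurrences": s.pct_occurrences[region],
                    "pct_characters": s.pct_characters[region],
                    "coverage": s.coverage,
                }
            )
    return pd.DataFrame(rows, columns=["group_id", "region", "pct_occurrences", "pct_characters", "coverage"])
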