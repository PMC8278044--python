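"""Abundance proxies: minimum number of individuals (MNI) and PBDB-style tallies.

MNI follows the classical zooarchaeological rule: the smallest number of
individuals that can account for the recovered elements, driven by the most
duplicated element.  Within-specimen multiplicity is honoured when recorded
(a bonebed specimen with five femora implies five individuals); otherwise
each specimen contributes presence (= 1) per element.

Group-level summaries sum species MNIs (including species lacking a
quantifiable diagnosis) plus the MNI of indeterminate material, and tally
occurrence-based proxies — occurrences, individuals, unique localities
(collections) and derived ratios — over all occurrence records assigned to
the group, higher-rank records included.  Species richness counts valid
species only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fossil_data import SpecimenRecord

__all__ = ["AbundanceSummary", "compute_mni", "species_pbdb_proxies", "group_abundance"]


@dataclass
class AbundanceSummary:
    """Abundance proxies for one unit (a species or a group of species)."""

    unit_id: str
    mni: int = 0
    pbdb_occurrences: int = 0
    pbdb_individuals: int = 0
    pbdb_localities: int = 0
    pbdb_species_richness: int = 0
    species_richness: int = 0  # valid-species count; groups only
    ratios: dict[str, float] = field(default_factory=dict)

    def compute_ratios(self) -> None:
        """Fill ratio proxies; a ratio with zero denominator is NaN (flagged, not 0)."""

        def ratio(num: float, den: float) -> float:
            return num / den if den else math.nan

        self.ratios = {
            "mni_per_species": ratio(self.mni, self.species_richness),
            "individuals_per_locality": ratio(self.pbdb_individuals, self.pbdb_localities),
            "individuals_per_species": ratio(self.pbdb_individuals, self.pbdb_species_richness),
            "species_per_locality": ratio(self.pbdb_species_richness, self.pbdb_localities),
        }


def compute_mni(specimens: Iterable[SpecimenRecord]) -> int:
    """MNI = max over elements of the summed multiplicity across specimens.

    Returns 0 for an empty collection; always >= 1 when any specimen exists
    (every specimen preserves at least one element).
    """
    totals: dict[str, int] = {}
    for spec in specimens:
        for element_id, mult in spec.elements.items():
            totals[element_id] = totals.get(element_id, 0) + int(mult)
    return max(totals.values(), default=0)


def species_pbdb_proxies(species_id: str, occurrences: pd.DataFrame) -> AbundanceSummary:
    """Occurrence-based proxies for one species from its occurrence rows."""
    rows = occurrences[
        (occurrences["taxon_rank"] == "species")
        & (occurrences["taxon_name"] == species_id)
    ]
    out = AbundanceSummary(
        unit_id=species_id,
        pbdb_occurrences=len(rows),
        pbdb_individuals=int(rows["n_individuals"].sum()),
        pbdb_localities=rows["collection_id"].nunique(),
        pbdb_species_richness=1 if len(rows) else 0,
    )
    out.ratios["individuals_per_locality"] = (
        out.pbdb_individuals / out.pbdb_localities if out.pbdb_localities else math.nan
    )
    return out


def group_abundance(
    group_id: str,
    species_specimens: Mapping[str, Sequence[SpecimenRecord]],
    indeterminate_specimens: Sequence[SpecimenRecord] = (),
    occurrences: pd.DataFrame | None = None,
) -> AbundanceSummary:
    """Summed abundance proxies for one group.

    *species_specimens* maps each constituent valid species to its specimens
    (species lacking a diagnosis still count).  *indeterminate_specimens* are
    higher-rank records assigned to the group; each contributes its own MNI.
    *occurrences* holds every occurrence row assigned to the group, including
    higher-rank records, for the PBDB-style proxies.
    """
    summary = AbundanceSummary(unit_id=group_id)
    summary.species_richness = len(species_specimens)
    summary.mni = sum(compute_mni(specs) for specs in species_specimens.values())
    summary.mni += sum(compute_mni([spec]) for spec in indeterminate_specimens)
    if occurrences is not None and len(occurrences):
        summary.pbdb_occurrences = len(occurrences)
        summary.pbdb_individuals = int(occurrences["n_individuals"].sum())
        summary.pbdb_localities = occurrences["collection_id"].nunique()
        species_rows = occurrences[occurrences["taxon_rank"] == "species"]
        summary.pbdb_species_richness = species_rows["taxon_name"].nunique()
    summary.compute_ratios()
    return summary


def abundance_table(summaries: Iterable[AbundanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "unit_id": s.unit_id,
            "mni": s.mni,
            "species_richness": s.species_richness,
            "pbdb_occurrences": s.pbdb_occurrences,
            "pbdb_individuals": s.pbdb_individuals,
            "pbdb_localities": s.pbdb_localities,
            "pbdb_species_richness": s.pbdb_species_richness,
        }
        row.update(s.ratios)
        rows.append(row)
    return pd.DataFrame(rows)
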