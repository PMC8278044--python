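"""Global preservation potential of skeletal elements.

An element's preservation potential (PP) is the proportion of all recorded
skeletal-element occurrences contributed by that element, tallied across every
specimen in the dataset: a cheap, model-free proxy for how likely the element
is to be found.  Presence counts once per specimen; within-specimen
multiplicity does not inflate the tally (the underlying data are
presence/absence).  PP values sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .fossil_data import ElementSchema, SpecimenRecord, ValidationError

__all__ = [
    "PreservationTable",
    "count_element_occurrences",
    "compute_preservation_potential",
]


@dataclass
class PreservationTable:
    """Per-element global preservation potential; values sum to 1."""

    pp: dict[str, float]
    total_occurrences: int
    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, element_id: str) -> float:
        return self.pp[element_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"element_id": list(self.pp), "pp": list(self.pp.values())}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def read(cls, path) -> "PreservationTable":
        df = pd.read_csv(path)
        return cls(pp=dict(zip(df["element_id"], df["pp"].astype(float))),
                   total_occurrences=0)


def count_element_occurrences(
    specimens: Iterable[SpecimenRecord],
    schema: ElementSchema | None = None,
    include_indeterminate: bool = True,
) -> dict[str, int]:
    """Tally, for each element, the number of specimens preserving it.

    A specimen contributes at most 1 per element regardless of multiplicity.
    With *schema* given, elements never observed are retained with count 0.
    ``include_indeterminate=False`` restricts the tally to species-rank
    specimens.
    """
    counts: dict[str, int] = (
        {e: 0 for e in schema.element_ids} if schema is not None else {}
    )
    for spec in specimens:
        if not include_indeterminate and spec.taxon_rank != "species":
            continue
        for element_id in spec.elements:
            counts[element_id] = counts.get(element_id, 0) + 1
    return counts


def compute_preservation_potential(counts: Mapping[str, int]) -> PreservationTable:
    """Normalize occurrence counts into preservation potentials.

    PP_e = count_e / sum(counts).  Raises :class:`ValidationError` when all
    counts are zero (the proportions are undefined).
    """
    if any(c < 0 for c in counts.values()):
        raise ValidationError("element occurrence counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(
            "all element counts are zero; preservation potential is undefined"
        )
    pp = {e: c / total for e, c in counts.items()}
    return PreservationTable(pp=pp, total_occurrences=total, counts=dict(counts))
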