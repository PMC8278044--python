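"""Assignment of species to taxonomic subgroups, formations, and stage-level time bins.

Subgroup and formation modes partition (or, for species spanning several
formations, duplicate into) discrete bins from the grouping table.  Stage
mode assigns each species to every geological stage its stratigraphic range
could fall in: taxa with uncertain or multi-stage ranges are duplicated into
each candidate stage rather than forced into one.

Stage intervals are half-open ``[age_min_ma, age_max_ma)`` in Ma (older bound
exclusive), so a point age sitting exactly on a stage boundary falls in
exactly one stage — the older-starting one — while genuinely range-spanning
taxa are still duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .fossil_data import GroupAssignment, StageBin, ValidationError

__all__ = ["BinnedDataset", "assign_stage_bins", "bin_dataset"]


@dataclass
class BinnedDataset:
    """Species membership per bin for one grouping mode."""

    mode: str  # subgroup | formation | stage
    bins: dict[str, set[str]] = field(default_factory=dict)  # bin_id -> species_ids
    unassigned: list[str] = field(default_factory=list)
    #: bins in analysis order (stages oldest -> youngest; otherwise sorted)
    order: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin_id": b, "species_id": s}
            for b in self.order
            for s in sorted(self.bins[b])
        ]
        return pd.DataFrame(rows, columns=["bin_id", "species_id"])


def assign_stage_bins(
    age_max_ma: float, age_min_ma: float, stages: Sequence[StageBin]
) -> list[str]:
    """Every stage whose half-open interval intersects the [min, max] age range.

    A point age (min == max) is treated as a single instant and lands in the
    unique stage containing it under the half-open convention.  An age range
    outside all stages returns an empty list with a warning.
    """
    if age_max_ma < age_min_ma:
        raise ValidationError("age_max_ma must be >= age_min_ma")
    hits = []
    for stage in stages:
        # closed species range vs half-open [stage.age_min_ma, stage.age_max_ma)
        if age_max_ma >= stage.age_min_ma and age_min_ma < stage.age_max_ma:
            hits.append(stage.stage_name)
    if not hits:
        warnings.warn(
            f"age range [{age_min_ma}, {age_max_ma}] Ma falls outside all stages",
            stacklevel=2,
        )
    return hits


def bin_dataset(
    groupings: Iterable[GroupAssignment],
    stages: Sequence[StageBin] | None,
    mode: str,
    top_n_formations: int | None = None,
) -> BinnedDataset:
    """Bin species by subgroup, formation or stage.

    Subgroup mode partitions species; formation and stage modes may duplicate
    a species into several bins.  Formation mode can be restricted to the
    *top_n_formations* most species-rich formations (ties broken
    lexicographically by formation name).  Species lacking the assignment
    needed for the requested mode are listed in ``unassigned`` and excluded.
    Output is deterministic regardless of input order.
    """
    groupings = sorted(groupings, key=lambda g: g.species_id)
    out = BinnedDataset(mode=mode)
    if mode == "subgroup":
        for g in groupings:
            if not g.subgroup:
                out.unassigned.append(g.species_id)
                continue
            out.bins.setdefault(g.subgroup, set()).add(g.species_id)
        out.order = sorted(out.bins)
    elif mode == "formation":
        for g in groupings:
            if not g.formations:
                out.unassigned.append(g.species_id)
                continue
            for fm in sorted(g.formations):
                out.bins.setdefault(fm, set()).add(g.species_id)
        if top_n_formations is not None:
            ranked = sorted(out.bins, key=lambda fm: (-len(out.bins[fm]), fm))
            keep = set(ranked[:top_n_formations])
            out.bins = {fm: s for fm, s in out.bins.items() if fm in keep}
        out.order = sorted(out.bins)
    elif mode == "stage":
        if stages is None:
            raise ValidationError("stage mode requires a stage table")
        for g in groupings:
            hits = assign_stage_bins(g.age_max_ma, g.age_min_ma, stages)
            if not hits:
                out.unassigned.append(g.species_id)
                continue
            for stage_name in hits:
                out.bins.setdefault(stage_name, set()).add(g.species_id)
        # oldest -> youngest, as required by the AR(1) temporal ordering
        out.order = [
            s.stage_name
            for s in sorted(stages, key=lambda s: s.midpoint_ma, reverse=True)
            if s.stage_name in out.bins
        ]
    else:
        raise ValidationError(f"unknown binning mode {mode!r}")
    return out
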