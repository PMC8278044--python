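"""End-to-end orchestration: read -> filter -> PP -> Ch -> LoD -> abundance -> binning -> GLS.

The pipeline mirrors the full analysis workflow: compute every element's
global preservation potential from all specimens; convert each species'
diagnosis into per-element character weights (after exclusion filtering);
score species LoD; tally MNI and occurrence-based abundance proxies; bin
species by subgroup, formation and geological stage; and regress LoD against
each abundance proxy at every grouping level, with AR(1) errors for the
temporal series.

Species-level comparisons log-transform both LoD and the proxy.  Group-level
comparisons use the mean of logged LoD as the response (already on a log
scale) and log-transform only the proxy.

Indeterminate (higher-rank) material counts in the preservation-potential
tally and in group abundance: specimen records are resolved to subgroups by
taxon name, while formation- and stage-level indeterminate contributions are
tallied from higher-rank occurrence rows (specimen records carry no
spatio-temporal information).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import abundance as ab
from . import binning, diagnosis, lod_metric, preservation, regression
from .fossil_data import (
    ElementSchema,
    GroupAssignment,
    SpecimenRecord,
    StageBin,
    ValidationError,
    default_element_schema,
    read_element_schema,
    read_grouping_table,
    read_occurrence_table,
    read_specimen_table,
    read_stage_table,
)

__all__ = [
    "AnalysisInputs",
    "PipelineConfig",
    "SpeciesAnalysis",
    "species_analysis",
    "group_proxy_table",
    "default_taxonomic_comparisons",
    "default_spatiotemporal_comparisons",
    "run_full_analysis",
]


@dataclass
class AnalysisInputs:
    """The five validated input tables plus the element schema."""

    schema: ElementSchema
    specimens: list[SpecimenRecord]
    diagnoses: dict[str, diagnosis.SpeciesDiagnosis]
    occurrences: pd.DataFrame
    stages: list[StageBin]
    groupings: list[GroupAssignment]

    @classmethod
    def from_paths(
        cls,
        specimen_path,
        diagnosis_path,
        occurrence_path,
        stage_path,
        grouping_path,
        schema_path=None,
    ) -> "AnalysisInputs":
        schema = (
            read_element_schema(schema_path) if schema_path else default_element_schema()
        )
        return cls(
            schema=schema,
            specimens=read_specimen_table(specimen_path, schema),
            diagnoses=diagnosis.read_diagnosis_table(diagnosis_path),
            occurrences=read_occurrence_table(occurrence_path),
            stages=read_stage_table(stage_path),
            groupings=read_grouping_table(grouping_path),
        )

    @classmethod
    def from_bundle(cls, bundle) -> "AnalysisInputs":
        """Adopt an in-memory synthetic bundle without file round-trips."""
        return cls(
            schema=bundle.schema,
            specimens=bundle.specimens,
            diagnoses=bundle.diagnoses,
            occurrences=bundle.occurrences,
            stages=bundle.stages,
            groupings=bundle.groupings,
        )


@dataclass
class PipelineConfig:
    specimen_path: str
    diagnosis_path: str
    occurrence_path: str
    stage_path: str
    grouping_path: str
    output_dir: str
    schema_path: str | None = None
    log_base: float = 10.0
    year_threshold: int = diagnosis.POST_YEAR_THRESHOLD
    combination_denominator: str = "pre_exclusion"
    include_indeterminate_in_pp: bool = True
    coverage_denominator: str = "schema"
    top_n_formations: int = 5
    grouping_modes: tuple[str, ...] = ("subgroup", "formation", "stage")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        missing = [
            k for k in ("specimen_path", "diagnosis_path", "occurrence_path",
                        "stage_path", "grouping_path", "output_dir")
            if k not in raw
        ]
        if missing:
            raise ValidationError(f"config missing required key(s): {missing}")
        if "grouping_modes" in raw:
            raw["grouping_modes"] = tuple(raw["grouping_modes"])
        return cls(**raw)


@dataclass
class SpeciesAnalysis:
    """Species-level results: PP table, LoD scores and abundance proxies."""

    pp: preservation.PreservationTable
    weight_maps: dict[str, diagnosis.CharacterWeightMap]
    scores: dict[str, lod_metric.LoDScore]
    table: pd.DataFrame
    no_diagnosis: list[str]
    not_quantifiable: list[str]
    zero_lod: list[str]
    exclusion_reports: dict[str, diagnosis.ExclusionReport]


def _species_occurrence_proxies(occurrences: pd.DataFrame) -> pd.DataFrame:
    rows = occurrences[occurrences["taxon_rank"] == "species"]
    if not len(rows):
        return pd.DataFrame(
            columns=["pbdb_occurrences", "pbdb_individuals", "pbdb_localities"]
        )
    g = rows.groupby("taxon_name")
    return pd.DataFrame(
        {
            "pbdb_occurrences": g.size(),
            "pbdb_individuals": g["n_individuals"].sum(),
            "pbdb_localities": g["collection_id"].nunique(),
        }
    )


def species_analysis(
    inputs: AnalysisInputs,
    year_threshold: int = diagnosis.POST_YEAR_THRESHOLD,
    combination_denominator: str = "pre_exclusion",
    include_indeterminate_in_pp: bool = True,
) -> SpeciesAnalysis:
    """Compute PP, character weights, LoD and abundance proxies per species.

    Every species present in the specimen or diagnosis tables appears in the
    output table exactly once; species without a usable LoD are additionally
    listed in the no-diagnosis / not-quantifiable / zero-LoD reports.
    """
    counts = preservation.count_element_occurrences(
        inputs.specimens, schema=inputs.schema,
        include_indeterminate=include_indeterminate_in_pp,
    )
    pp = preservation.compute_preservation_potential(counts)

    by_species: dict[str, list[SpecimenRecord]] = {}
    for spec in inputs.specimens:
        if spec.taxon_rank == "species" and spec.species_id:
            by_species.setdefault(spec.species_id, []).append(spec)

    species_ids = sorted(set(by_species) | set(inputs.diagnoses))
    weight_maps: dict[str, diagnosis.CharacterWeightMap] = {}
    scores: dict[str, lod_metric.LoDScore] = {}
    reports: dict[str, diagnosis.ExclusionReport] = {}
    no_diagnosis, not_quantifiable, zero_lod = [], [], []

    for sid in species_ids:
        diag = inputs.diagnoses.get(sid)
        if diag is None:
            no_diagnosis.append(sid)
            scores[sid] = lod_metric.LoDScore(sid, 0.0, 0.0, quantifiable=False)
            continue
        filtered, report = diagnosis.apply_exclusion_filters(diag, year_threshold)
        reports[sid] = report
        wm = diagnosis.character_weights(filtered, combination_denominator)
        weight_maps[sid] = wm
        score = lod_metric.compute_lod(wm, pp)
        score.quantifiable = filtered.quantifiable and bool(filtered.characters)
        if not score.quantifiable:
            score.lod = 0.0
            not_quantifiable.append(sid)
        elif score.lod == 0:
            zero_lod.append(sid)
        scores[sid] = score

    proxies = _species_occurrence_proxies(inputs.occurrences)
    rows = []
    for sid in species_ids:
        s = scores[sid]
        mni = ab.compute_mni(by_species.get(sid, []))
        p = proxies.loc[sid] if sid in proxies.index else None
        occ = int(p["pbdb_occurrences"]) if p is not None else 0
        ind = int(p["pbdb_individuals"]) if p is not None else 0
        loc = int(p["pbdb_localities"]) if p is not None else 0
        rows.append(
            {
                "species_id": sid,
                "lod": s.lod,
                "quantifiable": s.quantifiable,
                "n_characters_included": s.n_characters_included,
                "mni": mni,
                "pbdb_occurrences": occ,
                "pbdb_individuals": ind,
                "pbdb_localities": loc,
                "individuals_per_locality": ind / loc if loc else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    return SpeciesAnalysis(
        pp=pp,
        weight_maps=weight_maps,
        scores=scores,
        table=table,
        no_diagnosis=no_diagnosis,
        not_quantifiable=not_quantifiable,
        zero_lod=zero_lod,
        exclusion_reports=reports,
    )


def _subgroup_of_taxon(taxon_name: str) -> str:
    """Resolve a higher-rank taxon label like 'subgroup_01 indet.' to its group."""
    return taxon_name.removesuffix(" indet.").removesuffix(" indet").strip()


def _occurrences_for_bin(
    occurrences: pd.DataFrame,
    mode: str,
    bin_id: str,
    species_in_bin: set[str],
    stages: Sequence[StageBin],
) -> pd.DataFrame:
    if mode == "subgroup":
        is_species = occurrences["taxon_rank"] == "species"
        keep = (is_species & occurrences["taxon_name"].isin(species_in_bin)) | (
            ~is_species
            & (occurrences["taxon_name"].map(_subgroup_of_taxon) == bin_id)
        )
    elif mode == "formation":
        keep = occurrences["formation"] == bin_id
    elif mode == "stage":
        stage = next(s for s in stages if s.stage_name == bin_id)
        keep = (occurrences["age_max_ma"] >= stage.age_min_ma) & (
            occurrences["age_min_ma"] < stage.age_max_ma
        )
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return occurrences[keep]


def group_proxy_table(
    inputs: AnalysisInputs,
    analysis: SpeciesAnalysis,
    mode: str,
    log_base: float = 10.0,
    top_n_formations: int | None = 5,
) -> pd.DataFrame:
    """One row per bin: mean logged LoD plus every abundance proxy.

    Bins are ordered for analysis (stages oldest to youngest, otherwise
    sorted by name), as required by the AR(1) temporal structure.
    """
    binned = binning.bin_dataset(
        inputs.groupings,
        inputs.stages,
        mode,
        top_n_formations=top_n_formations if mode == "formation" else None,
    )
    by_species: dict[str, list[SpecimenRecord]] = {}
    indet_specimens: list[SpecimenRecord] = []
    for spec in inputs.specimens:
        if spec.taxon_rank == "species" and spec.species_id:
            by_species.setdefault(spec.species_id, []).append(spec)
        else:
            indet_specimens.append(spec)

    rows = []
    for bin_id in binned.order:
        members = binned.bins[bin_id]
        scores = [analysis.scores[s] for s in sorted(members) if s in analysis.scores]
        glod = lod_metric.group_mean_log_lod(bin_id, scores, base=log_base)
        occ = _occurrences_for_bin(
            inputs.occurrences, mode, bin_id, members, inputs.stages
        )
        if mode == "subgroup":
            indet = [
                s for s in indet_specimens if _subgroup_of_taxon(s.taxon_name) == bin_id
            ]
            extra_mni = 0
        else:
            # spatio-temporal bins: indeterminate MNI from higher-rank occurrence rows
            indet = []
            extra_mni = int(occ.loc[occ["taxon_rank"] != "species", "n_individuals"].sum())
        summary = ab.group_abundance(
            bin_id,
            {s: by_species.get(s, []) for s in sorted(members)},
            indeterminate_specimens=indet,
            occurrences=occ,
        )
        summary.mni += extra_mni
        summary.compute_ratios()
        rows.append(
            {
                "bin_id": bin_id,
                "mean_log_lod": glod.mean_log_lod,
                "n_species_used": glod.n_species_used,
                "n_species_excluded": glod.n_species_excluded,
                "mni": summary.mni,
                "species_richness": summary.species_richness,
                "pbdb_occurrences": summary.pbdb_occurrences,
                "pbdb_individuals": summary.pbdb_individuals,
                "pbdb_localities": summary.pbdb_localities,
                "pbdb_species_richness": summary.pbdb_species_richness,
                **{k: v for k, v in summary.ratios.items()},
            }
        )
    return pd.DataFrame(rows)


_GROUP_PROXIES = [
    ("MNI", "mni"),
    ("species richness", "species_richness"),
    ("MNI per species", "mni_per_species"),
    ("PBDB individuals", "pbdb_individuals"),
    ("PBDB species richness", "pbdb_species_richness"),
    ("PBDB individuals per species", "individuals_per_species"),
    ("PBDB occurrences", "pbdb_occurrences"),
    ("PBDB individuals per locality", "individuals_per_locality"),
    ("PBDB species per locality", "species_per_locality"),
]

_SPECIES_PROXIES = [
    ("MNI", "mni"),
    ("PBDB individuals", "pbdb_individuals"),
    ("PBDB occurrences", "pbdb_occurrences"),
    ("PBDB individuals per locality", "individuals_per_locality"),
]


def default_taxonomic_comparisons() -> list[regression.ComparisonSpec]:
    """Species-level (4) plus subgroup-level (9) comparisons: 13 rows."""
    specs = [
        regression.ComparisonSpec(
            comparison_id=f"species LoD ~ {label}",
            table="species",
            response="lod",
            predictor=col,
            log_transform=True,
        )
        for label, col in _SPECIES_PROXIES
    ]
    specs += [
        regression.ComparisonSpec(
            comparison_id=f"subgroup LoD ~ {label}",
            table="subgroup",
            response="mean_log_lod",
            predictor=col,
            log_transform="x",  # the LoD side is already on a log scale
        )
        for label, col in _GROUP_PROXIES
    ]
    return specs


def default_spatiotemporal_comparisons() -> list[regression.ComparisonSpec]:
    """Formation-level (9) plus stage-level temporal (9, AR(1)) comparisons: 18 rows."""
    specs = [
        regression.ComparisonSpec(
            comparison_id=f"formation LoD ~ {label}",
            table="formation",
            response="mean_log_lod",
            predictor=col,
            log_transform="x",
        )
        for label, col in _GROUP_PROXIES
    ]
    specs += [
        regression.ComparisonSpec(
            comparison_id=f"time LoD ~ {label}",
            table="time",
            response="mean_log_lod",
            predictor=col,
            correlation="ar1",
            log_transform="x",
        )
        for label, col in _GROUP_PROXIES
    ]
    return specs


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute the whole workflow and write all result tables.

    Writes, under ``config.output_dir``: the PP table, species LoD table,
    per-mode group proxy tables, the subgroup region summary, the taxonomic
    and spatio-temporal regression tables, and a JSON run log recording every
    exclusion, drop and per-comparison error.  Identical inputs and config
    yield byte-identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = AnalysisInputs.from_paths(
        config.specimen_path,
        config.diagnosis_path,
        config.occurrence_path,
        config.stage_path,
        config.grouping_path,
        schema_path=config.schema_path,
    )
    analysis = species_analysis(
        inputs,
        year_threshold=config.year_threshold,
        combination_denominator=config.combination_denominator,
        include_indeterminate_in_pp=config.include_indeterminate_in_pp,
    )
    analysis.pp.write(outdir / "preservation_potential.csv")
    analysis.table.to_csv(outdir / "lod_species.csv", index=False)

    tables: dict[str, pd.DataFrame] = {"species": analysis.table}
    mode_to_table = {"subgroup": "subgroup", "formation": "formation", "stage": "time"}
    dropped_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for mode in config.grouping_modes:
            table = group_proxy_table(
                inputs,
                analysis,
                mode,
                log_base=config.log_base,
                top_n_formations=config.top_n_formations,
            )
            table.to_csv(outdir / f"abundance_{mode}.csv", index=False)
            tables[mode_to_table[mode]] = table

        # subgroup region summaries (radial-plot tables), plus a pooled row
        summaries = []
        if "subgroup" in config.grouping_modes:
            binned = binning.bin_dataset(inputs.groupings, inputs.stages, "subgroup")
            for bin_id in binned.order:
                members = binned.bins[bin_id]
                specs_in = [
                    s
                    for s in inputs.specimens
                    if (s.species_id in members)
                    or (s.taxon_rank == "higher" and _subgroup_of_taxon(s.taxon_name) == bin_id)
                ]
                wms = [analysis.weight_maps[m] for m in sorted(members) if m in analysis.weight_maps]
                summaries.append(
                    lod_metric.region_summary(
                        bin_id, specs_in, wms, inputs.schema,
                        coverage_denominator=config.coverage_denominator,
                    )
                )
            summaries.append(
                lod_metric.region_summary(
                    "all", inputs.specimens, analysis.weight_maps.values(), inputs.schema,
                    coverage_denominator=config.coverage_denominator,
                )
            )
            lod_metric.region_summary_table(summaries).to_csv(
                outdir / "region_summary.csv", index=False
            )

        taxonomic_specs = [
            s for s in default_taxonomic_comparisons() if s.table in tables
        ]
        spatiotemporal_specs = [
            s for s in default_spatiotemporal_comparisons() if s.table in tables
        ]
        tax_results, tax_errors = regression.run_comparisons(tables, taxonomic_specs)
        st_results, st_errors = regression.run_comparisons(tables, spatiotemporal_specs)
        dropped_warnings = [str(w.message) for w in caught]

    regression.results_table(tax_results).to_csv(
        outdir / "regressions_taxonomic.csv", index=False
    )
    regression.results_table(st_results).to_csv(
        outdir / "regressions_spatiotemporal.csv", index=False
    )

    run_log = {
        "seed": config.seed,
        "n_specimens": len(inputs.specimens),
        "n_species": int(analysis.table.shape[0]),
        "no_diagnosis": analysis.no_diagnosis,
        "not_quantifiable": analysis.not_quantifiable,
        "zero_lod": analysis.zero_lod,
        "n_characters_excluded": sum(
            len(r) for r in analysis.exclusion_reports.values()
        ),
        "comparison_errors": {**tax_errors, **st_errors},
        "warnings": dropped_warnings,
        "grouping_modes": list(config.grouping_modes),
        "log_base": config.log_base,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return {
        "inputs": inputs,
        "analysis": analysis,
        "tables": tables,
        "taxonomic": regression.results_table(tax_results),
        "spatiotemporal": regression.results_table(st_results),
        "errors": {**tax_errors, **st_errors},
        "run_log": run_log,
    }
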