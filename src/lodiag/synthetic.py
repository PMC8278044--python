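"""Synthetic fossil-record generator with known statistical structure.

Generates complete input bundles — specimen, diagnosis, occurrence, stage and
grouping tables — emulating a theropod-style fossil record, so the whole
pipeline is testable without any external download.  The world is explicit:

* each element has a true relative preservability; per-specimen element
  presence is Bernoulli with probability proportional to it, so the empirical
  preservation potential converges to the configured proportions;
* each species draws a Poisson number of diagnostic characters, placed on
  elements independently of preservability by default (optionally biased per
  region, or coupled to preservability); characters form unique combinations
  with a configurable probability and size range;
* species abundance is linked to diagnosability through the latent rate
  lambda = baseline * (LoD_true / LoD_ref)^beta * exp(noise), and the
  specimen count is Poisson(lambda).  ``coupling_beta`` is therefore directly
  the true slope of log-abundance on log-LoD; beta = 0 is a null world where
  abundance carries no signal of diagnosability.  Species drawing zero
  specimens are unobserved and appear in no table (the manifest still records
  them);
* every specimen yields one occurrence record (one individual at one locality
  in one formation); a configurable fraction of extra indeterminate,
  higher-rank specimens and occurrences is added per subgroup.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; a fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .diagnosis import DiagnosisCharacter, SpeciesDiagnosis, write_diagnosis_table
from .fossil_data import (
    ElementSchema,
    GroupAssignment,
    SpecimenRecord,
    StageBin,
    ValidationError,
    default_element_schema,
    default_stage_table,
    write_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "default_preservation_weights",
    "generate_dataset",
    "make_null_and_effect_suites",
]

#: true relative preservability for the packaged schema: hind limb, caudal
#: vertebrae and teeth commonest, delicate girdle/manus elements rarest
_DEFAULT_WEIGHTS = {
    "premaxilla": 1.0, "maxilla": 1.8, "nasal": 0.8, "lacrimal": 0.8,
    "jugal": 0.9, "postorbital": 0.9, "squamosal": 0.8, "quadrate": 0.9,
    "frontal": 1.2, "parietal": 1.0, "braincase": 1.2, "dentary": 1.8,
    "surangular": 0.9, "angular": 0.8, "teeth": 3.0,
    "cervical_vertebrae": 2.2, "dorsal_vertebrae": 2.4,
    "sacral_vertebrae": 1.6, "caudal_vertebrae": 3.2, "chevrons": 1.4,
    "ribs": 2.0, "gastralia": 0.6,
    "scapula": 1.6, "coracoid": 1.4, "furcula": 0.5, "sternum": 0.4,
    "humerus": 1.8, "radius": 1.2, "ulna": 1.3,
    "carpals": 0.5, "metacarpals": 1.0, "manual_phalanges": 1.2,
    "ilium": 1.6, "pubis": 1.5, "ischium": 1.5,
    "femur": 3.0, "tibia": 3.0, "fibula": 1.8, "astragalus": 1.2,
    "metatarsals": 2.8, "pedal_phalanges": 1.8,
}


def default_preservation_weights(schema: ElementSchema) -> dict[str, float]:
    """Packaged preservability weights, or uniform ones for a custom schema."""
    if all(e in _DEFAULT_WEIGHTS for e in schema.element_ids):
        return {e: _DEFAULT_WEIGHTS[e] for e in schema.element_ids}
    return {e: 1.0 for e in schema.element_ids}


@dataclass
class SimulationConfig:
    """Stated world for one synthetic fossil record.

    Defaults describe a moderately well-sampled record: ~60 species in four
    subgroups, about six individuals per species at the reference
    diagnosability, four diagnostic characters per species on average, a
    quarter of characters arriving inside 2-4-member unique combinations,
    and the commonest skeletal element present in 60% of specimens.
    """

    seed: int = 0
    n_species: int = 60
    n_subgroups: int = 4
    element_schema: ElementSchema | None = None
    preservation_weights: dict[str, float] | None = None
    character_rate: float = 4.0
    combination_prob: float = 0.25
    combination_size_range: tuple[int, int] = (2, 4)
    region_bias: dict[str, float] | None = None
    couple_placement_to_preservation: bool = False
    coupling_beta: float = 0.0
    abundance_dispersion: float = 0.5
    baseline_abundance: float = 6.0
    lod_reference: float = 0.1
    max_presence_prob: float = 0.6
    n_formations: int = 8
    stage_table: Sequence[StageBin] | None = None
    indeterminate_fraction: float = 0.10
    pre1981_fraction: float = 0.05
    species_age_span_ma: tuple[float, float] = (230.0, 70.0)
    species_duration_range_ma: tuple[float, float] = (2.0, 8.0)

    def resolved(self) -> "SimulationConfig":
        cfg = dataclasses.replace(self)
        if cfg.element_schema is None:
            cfg.element_schema = default_element_schema()
        if cfg.preservation_weights is None:
            cfg.preservation_weights = default_preservation_weights(cfg.element_schema)
        if cfg.stage_table is None:
            cfg.stage_table = default_stage_table()
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.element_schema) == 0:
            raise ValidationError("element schema is empty")
        if self.n_species < 0 or self.n_subgroups < 1 or self.n_formations < 1:
            raise ValidationError("n_species >= 0 and n_subgroups, n_formations >= 1 required")
        if self.character_rate <= 0 or self.baseline_abundance <= 0:
            raise ValidationError("rates must be positive")
        if not 0 <= self.combination_prob <= 1 or not 0 <= self.pre1981_fraction <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if not 0 < self.max_presence_prob <= 1:
            raise ValidationError("max_presence_prob must lie in (0, 1]")
        lo, hi = self.combination_size_range
        if lo < 2 or hi < lo:
            raise ValidationError("combination_size_range must satisfy 2 <= lo <= hi")
        missing = set(self.element_schema.element_ids) - set(self.preservation_weights)
        if missing:
            raise ValidationError(f"preservation_weights missing elements: {sorted(missing)}")
        if any(w <= 0 for w in self.preservation_weights.values()):
            raise ValidationError("preservation weights must be positive")


@dataclass
class SyntheticBundle:
    """One generated input bundle plus its ground truth."""

    schema: ElementSchema
    specimens: list[SpecimenRecord]
    diagnoses: dict[str, SpeciesDiagnosis]
    occurrences: pd.DataFrame
    stages: list[StageBin]
    groupings: list[GroupAssignment]
    truth: dict

    def write(self, outdir) -> None:
        """Emit the five CSV tables, the element schema and a truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.specimens, outdir / "specimens.csv")
        write_diagnosis_table(self.diagnoses.values(), outdir / "diagnoses.csv")
        write_table(self.occurrences, outdir / "occurrences.csv")
        write_table(list(self.stages), outdir / "stages.csv")
        write_table(self.groupings, outdir / "groupings.csv")
        write_table(self.schema, outdir / "element_schema.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _placement_probs(cfg: SimulationConfig) -> np.ndarray:
    schema = cfg.element_schema
    if cfg.couple_placement_to_preservation:
        raw = np.array([cfg.preservation_weights[e] for e in schema.element_ids])
    else:
        raw = np.ones(len(schema))
    if cfg.region_bias:
        raw = raw * np.array(
            [cfg.region_bias.get(schema.region_of(e), 1.0) for e in schema.element_ids]
        )
    return raw / raw.sum()


def _draw_characters(
    rng: np.random.Generator, cfg: SimulationConfig, species_id: str, probs: np.ndarray
) -> list[DiagnosisCharacter]:
    element_ids = cfg.element_schema.element_ids
    n_chars = int(rng.poisson(cfg.character_rate))
    chars: list[DiagnosisCharacter] = []
    lo, hi = cfg.combination_size_range
    remaining = n_chars
    combo_counter = 0
    while remaining > 0:
        if remaining >= lo and rng.random() < cfg.combination_prob:
            size = int(rng.integers(lo, min(hi, remaining) + 1))
            combo_counter += 1
            cid = f"{species_id}_c{combo_counter}"
            targets = rng.choice(len(element_ids), size=size, p=probs)
            for t in targets:
                chars.append(
                    DiagnosisCharacter(
                        species_id=species_id,
                        target=element_ids[int(t)],
                        kind="combination_member",
                        combination_id=cid,
                    )
                )
            remaining -= size
        else:
            t = int(rng.choice(len(element_ids), p=probs))
            chars.append(
                DiagnosisCharacter(species_id=species_id, target=element_ids[t])
            )
            remaining -= 1
    return chars


def _true_weights(chars: list[DiagnosisCharacter]) -> dict[str, float]:
    sizes: dict[str, int] = {}
    for ch in chars:
        if ch.combination_id:
            sizes[ch.combination_id] = sizes.get(ch.combination_id, 0) + 1
    weights: dict[str, float] = {}
    for ch in chars:
        share = 1.0 if ch.kind == "standalone" else 1.0 / sizes[ch.combination_id]
        weights[ch.target] = weights.get(ch.target, 0.0) + share
    return weights


def _draw_element_sets(
    rng: np.random.Generator, n: int, presence: np.ndarray
) -> np.ndarray:
    """n x n_elements boolean presence matrix; empty specimens are redrawn."""
    mat = rng.random((n, len(presence))) < presence
    for _ in range(100):
        empty = ~mat.any(axis=1)
        if not empty.any():
            break
        mat[empty] = rng.random((int(empty.sum()), len(presence))) < presence
    still = ~mat.any(axis=1)
    if still.any():  # pathological presence probs: force the commonest element
        mat[still, int(np.argmax(presence))] = True
    return mat


def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Generate one complete, schema-valid input bundle from *config*."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    schema = cfg.element_schema
    element_ids = schema.element_ids
    weights = np.array([cfg.preservation_weights[e] for e in element_ids], dtype=float)
    pp_true = weights / weights.sum()
    presence = weights / weights.max() * cfg.max_presence_prob
    placement = _placement_probs(cfg)

    subgroups = [f"subgroup_{i + 1:02d}" for i in range(cfg.n_subgroups)]
    formations = [f"formation_{i + 1:02d}" for i in range(cfg.n_formations)]
    old, young = cfg.species_age_span_ma

    specimens: list[SpecimenRecord] = []
    diagnoses: dict[str, SpeciesDiagnosis] = {}
    groupings: list[GroupAssignment] = []
    occ_rows: list[dict] = []
    truth_species: dict[str, dict] = {}
    occ_counter = 0

    for i in range(cfg.n_species):
        species_id = f"species_{i + 1:03d}"
        chars = _draw_characters(rng, cfg, species_id, placement)
        if rng.random() < cfg.pre1981_fraction:
            year = int(rng.integers(1950, 1981))
        else:
            year = int(rng.integers(1985, 2021))
        true_w = _true_weights(chars)
        true_lod = sum(
            w * pp_true[element_ids.index(e)] for e, w in true_w.items()
        )
        noise = rng.normal(0.0, cfg.abundance_dispersion)
        if true_lod > 0:
            lam = (
                cfg.baseline_abundance
                * (true_lod / cfg.lod_reference) ** cfg.coupling_beta
                * math.exp(noise)
            )
        else:
            lam = cfg.baseline_abundance * math.exp(noise)
        n_spec = int(rng.poisson(lam))

        subgroup = subgroups[int(rng.integers(cfg.n_subgroups))]
        fms = {formations[int(rng.integers(cfg.n_formations))]}
        if rng.random() < 0.2:
            fms.add(formations[int(rng.integers(cfg.n_formations))])
        duration = rng.uniform(*cfg.species_duration_range_ma)
        mid = rng.uniform(young + duration / 2, old - duration / 2)
        age_max = round(mid + duration / 2, 3)
        age_min = round(mid - duration / 2, 3)

        truth_species[species_id] = {
            "true_lod": true_lod,
            "lambda": lam,
            "n_specimens": n_spec,
            "publication_year": year,
            "subgroup": subgroup,
            "observed": n_spec > 0,
        }
        if n_spec == 0:
            continue  # unobserved species leave no record

        diagnoses[species_id] = SpeciesDiagnosis(
            species_id=species_id, publication_year=year, characters=chars
        )
        groupings.append(
            GroupAssignment(
                species_id=species_id,
                subgroup=subgroup,
                formations=frozenset(fms),
                age_max_ma=age_max,
                age_min_ma=age_min,
            )
        )
        mat = _draw_element_sets(rng, n_spec, presence)
        fm_list = sorted(fms)
        for j in range(n_spec):
            sid = f"{species_id}_s{j + 1:03d}"
            elements = {element_ids[k]: 1 for k in np.nonzero(mat[j])[0]}
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    taxon_name=species_id,
                    taxon_rank="species",
                    species_id=species_id,
                    named=True,
                    elements=elements,
                )
            )
            fm = fm_list[int(rng.integers(len(fm_list)))]
            occ_counter += 1
            occ_rows.append(
                {
                    "occurrence_id": f"occ_{occ_counter:05d}",
                    "collection_id": f"loc_{fm}_{int(rng.integers(1, 6)):02d}",
                    "taxon_name": species_id,
                    "taxon_rank": "species",
                    "n_individuals": 1,
                    "formation": fm,
                    "age_max_ma": age_max,
                    "age_min_ma": age_min,
                }
            )

    # indeterminate, higher-rank material
    n_indet = int(round(cfg.indeterminate_fraction * len(diagnoses)))
    for j in range(n_indet):
        subgroup = subgroups[int(rng.integers(cfg.n_subgroups))]
        mat = _draw_element_sets(rng, 1, presence)
        elements = {element_ids[k]: 1 for k in np.nonzero(mat[0])[0]}
        sid = f"indet_{j + 1:03d}"
        specimens.append(
            SpecimenRecord(
                specimen_id=sid,
                taxon_name=f"{subgroup} indet.",
                taxon_rank="higher",
                species_id=None,
                named=False,
                elements=elements,
            )
        )
        fm = formations[int(rng.integers(cfg.n_formations))]
        duration = rng.uniform(*cfg.species_duration_range_ma)
        mid = rng.uniform(young + duration / 2, old - duration / 2)
        occ_counter += 1
        occ_rows.append(
            {
                "occurrence_id": f"occ_{occ_counter:05d}",
                "collection_id": f"loc_{fm}_{int(rng.integers(1, 6)):02d}",
                "taxon_name": f"{subgroup} indet.",
                "taxon_rank": "higher",
                "n_individuals": 1,
                "formation": fm,
                "age_max_ma": round(mid + duration / 2, 3),
                "age_min_ma": round(mid - duration / 2, 3),
            }
        )

    occ_cols = ["occurrence_id", "collection_id", "taxon_name", "taxon_rank",
                "n_individuals", "formation", "age_max_ma", "age_min_ma"]
    occurrences = pd.DataFrame(occ_rows, columns=occ_cols)
    truth = {
        "seed": int(cfg.seed),
        "coupling_beta": cfg.coupling_beta,
        "baseline_abundance": cfg.baseline_abundance,
        "lod_reference": cfg.lod_reference,
        "abundance_dispersion": cfg.abundance_dispersion,
        "pp_true": {e: float(p) for e, p in zip(element_ids, pp_true)},
        "species": truth_species,
    }
    return SyntheticBundle(
        schema=schema,
        specimens=specimens,
        diagnoses=diagnoses,
        occurrences=occurrences,
        stages=list(cfg.stage_table),
        groupings=groupings,
        truth=truth,
    )


def make_null_and_effect_suites(
    base_config: SimulationConfig,
    betas: Sequence[float],
    n_replicates: int,
    seed: int,
) -> tuple[list[dict], Iterator[tuple[float, int, SyntheticBundle]]]:
    """Replicate suites across coupling strengths with derived seeds.

    Returns a manifest — one entry per (beta, replicate) recording the
    derived seed and the truth needed for recovery tests — and a lazy
    iterator of the corresponding bundles.  Seeds are spawned from a single
    ``SeedSequence`` so every bundle is independently reproducible.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(betas) * n_replicates)
    manifest = []
    idx = 0
    for beta in betas:
        for rep in range(n_replicates):
            derived = int(children[idx].generate_state(1)[0] % (2**31))
            manifest.append({"beta": float(beta), "replicate": rep, "seed": derived})
            idx += 1

    def _bundles() -> Iterator[tuple[float, int, SyntheticBundle]]:
        for entry in manifest:
            cfg = dataclasses.replace(
                base_config, seed=entry["seed"], coupling_beta=entry["beta"]
            )
            yield entry["beta"], entry["replicate"], generate_dataset(cfg)

    return manifest, _bundles()
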