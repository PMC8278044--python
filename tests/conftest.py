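import textwrap

import pytest

from lodiag.fossil_data import (
    ElementSchema,
    SkeletalElement,
    SpecimenRecord,
    default_element_schema,
)
from lodiag.pipeline import AnalysisInputs, species_analysis
from lodiag.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def schema() -> ElementSchema:
    return default_element_schema()


@pytest.fixture
def toy_schema() -> ElementSchema:
    return ElementSchema(
        [
            SkeletalElement("maxilla", "Maxilla", "skull"),
            SkeletalElement("dentary", "Dentary", "skull"),
            SkeletalElement("humerus", "Humerus", "forelimb"),
            SkeletalElement("femur", "Femur", "hind limb"),
            SkeletalElement("tibia", "Tibia", "hind limb"),
        ]
    )


def make_specimen(specimen_id, elements, species_id="sp1", rank="species"):
    return SpecimenRecord(
        specimen_id=specimen_id,
        taxon_name=species_id or "Theropoda indet.",
        taxon_rank=rank,
        species_id=species_id if rank == "species" else None,
        elements=dict(elements),
    )


# 12 hand-written specimens across 3 species plus one indeterminate record;
# per-element row counts double as an independent line-count oracle
TOY_SPECIMEN_CSV = textwrap.dedent(
    """\
    specimen_id,taxon_name,taxon_rank,species_id,named,element_id,multiplicity
    s01,sp_a,species,sp_a,True,femur,1
    s01,sp_a,species,sp_a,True,tibia,1
    s02,sp_a,species,sp_a,True,femur,1
    s03,sp_a,species,sp_a,True,maxilla,1
    s04,sp_b,species,sp_b,True,femur,2
    s05,sp_b,species,sp_b,True,dentary,1
    s05,sp_b,species,sp_b,True,humerus,1
    s06,sp_b,species,sp_b,True,tibia,1
    s07,sp_c,species,sp_c,True,femur,1
    s08,sp_c,species,sp_c,True,maxilla,1
    s08,sp_c,species,sp_c,True,femur,1
    s09,sp_c,species,sp_c,True,tibia,1
    s10,sp_c,species,sp_c,True,humerus,1
    s11,sp_c,species,sp_c,True,femur,1
    s12,Theropoda indet.,higher,,False,femur,3
    """
)


@pytest.fixture
def toy_specimen_csv(tmp_path):
    path = tmp_path / "specimens.csv"
    path.write_text(TOY_SPECIMEN_CSV)
    return path


@pytest.fixture(scope="session")
def null_bundle():
    """One synthetic bundle from the null world (no LoD-abundance coupling)."""
    return generate_dataset(SimulationConfig(seed=2021, n_species=60))


@pytest.fixture(scope="session")
def null_analysis(null_bundle):
    return species_analysis(AnalysisInputs.from_bundle(null_bundle))


@pytest.fixture(scope="session")
def pipeline_fixture_dir(tmp_path_factory):
    """A written-to-disk synthetic bundle serving as the toy pipeline fixture."""
    outdir = tmp_path_factory.mktemp("toy_bundle")
    bundle = generate_dataset(
        SimulationConfig(seed=99, n_species=40, n_subgroups=4, n_formations=6)
    )
    bundle.write(outdir)
    return outdir


@pytest.fixture
def pipeline_config(pipeline_fixture_dir, tmp_path):
    from lodiag.pipeline import PipelineConfig

    return PipelineConfig(
        specimen_path=str(pipeline_fixture_dir / "specimens.csv"),
        diagnosis_path=str(pipeline_fixture_dir / "diagnoses.csv"),
        occurrence_path=str(pipeline_fixture_dir / "occurrences.csv"),
        stage_path=str(pipeline_fixture_dir / "stages.csv"),
        grouping_path=str(pipeline_fixture_dir / "groupings.csv"),
        schema_path=str(pipeline_fixture_dir / "element_schema.csv"),
        output_dir=str(tmp_path / "out"),
    )
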