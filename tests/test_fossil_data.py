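"""Readers, writers and validation of the canonical tables."""

import textwrap

import pandas as pd
import pytest

from lodiag.fossil_data import (
    StageBin,
    ValidationError,
    default_stage_table,
    read_grouping_table,
    read_occurrence_table,
    read_specimen_table,
    read_stage_table,
    specimens_to_frame,
    write_table,
)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestSpecimenReader:
    def test_two_row_csv_gives_one_specimen_with_two_elements(self, tmp_path, toy_schema):
        path = write(
            tmp_path,
            "s.csv",
            """\
            specimen_id,taxon_name,taxon_rank,species_id,element_id
            s1,sp_a,species,sp_a,femur
            s1,sp_a,species,sp_a,tibia
            """,
        )
        records = read_specimen_table(path, toy_schema)
        assert len(records) == 1
        assert records[0].elements == {"femur": 1, "tibia": 1}

    def test_unknown_element_id_is_rejected_listing_offenders(self, tmp_path, toy_schema):
        path = write(
            tmp_path,
            "s.csv",
            """\
            specimen_id,species_id,element_id
            s1,sp_a,femur
            s2,sp_a,fibula_left
            """,
        )
        with pytest.raises(ValidationError, match="fibula_left"):
            read_specimen_table(path, toy_schema)

    def test_duplicate_specimen_element_pair_is_rejected(self, tmp_path, toy_schema):
        path = write(
            tmp_path,
            "s.csv",
            """\
            specimen_id,species_id,element_id
            s1,sp_a,femur
            s1,sp_a,femur
            """,
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_specimen_table(path, toy_schema)

    def test_toy_fixture_record_count_and_line_count_oracle(self, toy_specimen_csv, toy_schema):
        """12 specimens in the fixture; element tallies match a raw line scan."""
        records = read_specimen_table(toy_specimen_csv, toy_schema)
        assert len(records) == 12
        # independent oracle: count data lines mentioning each element id
        lines = toy_specimen_csv.read_text().splitlines()[1:]
        for element in ("femur", "tibia", "maxilla", "dentary", "humerus"):
            expected = sum(1 for ln in lines if f",{element}," in ln)
            got = sum(1 for r in records if element in r.elements)
            assert got == expected

    def test_wide_layout_is_converted(self, tmp_path, toy_schema):
        path = write(
            tmp_path,
            "wide.csv",
            """\
            specimen_id,species_id,femur,tibia,maxilla
            s1,sp_a,1,0,2
            """,
        )
        (rec,) = read_specimen_table(path, toy_schema)
        assert rec.elements == {"femur": 1, "maxilla": 2}

    def test_multiplicity_defaults_to_one_when_column_absent(self, tmp_path, toy_schema):
        path = write(
            tmp_path,
            "s.csv",
            """\
            specimen_id,species_id,element_id
            s1,sp_a,femur
            """,
        )
        (rec,) = read_specimen_table(path, toy_schema)
        assert rec.elements == {"femur": 1}


class TestRoundTrip:
    def test_specimen_round_trip_identity(self, toy_specimen_csv, toy_schema, tmp_path):
        records = read_specimen_table(toy_specimen_csv, toy_schema)
        out = tmp_path / "rt.csv"
        write_table(records, out)
        again = read_specimen_table(out, toy_schema)
        assert specimens_to_frame(records).equals(specimens_to_frame(again))

    def test_empty_collection_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_table([], out)
        text = out.read_text().strip().splitlines()
        assert len(text) == 1 and "specimen_id" in text[0]

    def test_occurrence_round_trip_preserves_age_precision(self, tmp_path):
        path = write(
            tmp_path,
            "occ.csv",
            """\
            occurrence_id,collection_id,taxon_name,taxon_rank,n_individuals,formation,age_max_ma,age_min_ma
            o1,c1,sp_a,species,2,Fm A,157.2999999,152.1000001
            """,
        )
        df = read_occurrence_table(path)
        out = tmp_path / "rt.csv"
        write_table(df, out)
        again = read_occurrence_table(out)
        pd.testing.assert_frame_equal(df, again)

    def test_stage_and_grouping_round_trip(self, tmp_path):
        stages = default_stage_table()
        out = tmp_path / "stages.csv"
        write_table(stages, out)
        assert read_stage_table(out) == stages

        path = write(
            tmp_path,
            "g.csv",
            """\
            species_id,subgroup,formations,age_max_ma,age_min_ma
            sp_a,G1,Fm A;Fm B,157.3,152.1
            """,
        )
        (g,) = read_grouping_table(path)
        out2 = tmp_path / "g2.csv"
        write_table([g], out2)
        assert read_grouping_table(out2) == [g]
        assert g.formations == frozenset({"Fm A", "Fm B"})


class TestOccurrences:
    def test_pbdb_download_columns_are_accepted(self, tmp_path):
        path = write(
            tmp_path,
            "pbdb.csv",
            """\
            occurrence_no,collection_no,accepted_name,accepted_rank,abund_value,formation,max_ma,min_ma
            101,9,Allosaurus fragilis,species,3,Morrison,157.3,145.0
            102,9,Tyrannosauridae,family,,Hell Creek,72.1,66.0
            """,
        )
        df = read_occurrence_table(path)
        assert list(df["occurrence_id"]) == ["101", "102"]
        assert list(df["taxon_rank"]) == ["species", "higher"]
        assert list(df["n_individuals"]) == [3, 1]  # missing abundance -> 1

    def test_inverted_age_bounds_are_rejected(self, tmp_path):
        path = write(
            tmp_path,
            "occ.csv",
            """\
            occurrence_id,collection_id,taxon_name,age_max_ma,age_min_ma
            o1,c1,sp_a,66.0,72.1
            """,
        )
        with pytest.raises(ValidationError, match="age bounds"):
            read_occurrence_table(path)


class TestStages:
    def test_overlapping_stages_are_rejected(self, tmp_path):
        path = write(
            tmp_path,
            "st.csv",
            """\
            stage_name,age_max_ma,age_min_ma
            A,100,90
            B,95,85
            """,
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_stage_table(path)

    def test_degenerate_stage_is_rejected(self):
        with pytest.raises(ValidationError):
            StageBin("bad", 90.0, 90.0)
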