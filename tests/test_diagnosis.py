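"""Exclusion filtering and character weighting of taxonomic diagnoses."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodiag.diagnosis import (
    DiagnosisCharacter,
    SpeciesDiagnosis,
    apply_exclusion_filters,
    character_weights,
    read_diagnosis_table,
)
from lodiag.fossil_data import ValidationError


def ch(target, kind="standalone", cid=None, sp="sp1"):
    return DiagnosisCharacter(species_id=sp, target=target, kind=kind, combination_id=cid)


def diag(characters, year=2000, sp="sp1"):
    return SpeciesDiagnosis(species_id=sp, publication_year=year, characters=list(characters))


class TestExclusionFilters:
    def test_pre_1981_diagnosis_loses_all_characters_and_is_flagged(self):
        d = diag([ch("maxilla")] * 6, year=1975)
        filtered, report = apply_exclusion_filters(d)
        assert filtered.characters == []
        assert not filtered.quantifiable
        assert report.no_quantifiable_diagnosis
        assert len(report) == 6

    @pytest.mark.parametrize("year,kept", [(1980, 0), (1981, 1), (2020, 1)])
    def test_year_boundary_post_1980_means_1981_onward(self, year, kept):
        filtered, _ = apply_exclusion_filters(diag([ch("maxilla")], year=year))
        assert len(filtered.characters) == kept

    @pytest.mark.parametrize(
        "target",
        ["body_partition", "integument", "multi_element_fenestra", "multi_element_association"],
    )
    def test_unassignable_targets_are_removed_with_rule(self, target):
        filtered, report = apply_exclusion_filters(diag([ch(target), ch("femur")]))
        assert [c.target for c in filtered.characters] == ["femur"]
        assert len(report) == 1 and target in report.removals[0][1]

    def test_empty_diagnosis_passes_through_empty(self):
        filtered, report = apply_exclusion_filters(diag([]))
        assert filtered.characters == [] and len(report) == 0
        assert filtered.quantifiable

    def test_filtering_is_idempotent(self):
        d = diag(
            [ch("maxilla"), ch("integument"),
             ch("femur", "combination_member", "c1"),
             ch("body_partition", "combination_member", "c1")]
        )
        once, _ = apply_exclusion_filters(d)
        twice, _ = apply_exclusion_filters(once)
        assert once.characters == twice.characters
        assert once.original_combination_sizes == twice.original_combination_sizes
        # and the weights computed after one or two passes agree
        assert character_weights(once).weights == character_weights(twice).weights


class TestCharacterWeights:
    def test_four_member_combination_gives_quarter_weights(self):
        d = diag(
            [ch(e, "combination_member", "c1") for e in ("maxilla", "femur", "tibia", "ilium")]
        )
        filtered, _ = apply_exclusion_filters(d)
        wm = character_weights(filtered)
        assert wm.weights == {e: 0.25 for e in ("maxilla", "femur", "tibia", "ilium")}

    def test_single_standalone_is_unit_weight(self):
        filtered, _ = apply_exclusion_filters(diag([ch("maxilla")]))
        assert character_weights(filtered).weights == {"maxilla": 1.0}

    def test_standalones_plus_combination_hand_sum(self):
        d = diag(
            [ch("maxilla"), ch("maxilla"),
             ch("maxilla", "combination_member", "c1"),
             ch("femur", "combination_member", "c1"),
             ch("tibia", "combination_member", "c1")]
        )
        filtered, _ = apply_exclusion_filters(d)
        wm = character_weights(filtered)
        assert wm.weights["maxilla"] == pytest.approx(2 + 1 / 3)
        assert wm.weights["femur"] == pytest.approx(1 / 3)
        assert wm.weights["tibia"] == pytest.approx(1 / 3)
        assert wm.total == pytest.approx(3.0)

    def test_excluded_member_share_is_dropped_not_redistributed(self):
        d = diag(
            [ch("maxilla", "combination_member", "c1"),
             ch("femur", "combination_member", "c1"),
             ch("integument", "combination_member", "c1"),
             ch("body_partition", "combination_member", "c1")]
        )
        filtered, _ = apply_exclusion_filters(d)
        wm = character_weights(filtered)  # k stays 4 from before exclusion
        assert wm.weights == {"maxilla": 0.25, "femur": 0.25}
        post = character_weights(filtered, combination_denominator="post_exclusion")
        assert post.weights == {"maxilla": 0.5, "femur": 0.5}

    def test_fully_excluded_combination_contributes_nothing(self):
        d = diag(
            [ch("integument", "combination_member", "c1"),
             ch("body_partition", "combination_member", "c1")]
        )
        filtered, _ = apply_exclusion_filters(d)
        assert character_weights(filtered).weights == {}

    def test_unfiltered_excluded_target_raises(self):
        with pytest.raises(ValidationError, match="apply_exclusion_filters"):
            character_weights(diag([ch("integument")]))


@given(
    n_standalone=st.integers(min_value=0, max_value=10),
    combo_sizes=st.lists(st.integers(min_value=2, max_value=6), max_size=5),
)
@settings(derandomize=True, max_examples=100)
def test_weight_conservation(n_standalone, combo_sizes):
    """No exclusions: total weight = #standalone + #combinations; all weights >= 0."""
    elements = [f"e{i}" for i in range(7)]
    chars = [ch(elements[i % 7]) for i in range(n_standalone)]
    for j, size in enumerate(combo_sizes):
        cid = f"c{j}"
        chars += [ch(elements[(i + j) % 7], "combination_member", cid) for i in range(size)]
    filtered, _ = apply_exclusion_filters(diag(chars))
    wm = character_weights(filtered)
    assert all(w >= 0 for w in wm.weights.values())
    assert wm.total == pytest.approx(n_standalone + len(combo_sizes), abs=1e-9)


def test_combination_spanning_species_is_rejected():
    with pytest.raises(ValidationError, match="spans multiple species"):
        SpeciesDiagnosis(
            species_id="sp1",
            publication_year=2000,
            characters=[
                ch("femur", "combination_member", "c1", sp="sp1"),
                ch("tibia", "combination_member", "c1", sp="sp2"),
            ],
        )


def test_read_diagnosis_table(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text(
        textwrap.dedent(
            """\
            species_id,publication_year,target,kind,combination_id,description
            sp_a,1999,maxilla,standalone,,ridge on maxilla
            sp_a,1999,femur,combination_member,c1,
            sp_a,1999,tibia,combination_member,c1,
            sp_b,1975,femur,standalone,,
            sp_c,2005,,,,
            """
        )
    )
    diags = read_diagnosis_table(path)
    assert set(diags) == {"sp_a", "sp_b", "sp_c"}
    assert len(diags["sp_a"].characters) == 3
    assert diags["sp_b"].publication_year == 1975
    assert diags["sp_c"].characters == []  # year-only row: diagnosed, no characters
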