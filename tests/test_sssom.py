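"""SSSOM TSV reading/writing and the free-text sign/symptom dialect."""

import pytest
from hypothesis import given, settings, strategies as st

from phenomap.sssom import (
    EXACT_MATCH,
    NARROW_MATCH,
    PREDICATES,
    Mapping,
    MappingSet,
    SssomFormatError,
    SymptomMapping,
    read_sssom,
    read_symptom_table,
    write_sssom,
    write_symptom_table,
)


def hypospadias_mapping():
    return Mapping(
        subject_id="MP:0003124",
        subject_label="hypospadia",
        predicate=NARROW_MATCH,
        object_id="HP:0000047",
        object_label="Hypospadias",
        method="manual",
        authors=("orcid.org/0000-0003-4606-0597",),
        mapping_date="2024-03-01",
        comment="HPO term is male-specific",
    )


class TestMappingModel:
    def test_bad_predicate_and_method_rejected(self):
        with pytest.raises(ValueError):
            Mapping("MP:1", "skos:exactmatch", "HP:1")
        with pytest.raises(ValueError):
            Mapping("MP:1", EXACT_MATCH, "HP:1", method="guessed")

    def test_duplicate_rows_rejected(self):
        m = hypospadias_mapping()
        with pytest.raises(ValueError, match="duplicate"):
            MappingSet([m, m])

    def test_prefix_convention_enforced_with_override(self):
        flipped = Mapping("HP:0000047", NARROW_MATCH, "MP:0003124")
        with pytest.raises(ValueError, match="prefix"):
            MappingSet([flipped])
        assert len(MappingSet([flipped], any_prefixes=True)) == 1


class TestSssomIO:
    def test_empty_set_writes_header_only(self):
        text = write_sssom(MappingSet(metadata={"license": "CC-BY-4.0"}))
        lines = text.strip().splitlines()
        assert lines[0] == "# license: CC-BY-4.0"
        assert lines[1].startswith("subject_id\t")
        assert len(lines) == 2

    def test_hypospadias_row(self):
        text = write_sssom(MappingSet([hypospadias_mapping()]))
        row = text.strip().splitlines()[-1].split("\t")
        assert row[0] == "MP:0003124"
        assert row[2] == "skos:narrowMatch"
        assert row[5] == "semapv:ManualMappingCuration"

    def test_round_trip(self):
        original = MappingSet(
            [hypospadias_mapping()], metadata={"mapping_set_id": "mh-test"}
        )
        assert read_sssom(write_sssom(original)) == original

    def test_extra_columns_preserved(self):
        text = (
            "# mapping_set_id: t\n"
            "subject_id\tpredicate_id\tobject_id\tconfidence\n"
            "MP:0000001\tskos:exactMatch\tHP:0000001\t0.9\n"
        )
        ms = read_sssom(text)
        assert ms.extra_columns == ("confidence",)
        assert dict(ms.mappings[0].extras) == {"confidence": "0.9"}
        assert read_sssom(write_sssom(ms)) == ms

    def test_predicate_case_is_strict(self):
        text = (
            "subject_id\tpredicate_id\tobject_id\n"
            "MP:0000001\tskos:exactmatch\tHP:0000001\n"
        )
        with pytest.raises(SssomFormatError, match="row 2"):
            read_sssom(text)

    def test_missing_required_column_named(self):
        with pytest.raises(SssomFormatError, match="predicate_id"):
            read_sssom("subject_id\tobject_id\nMP:1\tHP:1\n")

    def test_writer_is_deterministic(self):
        ms = MappingSet([hypospadias_mapping()], metadata={"b": "2", "a": "1"})
        assert write_sssom(ms) == write_sssom(
            MappingSet([hypospadias_mapping()], metadata={"a": "1", "b": "2"})
        )

    @given(
        st.lists(
            st.builds(
                Mapping,
                subject_id=st.integers(0, 30).map(lambda i: f"MP:{i:07d}"),
                predicate=st.sampled_from(PREDICATES),
                object_id=st.integers(0, 30).map(lambda i: f"HP:{i:07d}"),
                subject_label=st.text(
                    st.characters(categories=["L", "Nd"], include_characters=" "),
                    max_size=20,
                ),
                method=st.sampled_from(["manual", "logical", "lexical"]),
                authors=st.lists(
                    st.sampled_from(["orcid.org/0000-0001", "orcid.org/0000-0002"]),
                    max_size=2,
                ).map(tuple),
                comment=st.text(
                    st.characters(categories=["L", "Nd"], include_characters=" ;,"),
                    max_size=20,
                ),
            ),
            max_size=12,
            unique_by=lambda m: m.key,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_on_random_sets(self, mappings):
        # the writer emits rows in canonical sorted order, so round-trip
        # identity is stated on canonically ordered sets
        mappings = sorted(mappings, key=lambda m: m.key)
        original = MappingSet(mappings, metadata={"mapping_set_id": "prop"})
        assert read_sssom(write_sssom(original)) == original


class TestSymptomDialect:
    def test_fever_maps_to_three_mp_terms(self):
        row = SymptomMapping(
            description="fever",
            mp_ids=("MP:0005533", "MP:0011017", "MP:0011016"),
            hp_ids=("HP:0001945",),
            source_refs=("PMID:32000000",),
        )
        back = read_symptom_table(write_symptom_table([row]))
        assert back == [row]
        assert len(back[0].mp_ids) == 3

    def test_hp_only_rows_are_valid(self):
        """Human-specific signs (brain fog) have HP ids but no MP ids."""
        row = SymptomMapping(
            description="brain fog",
            hp_ids=("HP:0033630", "HP:0001289"),
            source_refs=("PMID:33000001",),
        )
        back = read_symptom_table(write_symptom_table([row]))
        assert back[0].mp_ids == ()
        assert back[0].hp_ids == ("HP:0033630", "HP:0001289")

    def test_empty_description_rejected(self):
        with pytest.raises(ValueError):
            SymptomMapping(description="")
        text = "description\tmp_ids\thp_ids\tsource_refs\n\tMP:1\t\t\n"
        with pytest.raises(SssomFormatError, match="row 2"):
            read_symptom_table(text)

    @given(
        st.lists(
            st.builds(
                SymptomMapping,
                description=st.text(
                    st.characters(categories=["L", "Nd"], include_characters=" "),
                    min_size=1,
                    max_size=30,
                ).filter(lambda s: s.strip()),
                mp_ids=st.lists(
                    st.integers(0, 99).map(lambda i: f"MP:{i:07d}"), max_size=3, unique=True
                ).map(tuple),
                hp_ids=st.lists(
                    st.integers(0, 99).map(lambda i: f"HP:{i:07d}"), max_size=3, unique=True
                ).map(tuple),
                source_refs=st.lists(
                    st.integers(0, 99).map(lambda i: f"PMID:{i}"), max_size=2
                ).map(tuple),
            ),
            max_size=10,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_on_random_tables(self, rows):
        assert read_symptom_table(write_symptom_table(rows)) == rows
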