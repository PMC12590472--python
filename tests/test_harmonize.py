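"""Priority-based merging and the three curator discrepancy reports."""

import random

import pytest

from phenomap.fixtures import generate_fixture_pair
from phenomap.harmonize import (
    MergePolicy,
    merge_mappings,
    report_exact_without_logical_agreement,
    report_logical_without_exact_mapping,
    report_multi_exact_lexical,
)
from phenomap.lexical import lexical_match
from phenomap.model import EQExpression, Ontology, Term
from phenomap.sssom import (
    BROAD_MATCH,
    CLOSE_MATCH,
    EXACT_MATCH,
    NARROW_MATCH,
    PREDICATES,
    RELATED_MATCH,
    Mapping,
    MappingSet,
)

METHODS = ("manual", "logical", "lexical")


def mapping(pred=EXACT_MATCH, method="manual", s="MP:0000010", o="HP:0000010", **kw):
    return Mapping(subject_id=s, predicate=pred, object_id=o, method=method, **kw)


def random_mapping_sets(rng, n_sets=3, n_pairs=6):
    sets = []
    for _ in range(n_sets):
        rows = {}
        for _ in range(rng.randint(0, 2 * n_pairs)):
            m = mapping(
                pred=rng.choice(PREDICATES),
                method=rng.choice(METHODS),
                s=f"MP:{rng.randint(1, n_pairs):07d}",
                o=f"HP:{rng.randint(1, n_pairs):07d}",
            )
            rows.setdefault(m.key, m)
        sets.append(MappingSet(list(rows.values())))
    return sets


class TestMerge:
    def test_manual_beats_stronger_lexical_predicate(self):
        manual = MappingSet([mapping(RELATED_MATCH, "manual")])
        lexical = MappingSet([mapping(EXACT_MATCH, "lexical")])
        merged = merge_mappings([manual, lexical])
        (m,) = merged.mappings
        assert (m.method, m.predicate) == ("manual", RELATED_MATCH)
        assert "superseded: lexical skos:exactMatch" in m.comment

    def test_predicate_priority_within_method(self):
        s = MappingSet(
            [mapping(EXACT_MATCH, "lexical"), mapping(NARROW_MATCH, "lexical")]
        )
        (m,) = merge_mappings([s]).mappings
        assert (m.method, m.predicate) == ("lexical", EXACT_MATCH)

    def test_empty_inputs(self):
        assert len(merge_mappings([])) == 0
        assert len(merge_mappings([MappingSet()])) == 0

    def test_full_priority_order(self):
        """Across every (method, predicate) combination the winner is the
        best method, then the strongest predicate within it."""
        rows = [
            mapping(pred, meth)
            for meth in METHODS
            for pred in (EXACT_MATCH, NARROW_MATCH, BROAD_MATCH, CLOSE_MATCH, RELATED_MATCH)
        ]
        for keep_method in METHODS:
            subset = [m for m in rows if m.method in (keep_method, "lexical")]
            merged = merge_mappings([MappingSet(subset)])
            (winner,) = merged.mappings
            best_method = "manual" if keep_method == "manual" else (
                "logical" if keep_method == "logical" else "lexical"
            )
            assert winner.method == best_method
            assert winner.predicate == EXACT_MATCH

    def test_pass_through_single_rows_unchanged(self):
        m = mapping(NARROW_MATCH, "manual", comment="curator note")
        (out,) = merge_mappings([MappingSet([m])]).mappings
        assert out == m

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_and_order_invariant(self, seed):
        rng = random.Random(seed)
        sets = random_mapping_sets(rng)
        merged = merge_mappings(sets)
        # idempotence
        assert merge_mappings([merged]).mappings == merged.mappings
        # input-order invariance
        shuffled = sets[::-1]
        assert merge_mappings(shuffled).mappings == merged.mappings
        # never invents rows
        input_keys = {m.key for s in sets for m in s}
        for m in merged:
            assert m.key in input_keys
        # one row per pair, matching a brute-force per-pair minimum
        policy = MergePolicy()
        best = {}
        for s in sets:
            for m in s:
                pair = (m.subject_id, m.object_id)
                if pair not in best or policy.rank(m) < policy.rank(best[pair]):
                    best[pair] = m
        assert {(m.subject_id, m.object_id): (m.method, m.predicate) for m in merged} == {
            p: (m.method, m.predicate) for p, m in best.items()
        }


class TestDiscrepancyReports:
    def test_anophthalmia_disagreement_found_then_resolved(self, anophthalmia_pair):
        mp, hp = anophthalmia_pair
        manual = MappingSet([mapping(EXACT_MATCH, "manual", "MP:0001293", "HP:0000528")])
        report = report_exact_without_logical_agreement(manual, mp, hp)
        assert len(report) == 1
        assert report.items[0][:2] == ("MP:0001293", ("HP:0000528",))
        # harmonize the filler the way the curators did, on the MP side
        mp["MP:0001293"].logical_def = hp["HP:0000528"].logical_def
        assert len(report_exact_without_logical_agreement(manual, mp, hp)) == 0

    def test_absent_definition_detail(self, osteopenia_pair):
        mp, hp = osteopenia_pair
        manual = MappingSet([mapping(EXACT_MATCH, "manual", "MP:0000063", "HP:0000938")])
        report = report_exact_without_logical_agreement(manual, mp, hp)
        assert len(report) == 1
        assert "absent" in report.items[0][2]

    def test_planted_disagreement_count(self):
        rng = random.Random(99)
        mp, hp = Ontology("MP"), Ontology("HP")
        rows = []
        k = 0
        for i in range(30):
            eq_mp = EQExpression("PATO:0000051", (("RO:0002314", f"UBERON:{i:07d}"),))
            disagree = rng.random() < 0.4
            eq_hp = (
                EQExpression("PATO:0000051", (("RO:0002314", f"UBERON:{i + 1000:07d}"),))
                if disagree
                else eq_mp
            )
            k += disagree
            mp.add_term(Term(f"MP:{i:07d}", label=f"mp {i}", definition="d", logical_def=eq_mp))
            hp.add_term(Term(f"HP:{i:07d}", label=f"hp {i}", definition="d", logical_def=eq_hp))
            rows.append(mapping(EXACT_MATCH, "manual", f"MP:{i:07d}", f"HP:{i:07d}"))
        report = report_exact_without_logical_agreement(MappingSet(rows), mp, hp)
        assert len(report) == k

    def test_polycystic_logical_without_exact(self, polycystic_pair):
        mp, hp = polycystic_pair
        manual = MappingSet([mapping(NARROW_MATCH, "manual", "MP:0008528", "HP:0000113")])
        report = report_logical_without_exact_mapping(manual, mp, hp)
        assert len(report) == 1
        assert "skos:narrowMatch" in report.items[0][2]
        # once mapped exact, the discrepancy disappears
        manual2 = MappingSet([mapping(EXACT_MATCH, "manual", "MP:0008528", "HP:0000113")])
        assert len(report_logical_without_exact_mapping(manual2, mp, hp)) == 0

    def test_unmapped_logical_pair_reported(self, polycystic_pair):
        mp, hp = polycystic_pair
        report = report_logical_without_exact_mapping(MappingSet(), mp, hp)
        assert len(report) == 1
        assert "not manually mapped" in report.items[0][2]

    def test_multi_exact_osteopenia(self, osteopenia_pair):
        mp, hp = osteopenia_pair
        lex = lexical_match(mp, hp)
        report = report_multi_exact_lexical(lex)
        assert report.items == [
            ("MP:0000063", ("HP:0000938", "HP:0004349"), "2 exact lexical matches")
        ]

    def test_injective_lexical_set_is_clean(self):
        mp, hp, _ = generate_fixture_pair(3, 1, 0)
        report = report_multi_exact_lexical(lexical_match(mp, hp))
        assert len(report) == 0

    def test_multi_exact_counts_on_planted_fanout(self):
        """k subjects with a planted double exact match yield exactly k items."""
        k = 7
        rows = []
        for i in range(k):
            rows.append(mapping(EXACT_MATCH, "lexical", f"MP:{i:07d}", f"HP:{2 * i:07d}"))
            rows.append(mapping(EXACT_MATCH, "lexical", f"MP:{i:07d}", f"HP:{2 * i + 1:07d}"))
        report = report_multi_exact_lexical(MappingSet(rows))
        assert len(report) == k
        assert all(len(objects) == 2 for _, objects, _ in report.items)
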