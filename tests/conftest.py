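"""Shared fixtures: tiny MP/HP ontology pairs built from the published
worked examples (osteopenia, hypospadias, midface, anophthalmia,
polycystic kidney) plus generated random pairs."""

import pytest

from phenomap.model import (
    CHARACTERISTIC_OF_PART_OF,
    HAS_MODIFIER,
    EQExpression,
    Ontology,
    Synonym,
    Term,
)

ABSENT = "PATO:0000462"
ABNORMAL = "PATO:0000460"
MORPHOLOGY = "PATO:0000051"
CAMERA_EYE = "UBERON:0000019"
EYEBALL = "UBERON:0010230"
KIDNEY = "UBERON:0002113"


def eq(genus, *mods):
    return EQExpression(genus, tuple(mods))


@pytest.fixture
def osteopenia_pair():
    """MP 'decreased bone mineral density' with two exact synonyms vs the
    two HP terms those synonyms name."""
    mp = Ontology("MP")
    mp.add_term(
        Term(
            "MP:0000063",
            label="decreased bone mineral density",
            definition="Reduced mineral content of bone.",
            synonyms=[
                Synonym("osteopenia", "exact"),
                Synonym("reduced bone mineral density", "exact"),
            ],
        )
    )
    hp = Ontology("HP")
    hp.add_term(Term("HP:0000938", label="Osteopenia", definition="Mild bone mass loss."))
    hp.add_term(
        Term(
            "HP:0004349",
            label="Reduced bone mineral density",
            definition="Below-normal bone mineral density.",
        )
    )
    return mp, hp


@pytest.fixture
def hypospadias_pair():
    """Near-identical labels that differ by one character: no lexical match."""
    mp = Ontology("MP")
    mp.add_term(
        Term(
            "MP:0003124",
            label="hypospadia",
            definition="Displaced urethral opening, either sex.",
        )
    )
    hp = Ontology("HP")
    hp.add_term(
        Term(
            "HP:0000047",
            label="Hypospadias",
            definition="Displaced urethral meatus in males.",
        )
    )
    return mp, hp


@pytest.fixture
def anophthalmia_pair():
    """Exact manual mapping whose EQ fillers disagree on the anatomical
    entity (camera-type eye vs eyeball of camera-type eye)."""
    mp = Ontology("MP")
    mp.add_term(
        Term(
            "MP:0001293",
            label="anophthalmia",
            definition="Absence of the eye.",
            logical_def=eq(ABSENT, (CHARACTERISTIC_OF_PART_OF, CAMERA_EYE)),
        )
    )
    hp = Ontology("HP")
    hp.add_term(
        Term(
            "HP:0000528",
            label="Anophthalmia",
            definition="Absence of the eyeball.",
            logical_def=eq(ABSENT, (CHARACTERISTIC_OF_PART_OF, EYEBALL)),
        )
    )
    return mp, hp


@pytest.fixture
def polycystic_pair():
    """Identical EQ definitions but the manual mapping is a narrowMatch."""
    shared = eq(
        MORPHOLOGY, (CHARACTERISTIC_OF_PART_OF, KIDNEY), (HAS_MODIFIER, ABNORMAL)
    )
    mp = Ontology("MP")
    mp.add_term(
        Term(
            "MP:0008528",
            label="polycystic kidney",
            definition="Multiple cysts in both kidneys.",
            logical_def=shared,
        )
    )
    hp = Ontology("HP")
    hp.add_term(
        Term(
            "HP:0000113",
            label="Polycystic kidney dysplasia",
            definition="Multiple renal cysts.",
            logical_def=shared,
        )
    )
    return mp, hp


@pytest.fixture
def midface_onto():
    """MP fragment with separate retrusion/hypoplasia terms, pre-obsoletion."""
    mp = Ontology("MP")
    mp.add_term(
        Term(
            "MP:0009855",
            label="midface retrusion",
            definition="Posterior positioning of the midface.",
        )
    )
    mp.add_term(
        Term(
            "MP:0012085",
            label="midface hypoplasia",
            definition="Underdevelopment of the midface.",
        )
    )
    return mp
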