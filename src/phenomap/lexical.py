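"""Lexical mapping between two phenotype ontologies.

A match is called only when *all* the words of the two strings match:
labels and synonyms are reduced to lowercased token multisets ("token
bags") and compared for bag equality — "Cleft lip, cleft palate" and
"cleft palate cleft lip" match; "hypospadia" and "Hypospadias" do not.

Each hit is classified with a SKOS mapping predicate from the synonym
scope of the two matched fields.  With the mouse-side (MP) term as
subject and the human-side (HP) term as object:

=============  =============  ==================
subject field  object field   predicate
=============  =============  ==================
label/exact    label/exact    skos:exactMatch
narrow         label/exact    skos:narrowMatch
label/exact    broad          skos:narrowMatch
broad          label/exact    skos:broadMatch
label/exact    narrow         skos:broadMatch
any other combination         skos:relatedMatch
=============  =============  ==================

"A narrowMatch B" states that B (the object, HP side) is narrower than
A; a match through an MP narrow synonym therefore yields narrowMatch,
and the mirrored cells yield broadMatch.  Cells involving related
synonyms, or two scoped synonyms of ambiguous direction, degrade to
relatedMatch.  closeMatch is never produced lexically; it is reserved
for manual curation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .model import Ontology
from .sssom import (
    EXACT_MATCH,
    NARROW_MATCH,
    BROAD_MATCH,
    RELATED_MATCH,
    PREDICATE_PRIORITY,
    Mapping,
    MappingSet,
)

__all__ = [
    "normalize_label",
    "classify_pair",
    "lexical_match",
    "LexicalHit",
    "MATCH_FIELDS",
]

#: fields a match can arise from: the term label or a scoped synonym
MATCH_FIELDS = ("label", "exact", "narrow", "broad", "related")

_PUNCT = re.compile(r"[,;:.()/'\-]")


def normalize_label(text: str) -> tuple[str, ...]:
    """Reduce a label to its token bag.

    Lowercases, replaces punctuation by spaces, splits on whitespace and
    drops empty tokens.  The bag is returned as a sorted tuple, which is
    a canonical, hashable multiset representation: two strings match
    lexically iff their bags are equal.
    """
    tokens = _PUNCT.sub(" ", text.lower()).split()
    return tuple(sorted(tokens))


def token_counts(text: str) -> Counter:
    """Token multiset of a label as a Counter (convenience view)."""
    return Counter(normalize_label(text))


_LABELISH = {"label", "exact"}


def classify_pair(subject_field: str, object_field: str) -> str:
    """SKOS predicate for a lexical hit between two fields.

    Total over ``MATCH_FIELDS`` x ``MATCH_FIELDS``; see the module
    docstring for the matrix.
    """
    for f in (subject_field, object_field):
        if f not in MATCH_FIELDS:
            raise ValueError(f"unknown match field {f!r}")
    s_lab = subject_field in _LABELISH
    o_lab = object_field in _LABELISH
    if s_lab and o_lab:
        return EXACT_MATCH
    if subject_field == "narrow" and o_lab:
        return NARROW_MATCH
    if s_lab and object_field == "broad":
        return NARROW_MATCH
    if subject_field == "broad" and o_lab:
        return BROAD_MATCH
    if s_lab and object_field == "narrow":
        return BROAD_MATCH
    return RELATED_MATCH


@dataclass(frozen=True)
class LexicalHit:
    """One raw field-level match, before per-pair collapsing."""

    subject: str
    object: str
    subject_field: str
    object_field: str
    subject_text: str
    object_text: str

    @property
    def predicate(self) -> str:
        return classify_pair(self.subject_field, self.object_field)


def _field_index(onto: Ontology) -> dict[tuple[str, ...], list[tuple[str, str, str]]]:
    """bag -> [(term id, field, raw text)] over labels and synonyms."""
    index: dict[tuple[str, ...], list[tuple[str, str, str]]] = {}
    for term in sorted(onto.active_terms(), key=lambda t: t.id):
        entries = [("label", term.label)] if term.label else []
        entries += [(s.scope, s.text) for s in term.synonyms]
        for fld, text in entries:
            bag = normalize_label(text)
            if bag:
                index.setdefault(bag, []).append((term.id, fld, text))
    return index


def lexical_hits(subject_onto: Ontology, object_onto: Ontology) -> list[LexicalHit]:
    """All field-level matches between two ontologies (deprecated terms skipped)."""
    s_index = _field_index(subject_onto)
    o_index = _field_index(object_onto)
    hits: list[LexicalHit] = []
    for bag in sorted(set(s_index) & set(o_index)):
        for s_id, s_fld, s_text in s_index[bag]:
            for o_id, o_fld, o_text in o_index[bag]:
                hits.append(LexicalHit(s_id, o_id, s_fld, o_fld, s_text, o_text))
    return hits


def lexical_match(mp: Ontology, hp: Ontology) -> MappingSet:
    """Generate lexical mappings with the MP-side ontology as subject.

    Multiple hits for the same (subject, object) pair collapse to a
    single mapping carrying the highest-priority predicate
    (exact > narrow > broad > related).
    """
    best: dict[tuple[str, str], tuple[int, LexicalHit]] = {}
    for hit in lexical_hits(mp, hp):
        rank = PREDICATE_PRIORITY.index(hit.predicate)
        key = (hit.subject, hit.object)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, hit)
    mappings = [
        Mapping(
            subject_id=s,
            subject_label=mp[s].label,
            predicate=best[(s, o)][1].predicate,
            object_id=o,
            object_label=hp[o].label,
            method="lexical",
        )
        for (s, o) in sorted(best)
    ]
    return MappingSet(
        mappings,
        metadata={"mapping_set_id": f"{mp.prefix.lower()}-{hp.prefix.lower()}-lexical"},
        subject_prefix=mp.prefix,
        object_prefix=hp.prefix,
    )
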