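"""Core data model for phenotype ontologies.

The model covers the subset of an OBO-style ontology needed for
cross-species phenotype mapping: terms with scoped synonyms, text
definitions, is_a parents, entity-quality (EQ) logical definitions,
and deprecation metadata.  Identifiers are CURIEs (``MP:0000063``,
``HP:0000938``, ``UBERON:0002387`` ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "SYNONYM_SCOPES",
    "Synonym",
    "EQExpression",
    "Term",
    "Ontology",
    "curie_prefix",
    "is_curie",
    # common RO relations used in EQ definitions
    "CHARACTERISTIC_OF",
    "CHARACTERISTIC_OF_PART_OF",
    "HAS_MODIFIER",
    "TOWARDS",
    "DEFAULT_EQ_RELATIONS",
]

#: Relations Ontology terms conventionally used in phenotype EQ definitions.
CHARACTERISTIC_OF = "RO:0000053"
CHARACTERISTIC_OF_PART_OF = "RO:0002314"
HAS_MODIFIER = "RO:0002573"
TOWARDS = "RO:0002503"

DEFAULT_EQ_RELATIONS = frozenset(
    {CHARACTERISTIC_OF, CHARACTERISTIC_OF_PART_OF, HAS_MODIFIER, TOWARDS}
)

SYNONYM_SCOPES = ("exact", "narrow", "broad", "related")

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")


def is_curie(s: str) -> bool:
    return bool(_CURIE_RE.match(s))


def curie_prefix(curie: str) -> str:
    """Prefix of a CURIE (``MP:0000063`` -> ``MP``)."""
    return curie.split(":", 1)[0]


@dataclass(frozen=True)
class Synonym:
    """A scoped synonym: EXACT, NARROW, BROAD or RELATED in OBO terms.

    The scope states how the synonym's meaning relates to the term's:
    a NARROW synonym names a narrower concept than the term itself.
    """

    text: str
    scope: str = "exact"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("synonym text must be non-empty")
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(
                f"synonym scope must be one of {SYNONYM_SCOPES}, got {self.scope!r}"
            )


@dataclass(frozen=True)
class EQExpression:
    """An entity-quality logical definition.

    A genus quality (a PATO term such as 'increased size') plus modifier
    clauses, each a (relation, filler) pair — e.g. the definition
    "increased size and characteristic_of some pes and has_modifier some
    abnormal" is ``EQExpression("PATO:0000586", ((RO:0000053, UBERON:0002387),
    (RO:0002573, PATO:0000460)))``.

    Modifiers are stored as a tuple; :func:`phenomap.logical.canonicalize`
    produces the order-free canonical form used for comparison.
    """

    genus: str
    modifiers: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError("EQ expression requires a genus quality")
        if len(set(self.modifiers)) != len(self.modifiers):
            raise ValueError("EQ modifiers must not contain duplicates")


@dataclass
class Term:
    """One ontology class.

    Deprecated (obsoleted) terms keep their identifier forever — ids are
    never deleted from an ontology — and may point at a replacement term.
    """

    id: str
    label: str = ""
    definition: Optional[str] = None
    synonyms: list[Synonym] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    logical_def: Optional[EQExpression] = None
    deprecated: bool = False
    replaced_by: Optional[str] = None
    contributors: list[str] = field(default_factory=list)
    creation_date: Optional[str] = None
    #: unknown OBO tag-value pairs, preserved verbatim for round-trip
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not is_curie(self.id):
            raise ValueError(f"term id must be a CURIE, got {self.id!r}")
        if self.deprecated and self.logical_def is not None:
            raise ValueError(f"{self.id}: deprecated terms carry no logical definition")
        if self.replaced_by is not None and not self.deprecated:
            raise ValueError(f"{self.id}: replaced_by is only valid on deprecated terms")

    @property
    def prefix(self) -> str:
        return curie_prefix(self.id)

    def copy(self) -> "Term":
        return replace(
            self,
            synonyms=list(self.synonyms),
            parents=list(self.parents),
            contributors=list(self.contributors),
            annotations=list(self.annotations),
        )


class Ontology:
    """An id-indexed collection of terms from one namespace (MP, HP, ...).

    Parent CURIEs pointing outside the loaded fragment are tolerated
    (fragments of large ontologies are normal inputs); ``dangling_parents``
    reports them.
    """

    def __init__(self, prefix: str, terms: Iterable[Term] = ()) -> None:
        self.prefix = prefix
        self.terms: dict[str, Term] = {}
        for t in terms:
            self.add_term(t)

    def add_term(self, term: Term) -> Term:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id}")
        self.terms[term.id] = term
        return term

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[term_id]

    def get(self, term_id: str) -> Optional[Term]:
        return self.terms.get(term_id)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def active_terms(self) -> Iterator[Term]:
        """Terms that are not deprecated (the ones matching and QC look at)."""
        return (t for t in self if not t.deprecated)

    def dangling_parents(self) -> list[tuple[str, str]]:
        """(term id, parent id) pairs whose parent does not resolve here."""
        return [
            (t.id, p) for t in self for p in t.parents if p not in self.terms
        ]

    def copy(self) -> "Ontology":
        return Ontology(self.prefix, (t.copy() for t in self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self.prefix == other.prefix and self.terms == other.terms

    def __repr__(self) -> str:
        return f"Ontology(prefix={self.prefix!r}, n_terms={len(self)})"
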