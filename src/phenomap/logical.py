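"""EQ logical-definition comparison and logical cross-ontology matching.

Two phenotype terms "mean the same thing" logically when their
entity-quality definitions are identical: same genus quality and the
same set of (relation, filler) modifier clauses.  Relations are compared
as opaque CURIEs — ``characteristic_of`` (RO:0000053) and
``characteristic_of_part_of`` (RO:0002314) are simply unequal, as are
two anatomical fillers such as 'camera-type eye' (UBERON:0000019) and
'eyeball of camera-type eye' (UBERON:0010230).  No reasoning or
subsumption is attempted.
"""

from __future__ import annotations

from .model import EQExpression, Ontology
from .sssom import EXACT_MATCH, Mapping, MappingSet

__all__ = ["canonicalize", "eq_equal", "logical_match", "EQExpression"]


def canonicalize(eq: EQExpression) -> EQExpression:
    """Canonical form: modifiers de-duplicated and sorted by (relation, filler).

    Idempotent; two expressions are logically identical iff their
    canonical forms are equal.
    """
    return EQExpression(eq.genus, tuple(sorted(set(eq.modifiers))))


def eq_equal(a: EQExpression, b: EQExpression) -> bool:
    """True iff the two definitions are identical up to modifier order."""
    return canonicalize(a) == canonicalize(b)


def logical_match(mp: Ontology, hp: Ontology) -> MappingSet:
    """Mappings between terms sharing an identical logical definition.

    One ``skos:exactMatch`` per (MP term, HP term) pair with equal EQ
    definitions, method "logical".  Terms without a logical definition
    and deprecated terms are skipped.  Note that identical logical
    definitions do not guarantee identical meaning: the textual
    definitions may carry nuances the EQ expression lacks (the
    'polycystic kidney' case), which is exactly what the downstream
    discrepancy reports surface.
    """
    def index(onto: Ontology) -> dict[EQExpression, list[str]]:
        idx: dict[EQExpression, list[str]] = {}
        for t in sorted(onto.active_terms(), key=lambda t: t.id):
            if t.logical_def is not None:
                idx.setdefault(canonicalize(t.logical_def), []).append(t.id)
        return idx

    mp_idx = index(mp)
    hp_idx = index(hp)
    mappings = []
    for eq in sorted(set(mp_idx) & set(hp_idx), key=lambda e: (e.genus, e.modifiers)):
        for s in mp_idx[eq]:
            for o in hp_idx[eq]:
                mappings.append(
                    Mapping(
                        subject_id=s,
                        subject_label=mp[s].label,
                        predicate=EXACT_MATCH,
                        object_id=o,
                        object_label=hp[o].label,
                        method="logical",
                    )
                )
    mappings.sort(key=lambda m: (m.subject_id, m.object_id))
    return MappingSet(
        mappings,
        metadata={"mapping_set_id": f"{mp.prefix.lower()}-{hp.prefix.lower()}-logical"},
        subject_prefix=mp.prefix,
        object_prefix=hp.prefix,
    )
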