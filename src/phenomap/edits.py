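"""Curation edits: term obsoletion with optional merge.

Identifiers are never deleted from an ontology.  Obsoleting a term flips
it to deprecated, strips its logical definition, and — when merging into
a surviving term — records the replacement and transfers the obsoleted
label to the survivor as an exact synonym, the way 'midface retrusion'
was folded into 'midface hypoplasia'.
"""

from __future__ import annotations

from typing import Optional

from .model import Ontology, Synonym

__all__ = ["obsolete_term"]


def obsolete_term(onto: Ontology, victim: str, merge_into: Optional[str] = None) -> Ontology:
    """Deprecate ``victim`` in place, optionally merging it into another term.

    Postconditions: the victim id persists with ``deprecated=True`` and
    no logical definition; when ``merge_into`` is given, the victim
    points at it via ``replaced_by`` and its label is added to the
    survivor as an exact synonym (unless already present).
    """
    term = onto.get(victim)
    if term is None:
        raise KeyError(f"cannot obsolete unknown term {victim}")
    if term.deprecated:
        raise ValueError(f"{victim} is already deprecated")
    if merge_into is not None:
        if merge_into == victim:
            raise ValueError(f"cannot merge {victim} into itself")
        target = onto.get(merge_into)
        if target is None:
            raise KeyError(f"merge target {merge_into} does not exist")
        if target.deprecated:
            raise ValueError(f"merge target {merge_into} is deprecated")
        if term.label and term.label not in {s.text for s in target.synonyms}:
            target.synonyms.append(Synonym(term.label, "exact"))

    term.deprecated = True
    term.logical_def = None
    term.replaced_by = merge_into
    return onto
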