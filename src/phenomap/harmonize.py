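"""Merging mapping sets and extracting curator discrepancy reports.

When a pair of terms is mapped by multiple methods, a single row is
kept, with method priority manual > logical > lexical; when one method
yields several predicates for the same pair, the strongest wins
(exact > narrow > broad > close > related).  closeMatch sits between
broad and related: directional matches carry more information than
close, and close more than related.

The discrepancy reports reproduce the curation workflows that surface
MP/HPO misalignments for human review:

* manual exactMatch pairs whose logical definitions are absent or
  differ (the anophthalmia filler case);
* pairs with identical logical definitions that are *not* manually
  mapped exact (the polycystic-kidney case);
* terms with more than one exact lexical match (the osteopenia
  synonym-scope case).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .logical import eq_equal, logical_match
from .model import Ontology
from .sssom import (
    EXACT_MATCH,
    METHODS,
    PREDICATE_PRIORITY,
    Mapping,
    MappingSet,
)

__all__ = [
    "MergePolicy",
    "DiscrepancyReport",
    "merge_mappings",
    "report_exact_without_logical_agreement",
    "report_logical_without_exact_mapping",
    "report_multi_exact_lexical",
    "write_discrepancy_report",
]


@dataclass(frozen=True)
class MergePolicy:
    """Total orders used to pick the winning row per (subject, object) pair."""

    method_priority: tuple[str, ...] = ("manual", "logical", "lexical")
    predicate_priority: tuple[str, ...] = PREDICATE_PRIORITY

    def __post_init__(self) -> None:
        if sorted(self.method_priority) != sorted(METHODS):
            raise ValueError("method_priority must totally order the three methods")
        if sorted(self.predicate_priority) != sorted(PREDICATE_PRIORITY):
            raise ValueError("predicate_priority must totally order the five predicates")

    def rank(self, m: Mapping) -> tuple[int, int]:
        return (
            self.method_priority.index(m.method),
            self.predicate_priority.index(m.predicate),
        )


def merge_mappings(
    sets: list[MappingSet], policy: Optional[MergePolicy] = None
) -> MappingSet:
    """Collapse several mapping sets to one row per (subject, object).

    The winner is the row ranked first by method priority, then
    predicate priority; superseded rows are recorded in the winner's
    comment.  Identical rows across sets deduplicate silently.  The
    merge is idempotent and independent of input-set order, and never
    invents rows: every output (subject, object, predicate, method)
    occurs in some input.
    """
    policy = policy or MergePolicy()
    by_pair: dict[tuple[str, str], dict[tuple, Mapping]] = {}
    any_prefixes = any(s.any_prefixes for s in sets)
    subject_prefix = sets[0].subject_prefix if sets else "MP"
    object_prefix = sets[0].object_prefix if sets else "HP"
    for s in sets:
        for m in s:
            by_pair.setdefault((m.subject_id, m.object_id), {}).setdefault(m.key, m)

    merged = []
    for pair in sorted(by_pair):
        candidates = sorted(by_pair[pair].values(), key=lambda m: (policy.rank(m), m.key))
        winner, losers = candidates[0], candidates[1:]
        if losers:
            superseded = ", ".join(f"{m.method} {m.predicate}" for m in losers)
            note = f"superseded: {superseded}"
            comment = f"{winner.comment}; {note}" if winner.comment else note
            winner = winner.with_comment(comment)
        merged.append(winner)
    return MappingSet(
        merged,
        metadata={"mapping_set_id": "merged"},
        subject_prefix=subject_prefix,
        object_prefix=object_prefix,
        any_prefixes=any_prefixes,
    )


@dataclass
class DiscrepancyReport:
    """Findings for curator review; items are (subject, objects, detail)."""

    kind: str
    items: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)


def report_exact_without_logical_agreement(
    manual: MappingSet, mp: Ontology, hp: Ontology
) -> DiscrepancyReport:
    """Manual exactMatch pairs whose logical definitions do not agree.

    A pair is flagged when either side lacks a logical definition or
    the two definitions differ (modulo modifier order).
    """
    report = DiscrepancyReport("exact_without_logical_agreement")
    for m in sorted(manual, key=lambda m: (m.subject_id, m.object_id)):
        if m.predicate != EXACT_MATCH:
            continue
        s_term, o_term = mp.get(m.subject_id), hp.get(m.object_id)
        s_def = s_term.logical_def if s_term else None
        o_def = o_term.logical_def if o_term else None
        if s_def is None or o_def is None:
            missing = [
                tid
                for tid, d in ((m.subject_id, s_def), (m.object_id, o_def))
                if d is None
            ]
            report.items.append(
                (m.subject_id, (m.object_id,), f"logical definition absent on {', '.join(missing)}")
            )
        elif not eq_equal(s_def, o_def):
            report.items.append(
                (m.subject_id, (m.object_id,), "logical definitions differ")
            )
    return report


def report_logical_without_exact_mapping(
    manual: MappingSet, mp: Ontology, hp: Ontology
) -> DiscrepancyReport:
    """Pairs with identical logical definitions not manually mapped exact.

    Covers both pairs mapped with a weaker predicate and pairs absent
    from the manual set entirely.
    """
    report = DiscrepancyReport("logical_without_exact_mapping")
    manual_pred = {(m.subject_id, m.object_id): m.predicate for m in manual}
    for m in logical_match(mp, hp):
        pair = (m.subject_id, m.object_id)
        pred = manual_pred.get(pair)
        if pred is None:
            report.items.append((m.subject_id, (m.object_id,), "pair not manually mapped"))
        elif pred != EXACT_MATCH:
            report.items.append((m.subject_id, (m.object_id,), f"manual predicate is {pred}"))
    return report


def report_multi_exact_lexical(lexical: MappingSet) -> DiscrepancyReport:
    """Terms participating in two or more exact lexical matches.

    Checked on both sides: a subject matched exactly to several objects
    and an object matched exactly by several subjects are each one item.
    Such fan-outs usually indicate a synonym whose scope is too strong.
    """
    report = DiscrepancyReport("multi_exact_lexical")
    by_subject: dict[str, list[str]] = {}
    by_object: dict[str, list[str]] = {}
    for m in lexical:
        if m.predicate == EXACT_MATCH:
            by_subject.setdefault(m.subject_id, []).append(m.object_id)
            by_object.setdefault(m.object_id, []).append(m.subject_id)
    for subject in sorted(by_subject):
        objects = by_subject[subject]
        if len(objects) >= 2:
            report.items.append(
                (subject, tuple(sorted(objects)), f"{len(objects)} exact lexical matches")
            )
    for obj in sorted(by_object):
        subjects = by_object[obj]
        if len(subjects) >= 2:
            report.items.append(
                (obj, tuple(sorted(subjects)), f"{len(subjects)} exact lexical matches")
            )
    return report


def write_discrepancy_report(report: DiscrepancyReport) -> str:
    """TSV serialization: kind, term, counterpart term(s), detail."""
    lines = ["kind\tterm_id\tcounterparts\tdetail"]
    for subject, objects, detail in report.items:
        lines.append(f"{report.kind}\t{subject}\t{'|'.join(objects)}\t{detail}")
    return "\n".join(lines) + "\n"
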