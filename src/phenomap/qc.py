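"""Ontology quality-control checks.

Mirrors the dashboard-style checks relevant to mapping hygiene: terms
with missing text definitions, synonyms that duplicate the term label,
duplicate synonyms within one term, exact synonyms shared across terms
(ambiguous for lexical tools — the 'decreased PPI' acronym case), and
EQ definitions using relations outside the allowed set.

Checks report findings; they never raise.  Deprecated terms are exempt
(they are no longer curated and never matched).  Label/synonym
comparisons use the lexical normalizer, so they are case- and
punctuation-insensitive; this may be stricter than tools that compare
raw strings.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import FrozenSet

from .lexical import normalize_label
from .model import DEFAULT_EQ_RELATIONS, Ontology

__all__ = ["QCReport", "qc_check", "write_qc_report"]


@dataclass
class QCReport:
    missing_definitions: list[str] = field(default_factory=list)
    synonym_equals_label: list[tuple[str, str]] = field(default_factory=list)
    duplicate_synonyms_within_term: list[tuple[str, str]] = field(default_factory=list)
    shared_exact_synonyms: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    invalid_relations: list[tuple[str, str]] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.missing_definitions
            or self.synonym_equals_label
            or self.duplicate_synonyms_within_term
            or self.shared_exact_synonyms
            or self.invalid_relations
        )

    def n_findings(self) -> int:
        return (
            len(self.missing_definitions)
            + len(self.synonym_equals_label)
            + len(self.duplicate_synonyms_within_term)
            + len(self.shared_exact_synonyms)
            + len(self.invalid_relations)
        )


def qc_check(onto: Ontology, allowed_relations: FrozenSet[str] = DEFAULT_EQ_RELATIONS) -> QCReport:
    """Run all checks over the non-deprecated terms of one ontology."""
    report = QCReport()
    exact_index: dict[tuple[str, ...], dict[str, str]] = {}

    for term in sorted(onto.active_terms(), key=lambda t: t.id):
        if term.definition is None:
            report.missing_definitions.append(term.id)

        label_bag = normalize_label(term.label)
        seen_bags: set[tuple[str, ...]] = set()
        for syn in term.synonyms:
            bag = normalize_label(syn.text)
            if bag == label_bag:
                report.synonym_equals_label.append((term.id, syn.text))
            if bag in seen_bags:
                report.duplicate_synonyms_within_term.append((term.id, syn.text))
            seen_bags.add(bag)
            if syn.scope == "exact":
                exact_index.setdefault(bag, {}).setdefault(term.id, syn.text)

        if term.logical_def is not None:
            for rel, _filler in term.logical_def.modifiers:
                if rel not in allowed_relations:
                    report.invalid_relations.append((term.id, rel))

    for bag in sorted(exact_index):
        holders = exact_index[bag]
        if len(holders) >= 2:
            ids = tuple(sorted(holders))
            report.shared_exact_synonyms.append((holders[ids[0]], ids))
    return report


def write_qc_report(report: QCReport) -> str:
    """Serialize as TSV, one finding per row: check_id, term_id, detail."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["check_id", "term_id", "detail"])
    for tid in report.missing_definitions:
        writer.writerow(["missing_definition", tid, ""])
    for tid, text in report.synonym_equals_label:
        writer.writerow(["synonym_equals_label", tid, text])
    for tid, text in report.duplicate_synonyms_within_term:
        writer.writerow(["duplicate_synonym_within_term", tid, text])
    for text, ids in report.shared_exact_synonyms:
        writer.writerow(["shared_exact_synonym", "|".join(ids), text])
    for tid, rel in report.invalid_relations:
        writer.writerow(["invalid_relation", tid, rel])
    return out.getvalue()
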