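"""SSSOM TSV mapping sets, plus the free-text sign/symptom dialect.

The Simple Standard for Sharing Ontological Mappings (SSSOM) serializes
a mapping set as a ``#``-prefixed YAML metadata header followed by a
TSV table.  This module reads and writes the column subset used for
MP-HP phenotype mappings, and a modified dialect in which the subject is
a free-text sign/symptom description from the literature mapped to zero
or more MP and HP terms.

By curation convention the MP term is always the mapping subject and the
HP term the object, so ``skos:broadMatch`` states that the HP term is
the broader class.  Prefix enforcement can be relaxed with
``any_prefixes=True`` for other ontology pairs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import yaml

from .model import curie_prefix

__all__ = [
    "EXACT_MATCH",
    "NARROW_MATCH",
    "BROAD_MATCH",
    "CLOSE_MATCH",
    "RELATED_MATCH",
    "PREDICATES",
    "PREDICATE_PRIORITY",
    "METHODS",
    "Mapping",
    "MappingSet",
    "SymptomMapping",
    "read_sssom",
    "write_sssom",
    "read_symptom_table",
    "write_symptom_table",
    "SssomFormatError",
]

EXACT_MATCH = "skos:exactMatch"
NARROW_MATCH = "skos:narrowMatch"
BROAD_MATCH = "skos:broadMatch"
CLOSE_MATCH = "skos:closeMatch"
RELATED_MATCH = "skos:relatedMatch"

#: the five SKOS mapping predicates, case-sensitive
PREDICATES = (EXACT_MATCH, NARROW_MATCH, BROAD_MATCH, RELATED_MATCH, CLOSE_MATCH)

#: strongest-first order used when collapsing multiple predicates
PREDICATE_PRIORITY = (EXACT_MATCH, NARROW_MATCH, BROAD_MATCH, CLOSE_MATCH, RELATED_MATCH)

METHODS = ("manual", "logical", "lexical")

#: method enum <-> semapv mapping_justification tokens
_JUSTIFICATION = {
    "manual": "semapv:ManualMappingCuration",
    "logical": "semapv:LogicalReasoning",
    "lexical": "semapv:LexicalMatching",
}
_JUSTIFICATION_INV = {v: k for k, v in _JUSTIFICATION.items()}

_COLUMNS = (
    "subject_id",
    "subject_label",
    "predicate_id",
    "object_id",
    "object_label",
    "mapping_justification",
    "author_id",
    "mapping_date",
    "comment",
)
_REQUIRED_COLUMNS = ("subject_id", "predicate_id", "object_id")


class SssomFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Mapping:
    """One subject -> object mapping assertion."""

    subject_id: str
    predicate: str
    object_id: str
    subject_label: str = ""
    object_label: str = ""
    method: str = "manual"
    authors: tuple[str, ...] = ()
    mapping_date: str = ""
    comment: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(f"unknown mapping predicate {self.predicate!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown mapping method {self.method!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.subject_id, self.object_id, self.predicate, self.method)

    def with_comment(self, comment: str) -> "Mapping":
        return replace(self, comment=comment)


@dataclass
class MappingSet:
    """A list of mappings plus set-level metadata.

    Duplicate (subject, object, predicate, method) rows are rejected.
    ``subject_prefix``/``object_prefix`` pin the expected CURIE prefixes
    (MP subjects, HP objects by default) unless ``any_prefixes`` is set.
    """

    mappings: list[Mapping] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    extra_columns: tuple[str, ...] = ()
    subject_prefix: str = "MP"
    object_prefix: str = "HP"
    any_prefixes: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for m in self.mappings:
            if m.key in seen:
                raise ValueError(f"duplicate mapping row {m.key}")
            seen.add(m.key)
            if not self.any_prefixes:
                if curie_prefix(m.subject_id) != self.subject_prefix:
                    raise ValueError(
                        f"subject {m.subject_id} does not carry prefix "
                        f"{self.subject_prefix} (use any_prefixes to override)"
                    )
                if curie_prefix(m.object_id) != self.object_prefix:
                    raise ValueError(
                        f"object {m.object_id} does not carry prefix "
                        f"{self.object_prefix} (use any_prefixes to override)"
                    )

    def __len__(self) -> int:
        return len(self.mappings)

    def __iter__(self):
        return iter(self.mappings)

    def by_pair(self) -> dict[tuple[str, str], list[Mapping]]:
        pairs: dict[tuple[str, str], list[Mapping]] = {}
        for m in self.mappings:
            pairs.setdefault((m.subject_id, m.object_id), []).append(m)
        return pairs


def write_sssom(mapping_set: MappingSet) -> str:
    """Serialize a mapping set to SSSOM TSV.

    Deterministic: metadata keys and rows (by subject_id, object_id,
    then predicate/method) are sorted, so equal sets produce
    byte-identical documents.
    """
    out = io.StringIO()
    for key in sorted(mapping_set.metadata):
        out.write(f"# {key}: {mapping_set.metadata[key]}\n")
    columns = _COLUMNS + tuple(sorted(mapping_set.extra_columns))
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(columns)
    for m in sorted(
        mapping_set.mappings,
        key=lambda m: (m.subject_id, m.object_id, m.predicate, m.method),
    ):
        extras = dict(m.extras)
        row = [
            m.subject_id,
            m.subject_label,
            m.predicate,
            m.object_id,
            m.object_label,
            _JUSTIFICATION[m.method],
            "|".join(m.authors),
            m.mapping_date,
            m.comment,
        ] + [extras.get(c, "") for c in columns[len(_COLUMNS):]]
        writer.writerow(row)
    return out.getvalue()


def _split_header(text: str) -> tuple[dict, list[str]]:
    meta_lines, body = [], []
    for line in text.splitlines():
        if line.startswith("#"):
            meta_lines.append(line.lstrip("#").strip())
        elif line.strip():
            body.append(line)
    metadata = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    return (metadata or {}), body


def read_sssom(text: str, any_prefixes: bool = False) -> MappingSet:
    """Parse an SSSOM TSV document.

    Unknown columns are preserved per-row and on the set, so reading and
    rewriting a file with extra columns is lossless.  Predicate values
    are matched case-sensitively against the SKOS CURIEs; anything else
    (including a case variant such as ``skos:exactmatch``) is a row
    error.
    """
    metadata, body = _split_header(text)
    if not body:
        raise SssomFormatError("document has no column header row")
    reader = csv.DictReader(body, delimiter="\t")
    columns = reader.fieldnames or []
    for col in _REQUIRED_COLUMNS:
        if col not in columns:
            raise SssomFormatError(f"missing required column {col!r}")
    extra_columns = tuple(c for c in columns if c not in _COLUMNS)

    mappings = []
    prefixes: set[tuple[str, str]] = set()
    for i, row in enumerate(reader, start=2):  # row 1 is the column header
        predicate = row["predicate_id"]
        if predicate not in PREDICATES:
            raise SssomFormatError(f"row {i}: invalid predicate_id {predicate!r}")
        justification = row.get("mapping_justification", "")
        if justification and justification not in _JUSTIFICATION_INV:
            raise SssomFormatError(
                f"row {i}: unknown mapping_justification {justification!r}"
            )
        method = _JUSTIFICATION_INV.get(justification, "manual")
        authors = tuple(a for a in (row.get("author_id") or "").split("|") if a)
        mappings.append(
            Mapping(
                subject_id=row["subject_id"],
                subject_label=row.get("subject_label", "") or "",
                predicate=predicate,
                object_id=row["object_id"],
                object_label=row.get("object_label", "") or "",
                method=method,
                authors=authors,
                mapping_date=row.get("mapping_date", "") or "",
                comment=row.get("comment", "") or "",
                extras=tuple((c, row.get(c, "") or "") for c in extra_columns),
            )
        )
        prefixes.add((curie_prefix(row["subject_id"]), curie_prefix(row["object_id"])))

    subject_prefix = "MP"
    object_prefix = "HP"
    if len(prefixes) == 1:
        subject_prefix, object_prefix = next(iter(prefixes))
    elif len(prefixes) > 1:
        any_prefixes = True
    return MappingSet(
        mappings,
        metadata=metadata,
        extra_columns=extra_columns,
        subject_prefix=subject_prefix,
        object_prefix=object_prefix,
        any_prefixes=any_prefixes,
    )


# ---------------------------------------------------------------------------
# free-text sign/symptom dialect


@dataclass(frozen=True)
class SymptomMapping:
    """A literature sign/symptom description mapped to MP and/or HP terms.

    Either term list may be empty: not every sign or symptom has a
    matching term in both ontologies (brain fog has HP terms only).
    """

    description: str
    mp_ids: tuple[str, ...] = ()
    hp_ids: tuple[str, ...] = ()
    source_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError("symptom description must be non-empty")


_SYMPTOM_COLUMNS = ("description", "mp_ids", "hp_ids", "source_refs")


def write_symptom_table(rows: Iterable[SymptomMapping], metadata: Optional[dict] = None) -> str:
    out = io.StringIO()
    for key in sorted(metadata or {}):
        out.write(f"# {key}: {metadata[key]}\n")
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_SYMPTOM_COLUMNS)
    for r in rows:
        writer.writerow(
            [r.description, "|".join(r.mp_ids), "|".join(r.hp_ids), "|".join(r.source_refs)]
        )
    return out.getvalue()


def read_symptom_table(text: str) -> list[SymptomMapping]:
    _, body = _split_header(text)
    if not body:
        raise SssomFormatError("document has no column header row")
    reader = csv.DictReader(body, delimiter="\t")
    for col in _SYMPTOM_COLUMNS:
        if col not in (reader.fieldnames or []):
            raise SssomFormatError(f"missing required column {col!r}")
    rows = []
    for i, row in enumerate(reader, start=2):
        if not (row["description"] or "").strip():
            raise SssomFormatError(f"row {i}: empty symptom description")
        split = lambda v: tuple(x for x in (v or "").split("|") if x)
        rows.append(
            SymptomMapping(
                description=row["description"],
                mp_ids=split(row["mp_ids"]),
                hp_ids=split(row["hp_ids"]),
                source_refs=split(row["source_refs"]),
            )
        )
    return rows
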