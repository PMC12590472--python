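"""Design-pattern generation of EQ logical definitions.

A pattern is a template built from constant and variable ontology
terms.  The canonical example, ``abnormalMorphologyOfPartOfAnatomicalEntity``,
fixes the PATO constants 'morphology' (PATO:0000051) and 'abnormal'
(PATO:0000460) and declares one variable, an anatomical entity that
must come from Uberon::

    pattern_id: abnormalMorphologyOfPartOfAnatomicalEntity
    variables:
      anatomical_entity: UBERON
    template:
      genus: PATO:0000051
      modifiers:
        - relation: RO:0002314      # characteristic_of_part_of
          filler: anatomical_entity
        - relation: RO:0002573      # has_modifier
          filler: PATO:0000460

Filler tables bind the variables per term (one spreadsheet row per
term).  Applying a pattern *replaces* any existing logical definition of
each listed term with the instantiated template; labels, definitions and
synonyms are never generated (they remain curated by hand).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .model import EQExpression, Ontology, curie_prefix, is_curie

__all__ = [
    "Pattern",
    "FillerTable",
    "FillerViolation",
    "parse_pattern",
    "read_filler_table",
    "write_filler_table",
    "validate_filler_table",
    "apply_pattern",
    "PatternError",
]


class PatternError(ValueError):
    pass


def _is_constant(value: str) -> bool:
    # constants are CURIEs; anything else is a variable name
    return ":" in value


@dataclass(frozen=True)
class Pattern:
    """A logical-definition template of constants and variables."""

    pattern_id: str
    variables: tuple[tuple[str, str], ...]  # (name, required ontology prefix)
    genus: str  # constant CURIE or variable name
    modifiers: tuple[tuple[str, str], ...]  # (relation CURIE, constant-or-variable)

    def __post_init__(self) -> None:
        declared = {name for name, _ in self.variables}
        used = {v for v in (self.genus, *(f for _, f in self.modifiers)) if not _is_constant(v)}
        undeclared = used - declared
        if undeclared:
            raise PatternError(
                f"{self.pattern_id}: undeclared template variables {sorted(undeclared)}"
            )
        for v in (self.genus, *(f for _, f in self.modifiers)):
            if _is_constant(v) and not is_curie(v):
                raise PatternError(f"{self.pattern_id}: malformed constant CURIE {v!r}")

    @property
    def variable_prefixes(self) -> dict[str, str]:
        return dict(self.variables)

    def instantiate(self, bindings: dict[str, str]) -> EQExpression:
        def resolve(v: str) -> str:
            return v if _is_constant(v) else bindings[v]

        return EQExpression(
            resolve(self.genus),
            tuple((rel, resolve(f)) for rel, f in self.modifiers),
        )


def parse_pattern(text: str) -> Pattern:
    """Load a pattern from its YAML serialization."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise PatternError("pattern document must be a mapping")
    try:
        template = doc["template"]
        return Pattern(
            pattern_id=str(doc["pattern_id"]),
            variables=tuple(sorted((str(k), str(v)) for k, v in (doc.get("variables") or {}).items())),
            genus=str(template["genus"]),
            modifiers=tuple(
                (str(m["relation"]), str(m["filler"])) for m in template.get("modifiers", [])
            ),
        )
    except KeyError as e:
        raise PatternError(f"pattern document missing key {e}") from None


def write_pattern(pattern: Pattern) -> str:
    doc = {
        "pattern_id": pattern.pattern_id,
        "variables": dict(pattern.variables),
        "template": {
            "genus": pattern.genus,
            "modifiers": [{"relation": r, "filler": f} for r, f in pattern.modifiers],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


@dataclass
class FillerTable:
    """Per-term variable bindings for one pattern (one spreadsheet row per term)."""

    pattern_id: str
    rows: list[tuple[str, dict[str, str]]] = field(default_factory=list)


@dataclass(frozen=True)
class FillerViolation:
    row: int  # 1-based data row number
    term_id: str
    variable: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row} ({self.term_id}), variable {self.variable!r}: {self.message}"


def validate_filler_table(pattern: Pattern, table: FillerTable) -> list[FillerViolation]:
    """Check that every row binds every declared variable with an
    allowed-prefix CURIE; returns one violation per defect (empty list
    means the table fits the pattern)."""
    violations = []
    prefixes = pattern.variable_prefixes
    for i, (term_id, bindings) in enumerate(table.rows, start=1):
        for name, required_prefix in pattern.variables:
            value = bindings.get(name, "")
            if not value:
                violations.append(FillerViolation(i, term_id, name, "missing binding"))
            elif not is_curie(value):
                violations.append(
                    FillerViolation(i, term_id, name, f"filler {value!r} is not a CURIE")
                )
            elif curie_prefix(value) != required_prefix:
                violations.append(
                    FillerViolation(
                        i,
                        term_id,
                        name,
                        f"filler {value} has prefix {curie_prefix(value)}, "
                        f"expected {required_prefix}",
                    )
                )
        for name in bindings:
            if name not in prefixes:
                violations.append(FillerViolation(i, term_id, name, "variable not declared"))
    return violations


def apply_pattern(pattern: Pattern, table: FillerTable, onto: Ontology) -> Ontology:
    """Instantiate the pattern for every table row, replacing each listed
    term's logical definition in place.

    Idempotent, and touches nothing but ``logical_def`` on the listed
    terms.  Raises on any filler-table violation or unknown term id.
    """
    if table.pattern_id != pattern.pattern_id:
        raise PatternError(
            f"filler table is for pattern {table.pattern_id!r}, not {pattern.pattern_id!r}"
        )
    violations = validate_filler_table(pattern, table)
    if violations:
        raise PatternError(
            "filler table does not fit pattern:\n" + "\n".join(str(v) for v in violations)
        )
    missing = [tid for tid, _ in table.rows if tid not in onto]
    if missing:
        raise PatternError(f"term ids not in ontology: {missing}")
    for term_id, bindings in table.rows:
        onto[term_id].logical_def = pattern.instantiate(bindings)
    return onto


def write_filler_table(table: FillerTable, variables: Iterable[str]) -> str:
    columns = ["term_id"] + sorted(variables)
    out = io.StringIO()
    out.write(f"# pattern_id: {table.pattern_id}\n")
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(columns)
    for term_id, bindings in table.rows:
        writer.writerow([term_id] + [bindings.get(c, "") for c in columns[1:]])
    return out.getvalue()


def read_filler_table(text: str) -> FillerTable:
    """Read a filler TSV: a ``# pattern_id:`` header line, then a
    ``term_id`` column plus one column per variable."""
    pattern_id = ""
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("pattern_id:"):
                pattern_id = stripped.split(":", 1)[1].strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise PatternError("filler table has no header row")
    reader = csv.DictReader(body, delimiter="\t")
    if "term_id" not in (reader.fieldnames or []):
        raise PatternError("filler table missing required column 'term_id'")
    rows = []
    for row in reader:
        term_id = row.pop("term_id")
        rows.append((term_id, {k: v for k, v in row.items() if v}))
    return FillerTable(pattern_id=pattern_id, rows=rows)
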