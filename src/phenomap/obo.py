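"""Reader and writer for a flat-file OBO dialect.

Supported ``[Term]`` tags: id, name, def, synonym (with
EXACT/NARROW/BROAD/RELATED scope), is_a, intersection_of, is_obsolete,
replaced_by, created_by, creation_date.  Any other tag is preserved
verbatim as an opaque annotation so that parse -> write round-trips the
dialect subset field-for-field.  Obsolete terms are written with the
conventional "obsolete " label prefix, which the parser strips again.

intersection_of lines encode EQ logical definitions: a bare CURIE line
is the genus quality, a "relation filler" line is one modifier clause::

    intersection_of: PATO:0000051
    intersection_of: RO:0002314 UBERON:0002387
    intersection_of: RO:0002573 PATO:0000460
"""

from __future__ import annotations

import re
from typing import Optional

from .model import EQExpression, Ontology, Synonym, Term, curie_prefix

__all__ = ["parse_obo", "write_obo", "OboParseError"]

_KNOWN_TAGS = {
    "id",
    "name",
    "def",
    "synonym",
    "is_a",
    "intersection_of",
    "is_obsolete",
    "replaced_by",
    "created_by",
    "creation_date",
}

_OBSOLETE_PREFIX = "obsolete "

# `"text" [xrefs]` with backslash escapes inside the quotes
_QUOTED_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(.*)$')
_SCOPE_KEYWORDS = {"EXACT": "exact", "NARROW": "narrow", "BROAD": "broad", "RELATED": "related"}


class OboParseError(ValueError):
    pass


def _unescape(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _parse_quoted(value: str, where: str) -> tuple[str, str]:
    m = _QUOTED_RE.match(value.strip())
    if not m:
        raise OboParseError(f"{where}: expected a quoted string, got {value!r}")
    return _unescape(m.group(1)), m.group(2).strip()


def _strip_comment(line: str) -> str:
    # OBO trailing comments start with ' !'; keep it simple: split outside quotes
    out = []
    in_quote = False
    i = 0
    while i < len(line):
        c = line[i]
        if c == "\\" and in_quote:
            out.append(line[i : i + 2])
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        if c == "!" and not in_quote:
            break
        out.append(c)
        i += 1
    return "".join(out).rstrip()


def parse_obo(text: str, prefix: Optional[str] = None) -> Ontology:
    """Parse an OBO-dialect document into an :class:`Ontology`.

    ``prefix`` overrides the namespace; otherwise it is taken from the
    ``ontology:`` header line or inferred from the first term id.
    """
    header_prefix: Optional[str] = None
    stanzas: list[list[str]] = []
    current: Optional[list[str]] = None
    in_term = False
    for raw in text.splitlines():
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            if in_term:
                current = []
                stanzas.append(current)
            else:
                current = None
            continue
        if current is not None:
            current.append(line)
        elif not in_term and ":" in line and not stanzas:
            tag, value = line.split(":", 1)
            if tag.strip() == "ontology":
                header_prefix = value.strip().upper()

    terms = []
    for ordinal, stanza in enumerate(stanzas, start=1):
        terms.append(_parse_term_stanza(stanza, ordinal))

    if prefix is None:
        if header_prefix:
            prefix = header_prefix
        elif terms:
            prefix = curie_prefix(terms[0].id)
        else:
            prefix = "NONE"

    onto = Ontology(prefix)
    for t in terms:
        try:
            onto.add_term(t)
        except ValueError as e:
            raise OboParseError(str(e)) from None
    return onto


def _parse_term_stanza(lines: list[str], ordinal: int) -> Term:
    fields: dict = {
        "id": None,
        "label": "",
        "definition": None,
        "synonyms": [],
        "parents": [],
        "deprecated": False,
        "replaced_by": None,
        "contributors": [],
        "creation_date": None,
        "annotations": [],
    }
    genus: Optional[str] = None
    modifiers: list[tuple[str, str]] = []
    where = f"[Term] stanza #{ordinal}"

    for line in lines:
        if ":" not in line:
            raise OboParseError(f"{where}: malformed line {line!r}")
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            fields["id"] = value
            where = f"[Term] stanza #{ordinal} ({value})"
        elif tag == "name":
            fields["label"] = value
        elif tag == "def":
            fields["definition"], _ = _parse_quoted(value, where)
        elif tag == "synonym":
            stext, rest = _parse_quoted(value, where)
            scope = "related"
            for token in rest.split():
                if token in _SCOPE_KEYWORDS:
                    scope = _SCOPE_KEYWORDS[token]
                    break
            fields["synonyms"].append(Synonym(stext, scope))
        elif tag == "is_a":
            fields["parents"].append(value.split()[0])
        elif tag == "intersection_of":
            parts = value.split()
            if len(parts) == 1:
                genus = parts[0]
            elif len(parts) == 2:
                modifiers.append((parts[0], parts[1]))
            else:
                raise OboParseError(f"{where}: malformed intersection_of {value!r}")
        elif tag == "is_obsolete":
            fields["deprecated"] = value.lower() == "true"
        elif tag == "replaced_by":
            fields["replaced_by"] = value
        elif tag == "created_by":
            fields["contributors"].append(value)
        elif tag == "creation_date":
            fields["creation_date"] = value
        else:
            fields["annotations"].append((tag, value))

    if fields["id"] is None:
        raise OboParseError(f"[Term] stanza #{ordinal}: missing id tag")
    if genus is not None:
        fields["logical_def"] = EQExpression(genus, tuple(modifiers))
    elif modifiers:
        raise OboParseError(f"{where}: intersection_of modifiers without a genus line")
    if fields["deprecated"] and fields["label"].startswith(_OBSOLETE_PREFIX):
        fields["label"] = fields["label"][len(_OBSOLETE_PREFIX):]
    try:
        return Term(**fields)
    except ValueError as e:
        raise OboParseError(f"{where}: {e}") from None


def write_obo(onto: Ontology, header_comments: tuple[str, ...] = ()) -> str:
    """Serialize an ontology to the OBO dialect.

    Deterministic: terms sorted by id, tags in a fixed order, so the same
    ontology always produces a byte-identical document.
    """
    out: list[str] = []
    for c in header_comments:
        out.append(f"! {c}")
    out.append("format-version: 1.2")
    out.append(f"ontology: {onto.prefix.lower()}")
    for term_id in sorted(onto.terms):
        t = onto.terms[term_id]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {t.id}")
        label = f"{_OBSOLETE_PREFIX}{t.label}" if t.deprecated and t.label else t.label
        if label:
            out.append(f"name: {label}")
        if t.definition is not None:
            out.append(f'def: "{_escape(t.definition)}" []')
        for s in t.synonyms:
            out.append(f'synonym: "{_escape(s.text)}" {s.scope.upper()} []')
        for p in t.parents:
            out.append(f"is_a: {p}")
        if t.logical_def is not None:
            out.append(f"intersection_of: {t.logical_def.genus}")
            for rel, filler in t.logical_def.modifiers:
                out.append(f"intersection_of: {rel} {filler}")
        if t.deprecated:
            out.append("is_obsolete: true")
        if t.replaced_by is not None:
            out.append(f"replaced_by: {t.replaced_by}")
        for c in t.contributors:
            out.append(f"created_by: {c}")
        if t.creation_date is not None:
            out.append(f"creation_date: {t.creation_date}")
        for tag, value in t.annotations:
            out.append(f"{tag}: {value}")
    return "\n".join(out) + "\n"
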