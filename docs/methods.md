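# Methods

## Scope and model

`phenomap` operates on *paired* phenotype ontologies: a species-spanning
subject ontology (MP-style) and a human-specific object ontology
(HPO-style). By convention every mapping is asserted with the MP-side
term as subject and the HP-side term as object, so the directional SKOS
predicates read: `skos:narrowMatch` — the HP term covers a narrower
concept than the MP term; `skos:broadMatch` — a broader one. The
toolkit deliberately automates only the mechanical parts of alignment
(string matching, logical-definition comparison, set merging, QC
scans); everything it cannot decide is emitted as a report for human
review, never auto-repaired.

The in-memory model is intentionally small: terms with a CURIE id,
label, optional text definition, scoped synonyms
(exact/narrow/broad/related), is_a parents, an optional EQ logical
definition, deprecation state and contributor/date metadata. Unknown
OBO tags are carried as opaque `(tag, value)` pairs so that documents
round-trip. Identifier persistence is a hard invariant: no operation
ever removes an id from an ontology; obsoletion flips a flag.

## Lexical matching

Normalization lowercases, maps the punctuation set `,;:.()/'-` to
spaces, splits on whitespace, and keeps token *multiplicity* (the bag
for "Cleft lip, cleft palate" contains "cleft" twice). Two strings
match iff their bags are equal — word-based, order-free, with no
stemming and no spelling normalization (British variants are expected
to be synonyms, not spelling-folded). The normalizer is the single
comparison primitive shared by the matcher and the QC checks, so QC is
case/punctuation-insensitive too; raw-string tools may report slightly
differently.

The scope→predicate matrix treats a term label and an exact synonym as
interchangeable ("label-ish"): label-ish × label-ish is exact; an MP
narrow synonym against a label-ish HP field is narrowMatch, and an MP
label-ish field against an HP broad synonym is also narrowMatch (both
say the HP string names the narrower concept); the two mirrored cells
are broadMatch. Every cell involving a related synonym, and the
scoped×scoped cells (narrow×narrow, narrow×broad, ...), carry too
little directional information and degrade to relatedMatch.
`skos:closeMatch` is never emitted lexically; it is reserved for manual
curation. This makes the matrix *dual*: swapping subject and object
ontologies exchanges narrowMatch and broadMatch and fixes
exact/related, which is property-tested.

Multiple field-level hits for one (subject, object) pair collapse to a
single mapping keeping the strongest predicate
(exact > narrow > broad > related). Deprecated terms never participate.

## Logical definitions and patterns

An EQ expression is a genus quality CURIE plus a set of
(relation, filler) modifier pairs. Canonicalization sorts and
de-duplicates the modifiers; two definitions are equal iff their
canonical forms are identical. Relations are compared as opaque CURIEs
— `characteristic_of` (RO:0000053) vs `characteristic_of_part_of`
(RO:0002314) is a real difference, and no reasoning over relation or
class hierarchies is attempted. Logical matching therefore emits
exactMatch only; subsumption-based narrow/broad logical matches are out
of scope. A consequence worth stating: identical logical definitions do
not imply identical meaning (the textual definition may carry nuances
the EQ form lacks, as with 'polycystic kidney' vs 'Polycystic kidney
dysplasia'), which is why logical matches that contradict the manual
mapping are *reported*, not resolved.

Patterns are serialized in a minimal YAML form (pattern id, variables
with required ontology prefixes, a template whose genus and fillers are
either constant CURIEs or variable names); a value is a constant iff it
contains a colon. Full DOSDP is out of scope, as is generating labels,
text definitions or synonyms from patterns. Filler tables are TSV
(`term_id` plus one column per variable) and are validated before
application: missing bindings, non-CURIE fillers, wrong-prefix fillers
and undeclared variables each produce one violation. Application
replaces the target term's logical definition wholesale and touches
nothing else; it is idempotent by construction.

## SSSOM dialects

The writer emits a sorted `#`-commented metadata header, a fixed column
set (`subject_id, subject_label, predicate_id, object_id, object_label,
mapping_justification, author_id, mapping_date, comment`, then sorted
extra columns), and rows sorted by subject, object, predicate, method —
so equal sets serialize byte-identically. `mapping_justification` uses
the semapv tokens (`semapv:LexicalMatching`, `semapv:LogicalReasoning`,
`semapv:ManualMappingCuration`); the stored three-valued method enum is
the source of truth. Predicates are matched case-sensitively
(`skos:exactmatch` is a row error, with the row number in the message).
Multi-author cells are pipe-delimited ORCIDs. Unknown columns are
preserved per-row. Full LinkML-schema validation is a non-goal.

The sign/symptom dialect replaces the subject CURIE with a free-text
description column plus pipe-delimited MP-id, HP-id and source-citation
columns; either id list may be empty, since not every sign has a
counterpart in both ontologies. An empty description is an error.

## Merging and discrepancy reports

Merging collapses per (subject, object) *pair* — not per subject —
keeping the row ranked first by method priority
(manual > logical > lexical), then predicate priority within the
winning method. closeMatch is slotted between broad and related in the
default predicate order: a directional assertion carries more
information than "close", and "close" more than "related"; the order is
a `MergePolicy` field, so callers can disagree. Superseded rows are
recorded in the winner's comment, sorted; a pair with a single
candidate passes through byte-identical. These two choices make the
merge exactly idempotent and input-order invariant, which is asserted
on random triples rather than argued.

Three reports reproduce the curation workflows: (1) manual exactMatch
pairs whose logical definitions are absent on either side or unequal;
(2) pairs with identical logical definitions whose manual predicate is
not exact, or that are not manually mapped at all; (3) terms on either
side participating in ≥2 exact lexical matches (usually a synonym whose
scope is too strong).

## Synthetic fixtures

`generate_fixture_pair(seed, n_planted_per_cell, n_decoys)` builds what
the matcher's contract needs and nothing more: for each of the 25 cells
of the field×field matrix it plants pairs whose only shared token bag
sits exactly in that cell's fields, so the expected predicate is the
matrix entry; phrases are drawn from a built-in anatomical vocabulary
(20 adjectives × 40 nouns, 2–3 tokens per phrase) under a global
bag-uniqueness check, so no accidental matches exist and planted truth
is recoverable with precision = recall = 1. Decoys take a proper token
subset of a planted phrase plus one extra noun — they share words but
never a whole bag, probing the all-words rule's boundary. HP-side
strings are capitalized to exercise case normalization. Every term gets
a definition and a root parent so the fixtures are QC-clean.

What the generator does **not** emulate: real label morphology
(plurals, "Hypospadias" vs "hypospadia" near-misses), deep is_a
hierarchies, multi-synonym terms, cross-ontology vocabulary skew, or
realistic EQ definitions. Passing recovery tests therefore demonstrates
the matcher implements its stated rule exactly — not that the rule has
any particular precision on full MP/HPO releases, where curated
mapping counts depend on external ontology versions and are out of
scope here.

Default fixture sizes (3 pairs per cell = 75 planted mappings, 20
decoys) keep every generated pair in the low hundreds of terms; the
full acceptance run — 10 recovery seeds, 100 duality fixtures, 100
round-trip fixtures, 100 merge triples — completes in about a second.

## Numerical and degenerate-input choices

- Ties in merging cannot occur between distinct rows of equal rank
  (rank is a function of the dedup key); candidate order is still made
  deterministic by a full-key sort.
- Empty documents parse to empty objects; empty ontologies write
  header-only documents; a zero-size fixture request returns genuinely
  empty ontologies with no root terms.
- Dangling is_a parents are reported (`Ontology.dangling_parents`),
  never fatal — fragments are normal inputs.
- The OBO writer emits the conventional "obsolete " label prefix on
  deprecated terms; the parser strips it, so the prefix is a
  serialization detail, not model state.
- CLI outputs embed the tool version and the run's parameters in file
  headers, and never embed wall-clock timestamps, so identical
  invocations are byte-identical.

## Known limitations

No OWL parsing or reasoning; no fuzzy or embedding similarity; no
release-pipeline automation (imports, builds, dashboards); discrepancy
reports are advisory and nothing is auto-repaired; the SSSOM reader
handles flat metadata headers only (nested YAML blocks such as
`curie_map` are not reconstructed).
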