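# phenomap

Cross-species phenotype ontology mapping toolkit, built around the
alignment machinery between the Mammalian Phenotype Ontology (MP, used
to annotate mouse models) and the Human Phenotype Ontology (HPO, used
for patient and disease phenotypes). Automated translation between the
two vocabularies needs term-to-term mappings; `phenomap` implements the
pieces of that workflow that are mechanical, leaving the judgments to
curators:

- **Lexical matching** — labels and synonyms are reduced to lowercased
  token multisets ("all the words must match"), and each hit is
  classified with a SKOS mapping predicate from the synonym scopes of
  the two matched fields. With the MP term as subject and the HP term
  as object: label/exact × label/exact → `skos:exactMatch`; an MP
  narrow synonym against an HP label/exact synonym → `skos:narrowMatch`
  (the HP term is the narrower concept); the mirrored cells →
  `skos:broadMatch`; ambiguous cells and related synonyms →
  `skos:relatedMatch`.
- **Logical matching** — terms carrying identical entity–quality (EQ)
  logical definitions (a PATO quality genus plus `(relation, filler)`
  modifier clauses, e.g. *increased size* and *characteristic_of* some
  *pes* and *has_modifier* some *abnormal*) are mapped `skos:exactMatch`
  with method `logical`.
- **SSSOM I/O** — mapping sets read/written as SSSOM TSV (YAML-style
  `#` metadata header + one row per mapping), plus a modified dialect
  for free-text sign/symptom descriptions mapped to MP and HP term
  lists.
- **Harmonization** — merging manual, logical and lexical sets to one
  row per term pair with priority `manual > logical > lexical`, then
  `exact > narrow > broad > close > related`; and discrepancy reports
  for curator review (exact mappings whose logical definitions
  disagree, identical logical definitions not mapped exact, terms with
  multiple exact lexical matches).
- **Pattern-driven logical definitions** — uPheno-style templates of
  constant and variable ontology terms, instantiated from per-term
  filler tables; applying a pattern replaces any existing logical
  definition.
- **Ontology QC and editing** — missing definitions, synonyms equal to
  labels, duplicate synonyms, exact synonyms shared across terms,
  invalid EQ relations; plus obsoletion-with-merge that never deletes
  an identifier.
- **Fixture generator** — seeded paired mini-ontologies with a planted
  ground-truth mapping set covering every cell of the match matrix,
  plus near-miss decoys.

## Worked example

The classic double-match case: the MP term *decreased bone mineral
density* carries exact synonyms "osteopenia" and "reduced bone mineral
density", each of which names its own HPO term.

```python
from phenomap import Ontology, Term, Synonym, lexical_match

mp = Ontology("MP")
mp.add_term(Term("MP:0000063", label="decreased bone mineral density",
                 synonyms=[Synonym("osteopenia", "exact"),
                           Synonym("reduced bone mineral density", "exact")]))
hp = Ontology("HP")
hp.add_term(Term("HP:0000938", label="Osteopenia"))
hp.add_term(Term("HP:0004349", label="Reduced bone mineral density"))

for m in lexical_match(mp, hp):
    print(m.subject_id, m.predicate, m.object_id)
```

prints

```
MP:0000063 skos:exactMatch HP:0000938
MP:0000063 skos:exactMatch HP:0004349
```

— one MP term with *two* exact matches, which
`report_multi_exact_lexical` flags for review. Demoting the
"osteopenia" synonym to narrow scope and rerunning turns the first line
into `MP:0000063 skos:narrowMatch HP:0000938`: the synonym scope, not
the string, decides the predicate.

The same pipeline is available from the shell:

```bash
phenomap fixtures --seed 1 -o fix/
phenomap lexmatch --mp fix/mp.obo --hp fix/hp.obo -o lex.sssom.tsv
phenomap merge manual.sssom.tsv lex.sssom.tsv -o merged.sssom.tsv
phenomap qc --input fix/mp.obo -o qc.tsv
```

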