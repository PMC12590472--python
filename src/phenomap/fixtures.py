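"""Seeded generator of paired mini-ontologies with known ground truth.

``generate_fixture_pair`` builds an MP-like and an HP-like ontology plus
the mapping set a perfect lexical matcher must recover.  For every cell
of the synonym-scope match matrix (label/exact/narrow/broad/related on
each side) it plants term pairs whose only shared token bag sits exactly
in that pair of fields, so the expected predicate of each planted
mapping is the matrix cell.  Decoy terms share at least one token with
some planted phrase but never a whole bag, probing the boundary of the
"all the words must match" rule.

Phrases are drawn from a built-in anatomical vocabulary with a global
bag-uniqueness check, so no accidental matches arise; HP-side strings
are capitalized the way HPO labels are, which exercises case
normalization.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from itertools import product

from .lexical import MATCH_FIELDS, classify_pair, normalize_label
from .model import Ontology, Synonym, Term
from .sssom import Mapping, MappingSet

__all__ = ["generate_fixture_pair", "ADJECTIVES", "NOUNS"]

ADJECTIVES = (
    "abnormal", "increased", "decreased", "small", "enlarged", "dilated",
    "short", "long", "thick", "thin", "fused", "absent", "cystic", "pale",
    "dense", "curved", "ectopic", "premature", "delayed", "irregular",
)
NOUNS = (
    "kidney", "heart", "femur", "palate", "retina", "cortex", "sperm",
    "alveolus", "spleen", "liver", "cornea", "tail", "vertebra", "molar",
    "thymus", "aorta", "urethra", "eyelid", "tongue", "ureter", "pancreas",
    "mandible", "humerus", "sternum", "patella", "ovary", "testis", "islet",
    "gland", "duct", "lobe", "valve", "septum", "follicle", "crypt",
    "villus", "nephron", "neuron", "axon", "tendon",
)

_MP_ROOT = "MP:0000001"
_HP_ROOT = "HP:0000001"


def _capitalize(text: str) -> str:
    return text[0].upper() + text[1:]


def generate_fixture_pair(
    seed: int, n_planted_per_cell: int = 3, n_decoys: int = 20
) -> tuple[Ontology, Ontology, MappingSet]:
    """Build (MP-like ontology, HP-like ontology, ground-truth mapping set).

    Plants ``n_planted_per_cell`` matching term pairs per match-matrix
    cell and ``n_decoys`` near-miss terms (alternating sides).  With
    both counts zero, returns two empty ontologies and an empty set.
    """
    if n_planted_per_cell < 0 or n_decoys < 0:
        raise ValueError("fixture sizes must be non-negative")
    rng = random.Random(seed)
    mp = Ontology("MP")
    hp = Ontology("HP")
    truth: list[Mapping] = []
    used_bags: set[tuple[str, ...]] = set()

    def fresh_phrase() -> str:
        while True:
            words = [rng.choice(ADJECTIVES)] + rng.sample(NOUNS, k=rng.randint(1, 2))
            bag = tuple(sorted(words))
            if bag not in used_bags:
                used_bags.add(bag)
                return " ".join(words)

    if n_planted_per_cell == 0 and n_decoys == 0:
        return mp, hp, MappingSet(metadata={"mapping_set_id": "fixture-truth", "seed": seed})

    mp.add_term(Term(_MP_ROOT, label="mammalian phenotype", definition="Root term."))
    hp.add_term(Term(_HP_ROOT, label="Phenotypic abnormality", definition="Root term."))
    used_bags.add(normalize_label("mammalian phenotype"))
    used_bags.add(normalize_label("Phenotypic abnormality"))

    counter = 10
    planted_bags: list[tuple[str, ...]] = []
    for s_field, o_field in product(MATCH_FIELDS, MATCH_FIELDS):
        for _ in range(n_planted_per_cell):
            phrase = fresh_phrase()
            planted_bags.append(normalize_label(phrase))
            mp_id = f"MP:{counter:07d}"
            hp_id = f"HP:{counter:07d}"
            counter += 1

            if s_field == "label":
                mp_label, mp_syns = phrase, []
            else:
                mp_label = fresh_phrase()
                mp_syns = [Synonym(phrase, s_field)]
            mp.add_term(
                Term(
                    mp_id,
                    label=mp_label,
                    definition=f"Any anomaly of the {phrase}.",
                    synonyms=mp_syns,
                    parents=[_MP_ROOT],
                )
            )

            if o_field == "label":
                hp_label, hp_syns = _capitalize(phrase), []
            else:
                hp_label = _capitalize(fresh_phrase())
                hp_syns = [Synonym(_capitalize(phrase), o_field)]
            hp.add_term(
                Term(
                    hp_id,
                    label=hp_label,
                    definition=f"A human anomaly of the {phrase}.",
                    synonyms=hp_syns,
                    parents=[_HP_ROOT],
                )
            )

            truth.append(
                Mapping(
                    subject_id=mp_id,
                    subject_label=mp_label,
                    predicate=classify_pair(s_field, o_field),
                    object_id=hp_id,
                    object_label=hp_label,
                    method="lexical",
                )
            )

    for j in range(n_decoys):
        while True:
            base = list(rng.choice(planted_bags))
            keep = rng.randint(1, len(base) - 1)
            tokens = rng.sample(base, k=keep) + [rng.choice(NOUNS)]
            bag = tuple(sorted(tokens))
            if bag not in used_bags:
                used_bags.add(bag)
                break
        phrase = " ".join(tokens)
        if j % 2 == 0:
            mp.add_term(
                Term(
                    f"MP:{counter:07d}",
                    label=phrase,
                    definition=f"Decoy phenotype of the {phrase}.",
                    parents=[_MP_ROOT],
                )
            )
        else:
            hp.add_term(
                Term(
                    f"HP:{counter:07d}",
                    label=_capitalize(phrase),
                    definition=f"Decoy phenotype of the {phrase}.",
                    parents=[_HP_ROOT],
                )
            )
        counter += 1

    truth.sort(key=lambda m: (m.subject_id, m.object_id))
    truth_set = MappingSet(
        truth, metadata={"mapping_set_id": "fixture-truth", "seed": seed}
    )
    return mp, hp, truth_set
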