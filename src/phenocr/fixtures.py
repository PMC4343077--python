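"""Self-contained synthetic fixtures: a miniature HPO-style ontology and a
small gold corpus exercising the annotation conventions.

The fixture ontology is a synthetic stand-in for the full Human Phenotype
Ontology: a few dozen terms under a category skeleton rooted at
HP:0000118 (Phenotypic abnormality), carrying the labels and synonyms the
worked examples need (order-transformed labels, coordination conjuncts,
derivational variants).  It is small enough to inline yet structured like
the real thing: multiple inheritance, scoped synonyms, an obsolete term.

The fixture gold corpus is six single-sentence abstracts covering the four
annotation conventions: canonical-form mentions, qualifier-preceding and
qualifier-succeeding coordinations, negated mentions (annotated anyway)
and a non-canonical mention (left unannotated).
"""

from __future__ import annotations

from .evaluation import GoldDocument
from .ontology import Concept, ConceptStore, serialize_obo
from .recognizer import Annotation

__all__ = [
    "build_fixture_ontology",
    "fixture_store",
    "fixture_gold_corpus",
]

_E = "EXACT"

_TERMS: list[Concept] = [
    Concept("HP:0000001", "All"),
    Concept("HP:0000118", "Phenotypic abnormality", parents=("HP:0000001",)),
    # top-level categories (direct children of HP:0000118)
    Concept("HP:0000119", "Abnormality of the genitourinary system",
            parents=("HP:0000118",)),
    Concept("HP:0000152", "Abnormality of the head and neck", parents=("HP:0000118",)),
    Concept("HP:0000478", "Abnormality of the eye", parents=("HP:0000118",)),
    Concept("HP:0000598", "Abnormality of the ear", parents=("HP:0000118",),
            synonyms=(("Otic malformation", _E),)),
    Concept("HP:0000707", "Abnormality of the nervous system", parents=("HP:0000118",)),
    Concept("HP:0000924", "Abnormality of the skeletal system", parents=("HP:0000118",)),
    Concept("HP:0001507", "Growth abnormality", parents=("HP:0000118",)),
    Concept("HP:0001574", "Abnormality of the integument", parents=("HP:0000118",)),
    Concept("HP:0002664", "Neoplasm", parents=("HP:0000118",),
            synonyms=(("Tumor", _E), ("Oncology", "RELATED"))),
    # genitourinary branch
    Concept("HP:0000077", "Abnormality of the kidney", parents=("HP:0000119",),
            synonyms=(("Kidney anomaly", _E),)),
    Concept("HP:0000792", "Abnormal renal morphology", parents=("HP:0000077",),
            synonyms=(("Renal malformation", _E),)),
    # head and neck / ear branch
    Concept("HP:0009794", "Branchial anomaly", parents=("HP:0000152",),
            synonyms=(("Branchial arch malformation", _E),)),
    Concept("HP:0004330", "Increased skull ossification", parents=("HP:0000152",)),
    # eye branch
    Concept("HP:0000609", "Optic nerve hypoplasia", parents=("HP:0000478",),
            synonyms=(("Hypoplasia of the optic nerve", _E),)),
    # nervous-system branch
    Concept("HP:0000733", "Stereotypical motor behaviours", parents=("HP:0000707",)),
    Concept("HP:0007087", "Involuntary jerking movements", parents=("HP:0000707",)),
    Concept("HP:0004374", "Hemiplegia/hemiparesis", parents=("HP:0000707",)),
    # skeletal branch
    Concept("HP:0002683", "Abnormality of the calvaria", parents=("HP:0000924",)),
    Concept("HP:0000250", "Dense calvaria",
            parents=("HP:0002683", "HP:0004330")),  # multi-parent example
    Concept("HP:0008368", "Synostosis involving tarsal bones", parents=("HP:0000924",)),
    Concept("HP:0009702", "Synostosis involving the carpal bones",
            parents=("HP:0000924",)),
    Concept("HP:0001591", "Bell-shaped thorax", parents=("HP:0000924",)),
    Concept("HP:0005918", "Abnormality of metacarpal IV", parents=("HP:0000924",)),
    Concept("HP:0001167", "Abnormality of finger", parents=("HP:0000924",)),
    Concept("HP:0009381", "Short fingers", parents=("HP:0001167",)),
    Concept("HP:0001500", "Broad fingers", parents=("HP:0001167",)),
    Concept("HP:0001156", "Brachydactyly", parents=("HP:0001167",)),
    Concept("HP:0009371", "Type A1 brachydactyly", parents=("HP:0001156",)),
    # growth branch
    Concept("HP:0004322", "Short stature", parents=("HP:0001507",),
            synonyms=(("Small stature", _E),)),
    # integument branch
    Concept("HP:0001792", "Small nail", parents=("HP:0001574",),
            synonyms=(("Nail hypoplasia", _E), ("Hypoplastic nails", _E))),
    Concept("HP:0001798", "Anonychia", parents=("HP:0001574",),
            synonyms=(("Aplasia of the nails", _E), ("Absent nails", _E))),
    # neoplasm branch
    Concept("HP:0002858", "Meningioma", parents=("HP:0002664",)),
    # an obsolete term: must never reach the lexicon
    Concept("HP:0006143", "Broad phalanges of the hand", parents=("HP:0000924",),
            obsolete=True),
]


def fixture_store() -> ConceptStore:
    """The fixture ontology as a ConceptStore."""
    return ConceptStore(list(_TERMS))


def build_fixture_ontology() -> str:
    """Deterministic OBO 1.2 text of the fixture ontology.

    Parsing the output and re-serializing it is a fixed point.
    """
    return serialize_obo(fixture_store(), ontology_name="hp-fixture")


def _doc(doc_id: str, text: str, spans: list[tuple[str, str]]) -> GoldDocument:
    """Build a GoldDocument from (substring, concept) pairs.

    Each substring must occur exactly once in the text; offsets are derived
    from it, keeping the fixture immune to hand-counted offset errors.
    """
    annotations = []
    for needle, concept_id in spans:
        start = text.find(needle)
        if start < 0 or text.find(needle, start + 1) >= 0:
            raise ValueError(f"{doc_id}: span {needle!r} not unique in text")
        annotations.append(
            Annotation(doc_id, start, start + len(needle), needle, concept_id, "GOLD")
        )
    annotations.sort(key=lambda a: a.instance)
    return GoldDocument(doc_id, text, annotations)


def fixture_gold_corpus() -> list[GoldDocument]:
    """Six single-sentence documents exercising the annotation conventions."""
    return [
        # canonical qualifier-entity mentions; the bare conjunction of two
        # complete phenotypes needs no decomposition
        _doc(
            "doc1",
            "The patient showed hypoplastic nails and broad fingers.",
            [("hypoplastic nails", "HP:0001792"), ("broad fingers", "HP:0001500")],
        ),
        # qualifier PRECEDING the conjunction: one full span, both concepts
        _doc(
            "doc2",
            "Radiographs revealed synostosis of some carpal and tarsal bones.",
            [
                ("synostosis of some carpal and tarsal bones", "HP:0008368"),
                ("synostosis of some carpal and tarsal bones", "HP:0009702"),
            ],
        ),
        # qualifier SUCCEEDING the conjunction: nested suffix spans
        _doc(
            "doc3",
            "The syndrome is characterized by branchial arch, otic and renal "
            "malformations.",
            [
                ("branchial arch, otic and renal malformations", "HP:0009794"),
                ("otic and renal malformations", "HP:0000598"),
                ("renal malformations", "HP:0000792"),
            ],
        ),
        # negated phenotypes are annotated anyway
        _doc(
            "doc4",
            "No kidney anomalies were found in any of the patients.",
            [("kidney anomalies", "HP:0000077")],
        ),
        # non-canonical (verbal) phrasing: excluded from the gold standard
        _doc("doc5", "The nails were hypoplastic.", []),
        # order-transformed mention plus an "or" coordination of qualifiers
        _doc(
            "doc6",
            "Brachydactyly type A1 was diagnosed, with aplastic or hypoplastic "
            "nails.",
            [
                ("Brachydactyly type A1", "HP:0009371"),
                ("aplastic or hypoplastic nails", "HP:0001792"),
                ("aplastic or hypoplastic nails", "HP:0001798"),
            ],
        ),
    ]
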