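"""Recognizer behavior: scanning, coordination, non-canonical phrases,
overlap resolution, and the matching invariants."""

import random

import pytest

from phenocr.ontology import Concept, ConceptStore, build_lexicon
from phenocr.recognizer import (
    Annotation,
    RecognizerOptions,
    annotate,
    build_index,
    decompose_coordination,
    resolve_overlaps,
)
from phenocr.textnorm import signature_key, tokenize


def spans(annotations):
    return [(a.start, a.end, a.concept_id) for a in annotations]


class TestIndex:
    def test_every_entry_findable_by_own_surface(self, index, lexicon):
        for e in lexicon:
            seq = tuple(t.norm for t in tokenize(e.surface) if t.is_word)
            assert e.concept_id in index.concepts_for_sequence(seq)

    def test_signature_lookup_of_transformed_order(self, index):
        assert index.concepts_for_signature(
            signature_key("type a1 brachydactyly")
        ) == ["HP:0009371"]

    def test_ambiguity_preserved_in_multimap(self, store):
        ambiguous = ConceptStore(
            [
                Concept("HP:0000010", "Broad nail"),
                Concept("HP:0000011", "Nail broad"),
            ]
        )
        idx = build_index(build_lexicon(ambiguous), store=ambiguous)
        assert idx.concepts_for_signature(signature_key("broad nail")) == [
            "HP:0000010",
            "HP:0000011",
        ]

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            build_index([])


class TestAnnotate:
    def test_negation_does_not_suppress(self, index):
        text = "No kidney anomalies were found."
        anns = annotate("d", text, index)
        assert spans(anns) == [(3, 19, "HP:0000077")]
        assert text[3:19] == "kidney anomalies"

    def test_order_invariant_toggle(self, index):
        text = "Brachydactyly type A1"
        on = annotate("d", text, index)
        assert spans(on) == [(0, 21, "HP:0009371")]
        assert on[0].match_type == "ORDER_INVARIANT"
        # without order-invariance only the nested verbatim surface
        # "Brachydactyly" is found, not the order-transformed concept
        off = annotate("d", text, index, RecognizerOptions(order_invariant=False))
        assert spans(off) == [(0, 13, "HP:0001156")]

    def test_conjoined_qualifiers_share_full_span(self, index):
        anns = annotate("d", "short and broad fingers", index)
        assert spans(anns) == [
            (0, 23, "HP:0001500"),
            (0, 23, "HP:0009381"),
        ]

    def test_empty_text(self, index):
        assert annotate("d", "", index) == []
        assert annotate("d", "   \n ", index) == []

    def test_exact_match_crosses_label_internal_conjunction(self, index):
        anns = annotate("d", "Abnormality of the head and neck", index)
        assert spans(anns) == [(0, 32, "HP:0000152")]

    def test_longest_match_wins_over_nested(self, index):
        # the nested "hypoplastic nails" must not surface next to the
        # longer coordination span carrying the same concept
        anns = annotate("d", "aplastic or hypoplastic nails", index)
        assert spans(anns) == [
            (0, 29, "HP:0001792"),
            (0, 29, "HP:0001798"),
        ]

    def test_determinism_byte_identical(self, index, gold_corpus):
        out1 = [annotate(d.doc_id, d.text, index) for d in gold_corpus]
        out2 = [annotate(d.doc_id, d.text, index) for d in gold_corpus]
        assert repr(out1) == repr(out2)


class TestCoordination:
    def test_qualifier_preceding_single_span_two_concepts(self, index):
        text = "synostosis of some carpal and tarsal bones"
        anns = decompose_coordination(tokenize(text), index, "d", text)
        assert sorted(spans(anns)) == [
            (0, len(text), "HP:0008368"),
            (0, len(text), "HP:0009702"),
        ]

    def test_qualifier_succeeding_nested_suffix_spans(self, index):
        text = "branchial arch, otic and renal malformations"
        anns = decompose_coordination(tokenize(text), index, "d", text)
        assert spans(anns) == [
            (0, 44, "HP:0009794"),
            (16, 44, "HP:0000598"),
            (25, 44, "HP:0000792"),
        ]
        assert text[16:44] == "otic and renal malformations"
        assert text[25:44] == "renal malformations"

    def test_unresolvable_conjuncts_do_not_fire(self, index):
        text = "apples and oranges were eaten"
        assert decompose_coordination(tokenize(text), index, "d", text) == []

    def test_or_conjunction(self, index):
        text = "aplastic or hypoplastic nails"
        anns = decompose_coordination(tokenize(text), index, "d", text)
        assert {(a.start, a.end) for a in anns} == {(0, 29)}
        assert {a.concept_id for a in anns} == {"HP:0001792", "HP:0001798"}

    def test_nested_spans_of_related_concepts_survive(self, index):
        # the suffix conjunct's concept (Growth abnormality) is a child of
        # the full span's concept (Phenotypic abnormality); the nested span
        # must not be suppressed by the specificity rule
        text = "phenotypic and growth abnormalities"
        anns = annotate("d", text, index)
        assert spans(anns) == [
            (0, 35, "HP:0000118"),
            (15, 35, "HP:0001507"),
        ]

    def test_disabled_coordination(self, index):
        anns = annotate(
            "d",
            "branchial arch, otic and renal malformations",
            index,
            RecognizerOptions(coordination=False),
        )
        # only the plain scan's tail match survives
        assert spans(anns) == [(25, 44, "HP:0000792")]


class TestNonCanonical:
    def test_copula_with_conjoined_qualifiers(self, index):
        text = "fingers are short and broad"
        anns = annotate("d", text, index, RecognizerOptions(non_canonical=True))
        assert {a.concept_id for a in anns} == {"HP:0009381", "HP:0001500"}
        assert {(a.start, a.end) for a in anns} == {(0, len(text))}
        assert all(a.match_type == "NON_CANONICAL" for a in anns)

    def test_single_qualifier_and_toggle(self, index):
        on = annotate("d", "nails were hypoplastic", index,
                      RecognizerOptions(non_canonical=True))
        assert spans(on) == [(0, 22, "HP:0001792")]
        off = annotate("d", "nails were hypoplastic", index)
        assert off == []

    def test_unknown_entity_yields_nothing(self, index):
        anns = annotate("d", "gadgets are short and broad", index,
                        RecognizerOptions(non_canonical=True))
        assert anns == []


class TestResolveOverlaps:
    def test_identical_span_keeps_descendant(self, store):
        parent = Annotation("d", 0, 10, "x" * 10, "HP:0001167")
        child = Annotation("d", 0, 10, "x" * 10, "HP:0009381")
        assert resolve_overlaps([parent, child], store) == [child]

    def test_unrelated_concepts_on_same_span_all_kept(self, store):
        a = Annotation("d", 0, 10, "x" * 10, "HP:0009381")
        b = Annotation("d", 0, 10, "x" * 10, "HP:0000077")
        assert resolve_overlaps([a, b], store) == [b, a]  # sorted by concept id

    def test_disjoint_spans_unchanged(self, store):
        a = Annotation("d", 0, 5, "aaaaa", "HP:0009381")
        b = Annotation("d", 6, 11, "bbbbb", "HP:0009381")
        assert resolve_overlaps([a, b], store) == [a, b]

    def test_related_overlap_keeps_longer_span(self, store):
        long = Annotation("d", 0, 12, "x" * 12, "HP:0009381")
        short = Annotation("d", 4, 12, "x" * 8, "HP:0009381")
        assert resolve_overlaps([long, short], store) == [long]

    def test_coordination_group_nested_spans_exempt(self, store):
        outer = Annotation("d", 0, 20, "x" * 20, "HP:0001167", "COORDINATION", 7)
        inner = Annotation("d", 10, 20, "x" * 10, "HP:0009381", "COORDINATION", 7)
        assert resolve_overlaps([outer, inner], store) == [outer, inner]

    def test_duplicate_instances_collapse(self, store):
        a = Annotation("d", 0, 5, "aaaaa", "HP:0009381", "EXACT_SURFACE")
        b = Annotation("d", 0, 5, "aaaaa", "HP:0009381", "COORDINATION", 1)
        kept = resolve_overlaps([a, b], store)
        assert len(kept) == 1 and kept[0].match_type == "EXACT_SURFACE"


def _unambiguous_entries(index, lexicon):
    out = []
    for e in lexicon:
        if len(index.concepts_for_signature(e.signature)) == 1:
            out.append(e)
    return out


class TestMatchingInvariants:
    def test_injection_recovery_for_every_fixture_surface(self, index, lexicon):
        """Embedding any unambiguous lexicon surface in a carrier sentence
        recovers exactly that surface span and concept."""
        for e in _unambiguous_entries(index, lexicon):
            text = f"Patient shows {e.surface} today."
            anns = annotate("d", text, index)
            start = text.index(e.surface)
            assert spans(anns) == [(start, start + len(e.surface), e.concept_id)], (
                e.surface,
                anns,
            )

    def test_order_invariance_over_label_permutations(self, index, lexicon):
        """Any content-token permutation of an unambiguous multi-token label
        is recovered with order_invariant on; a non-verbatim permutation is
        not recovered with it off."""
        rng = random.Random(7)
        strict = RecognizerOptions(order_invariant=False)
        exact_seqs = set(index.exact)
        for e in _unambiguous_entries(index, lexicon):
            content = [t.text for t in tokenize(e.surface) if t.is_content]
            if len(content) < 2 or any(t.lower() in ("and", "or") for t in content):
                continue
            for _ in range(3):
                perm = content[:]
                rng.shuffle(perm)
                text = " ".join(perm)
                assert spans(annotate("d", text, index)) == [
                    (0, len(text), e.concept_id)
                ], (e.surface, text)
                seq = tuple(t.norm for t in tokenize(text) if t.is_word)
                if seq not in exact_seqs:
                    # only nested verbatim sub-surfaces may remain; the
                    # full-span concept is not recovered without
                    # order-invariant matching
                    assert (0, len(text), e.concept_id) not in spans(
                        annotate("d", text, index, strict)
                    )

    def test_coordination_matches_enumeration_oracle(self, index, store):
        """On synthesized coordinations of two or three conjuncts, the
        decomposer reproduces a brute-force oracle that resolves every
        (qualifier, conjunct, tail) combination independently."""
        cases = [
            # (qualifier words, conjunct word lists, tail words, conj)
            ([], [["branchial", "arch"], ["otic"], ["renal"]], ["malformations"], "and"),
            ([], [["otic"], ["renal"]], ["malformations"], "or"),
            (["synostosis", "of", "some"], [["carpal"], ["tarsal"]], ["bones"], "and"),
            ([], [["short"], ["broad"]], ["fingers"], "and"),
            ([], [["aplastic"], ["hypoplastic"]], ["nails"], "or"),
        ]
        for qual, conjuncts, tail, conj in cases:
            words = list(qual)
            for i, c in enumerate(conjuncts):
                if i == len(conjuncts) - 1:
                    words.append(conj)
                elif i > 0:
                    words[-1] = words[-1] + ","
                words += c
            words += tail
            text = " ".join(words)
            # oracle: resolve each qualifier+conjunct+tail combination on its own
            expected = set()
            quality_tail = tail and any(
                t.norm in index.config.quality_nouns
                for t in tokenize(" ".join(tail))
            )
            for i, c in enumerate(conjuncts):
                key = signature_key(" ".join(qual + c + tail))
                for cid in index.concepts_for_signature(key):
                    if not qual and quality_tail:
                        start = text.index(" ".join(c))
                        expected.add((start, len(text), cid))
                    else:
                        expected.add((0, len(text), cid))
            anns = decompose_coordination(tokenize(text), index, "d", text)
            assert {a.instance for a in anns} == expected, text
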