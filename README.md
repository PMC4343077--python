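# phenocr

Phenotype concept recognition, evaluation and test-suite generation for
HPO-style ontologies.

Phenotype mentions in the biomedical literature are hard for dictionary
annotators: the same concept surfaces as "hypoplastic nails", "nail
hypoplasia" or "Hypoplasia of the nails"; conjunctions compress several
concepts into one phrase ("synostosis of some carpal and tarsal bones");
and word order in text rarely matches the ontology label ("Brachydactyly
type A1" vs the label "Type A1 brachydactyly"). `phenocr` is a toolkit for
people building or benchmarking such annotators — text-mining researchers
and curators working with the Human Phenotype Ontology (HPO) or any
ontology distributed as an OBO flat file. It provides:

* **a concept recognizer** — an inverted index over ontology labels and
  synonyms, matched with a greedy longest-match scan, normalization
  (case, inflection, adjective/noun derivation), order-invariant
  signature matching, coordination decomposition and optional handling of
  non-canonical verbal phrasings ("fingers are short and broad");
* **an evaluator** — exact-boundary, exact-concept instance alignment of
  any annotator's output against a gold standoff corpus, with
  P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), stratified by the
  top-level categories (direct children of HP:0000118);
* **a test-suite generator** — stratified one-phrase test cases sampled
  from the ontology by criterion (label length 1–14, punctuation,
  numerals, stop words, singular/plural, lexical variation,
  canonical-order vs transformed-order, synonyms, synthesized
  coordinations) for standardized error analysis.

The matching core is the *signature*: the multiset of normalized content
tokens of a phrase. Two phrases match order-invariantly iff their
signatures are equal, so "Hypoplasia of the optic nerve" and "Optic nerve
hypoplasia" land on the same key. Coordination decomposition follows the
standard annotation conventions: a qualifier *preceding* a conjunction
yields one full span carrying every conjunct's concept, while a qualifier
*succeeding* it yields nested suffix spans, one per conjunct. Negated
mentions are annotated anyway (negation belongs to a different layer).

## Worked example

```python
from phenocr import fixture_store, build_lexicon, build_index, annotate

store = fixture_store()                          # or load_obo("hp.obo")
index = build_index(build_lexicon(store), store=store)
text = ("The syndrome is characterized by branchial arch, otic and renal "
        "malformations, with aplastic or hypoplastic nails.")
for a in annotate("pmid1", text, index):
    print(f"{a.start:>3} {a.end:>3}  {a.concept_id}  {a.match_type:<13} {a.matched_text!r}")
```

prints

```
 33  77  HP:0009794  COORDINATION  'branchial arch, otic and renal malformations'
 49  77  HP:0000598  COORDINATION  'otic and renal malformations'
 58  77  HP:0000792  EXACT_SURFACE 'renal malformations'
 84 113  HP:0001792  COORDINATION  'aplastic or hypoplastic nails'
 84 113  HP:0001798  COORDINATION  'aplastic or hypoplastic nails'
```

The first coordination has its qualifier ("malformations") after the
conjuncts, so it decomposes into three nested suffix spans — branchial
anomaly, ear abnormality, abnormal renal morphology. The second conjoins
two qualifiers before one entity, so a single span carries both the nail
aplasia and nail hypoplasia concepts. Offsets are 0-based half-open
character positions.

The same workflows are available from the shell:

```bash
phenocr fixture --out fx                     # write fixture OBO + gold corpus + suite
phenocr pipeline --obo fx/fixture.obo --corpus fx/gold --out reports
phenocr testsuite generate --obo fx/fixture.obo --out suite.tsv --seed 42
phenocr testsuite run --obo fx/fixture.obo --suite suite.tsv
```

Every report embeds the tool version, a configuration hash and the seed.

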