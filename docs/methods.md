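# Methods

## The recognition model

`phenocr` treats concept recognition as dictionary lookup under a
normalizing, order-forgetting projection. Every matchable surface form
(an ontology label, or a synonym of a configurable scope — by default
labels plus EXACT synonyms feed the recognizer, while the lexicon
inventory keeps all scopes) is indexed twice:

* under its **exact normalized token sequence** — tokens lower-cased,
  regular plurals stripped, adjective/noun derivational variants collapsed
  through an exception table ("hypoplastic" → "hypoplasia");
* under its **signature** — the multiset of normalized *content* tokens,
  i.e. with stop words and punctuation removed. Signatures are the
  order-invariant key: two phrases that are content-token permutations of
  each other have equal signatures.

Scanning a document is a greedy longest-match sweep over token windows,
bounded at 14 tokens (the longest HPO label). At each content-token
position the longest window that hits the index wins and the scan resumes
after it; exact-sequence lookup is tried before signature lookup, and the
match is tagged `EXACT_SURFACE` or `ORDER_INVARIANT` accordingly. Windows
never cross sentence or punctuation boundaries. They may cross "and"/"or"
for exact-sequence lookup only (labels such as "Abnormality of the head
and neck" contain conjunctions); signature lookup is conjunction-free,
because conjunctions are the business of the coordination pass.

A window whose signature maps to several concepts emits all candidates
and lets overlap resolution arbitrate; a strict mode
(`RecognizerOptions(strict_ambiguity=True)`) instead emits none.

Negation is ignored by design: "no kidney anomalies were found" still
yields an annotation on "kidney anomalies". The assumption is that
negation/hedging is resolved by a separate layer over the annotations.

## Coordination decomposition

A conjunction can compress several atomic phenotypes into one phrase. For
every "and"/"or" token the decomposer enumerates bounded splits of the
surrounding tokens into a qualifier prefix Q (0–5 tokens), conjuncts
c_1..c_n (n ≤ 4, each 1–4 tokens; middles delimited by commas) and a
shared tail T (0–4 tokens), and resolves each combination Q + c_i + T
through the signature index. The split resolving the most combinations
wins (ties broken toward longer spans, then longer Q/T — all
deterministic); at least two conjuncts must resolve, and conjuncts that
resolve to nothing are skipped. A comma left of the conjunction is read
both as a conjunct separator and as mere sentence punctuation preceding
the whole coordination; resolution decides between the readings.

The emitted shape follows the gold-annotation conventions:

* **Q non-empty** (qualifier precedes): one full span from Q to T, one
  annotation instance per resolved conjunct — "synostosis of some carpal
  and tarsal bones" carries both synostosis concepts on the whole phrase.
* **Q empty, T headed by a quality noun** (qualifier succeeds): nested
  suffix spans, span_i running from c_i to the end of T — "branchial
  arch, otic and renal malformations" yields three annotations.
* **Q empty, T an entity noun** (conjoined qualifiers): one full span, as
  in "short and broad fingers" or "aplastic or hypoplastic nails".

Whether the shared tail is a *quality* noun (malformation, anomaly,
hypoplasia, ...) or an *entity* noun (fingers, nails, bones) is decided
against a shipped, user-extensible word list
(`resources/quality_nouns.txt`); there is no reliable structural cue, as
the conjuncts are adjectives in both of the Q-empty cases.
Qualifier-on-both-sides ("mixed") coordinations are not decomposed.

Non-canonical verbal phrasings are an optional pass (off by default, as
such phrasings are conventionally excluded from gold corpora of
abstracts): the pattern ENTITY copula QUALIFIER-list rewrites each
qualifier in front of the entity ("fingers are short and broad" →
"short fingers", "broad fingers") and resolves it through the same index;
the emitted span covers the whole clause.

## Overlap resolution

Duplicate (span, concept) instances collapse to one. Among overlapping
candidates whose concepts are hierarchically related (equal, or one an
is_a-ancestor of the other), the longer span wins; on identical spans the
more specific (descendant) concept wins. Hierarchically *unrelated*
concepts are never suppressed — multi-concept spans are legitimate, as
coordination produces them. The nested spans emitted by one coordination
group are exempt from suppression against each other, so a coordination
of a concept with its own descendant ("phenotypic and growth
abnormalities") keeps both nested spans. Tie-breaks are deterministic:
longer span, then deeper concept (more ancestors), then lexicographic id.

## Evaluation

Alignment is instance-level and exact: a predicted instance is a true
positive iff start, end and concept id all equal a gold instance, each
instance matched at most once (multiset intersection; duplicates in the
predictions are removed first). There is no overlap or partial credit: a
system predicting only the tail unit of a coordination collects both a
false positive and a false negative. A gold span carrying k concepts
counts as k instances. P, R and F use the 0/0 → 0 convention; rounding
(two decimals, half-up) happens only at the presentation layer.

Stratified reports assign each instance to every top-level category of
its concept — a direct child of the category root, default HP:0000118 —
so per-stratum counts can sum to more than the overall count under
multiple inheritance (e.g. a dense calvaria is both a skeletal and a
head-and-neck abnormality); concepts outside the root's subtree fall into
an "uncategorized" stratum.

## Test-suite generation

Criteria group ontology labels by one lexical property. Property families
(length 1–14, punctuation, Arabic/Roman numerals, stop words — the stop
word criterion keys on exactly the six prepositions in/of/to/by/from/with)
emit labels verbatim. Transformation families rewrite the sampled label
while preserving its signature:

* **canonical-order transformed** — "X of (the) Y" ↔ "Y X" and rotation
  of a "type ..." component; labels with no applicable pattern, or
  containing a conjunction (the result would not be order-invariantly
  recoverable), are skipped;
* **singular/plural** — the head noun (final non-stopword token) is
  inflected with rule tables; acronym heads are skipped;
* **lexical variation** — noun ↔ adjective swaps via the derivational
  table ("Hypoplasia of the optic nerve" → "Hypoplastic optic nerve");
* **synonym** — the entry text is a synonym surface, the expected concept
  its parent concept;
* **coordination** — two concepts sharing a component (common content
  prefix or suffix across their labels/EXACT synonyms) are composed into
  one phrase whose expected annotations follow the decomposition
  conventions above.

Mirror pairs ({singular, plural}, {canonical, transformed}) are drawn
from one shared sample, so the two halves are in bijection and a capable
system should score symmetrically on them. Sampling is seeded per
criterion (`random.Random(f"{seed}/{criterion_id}")`), making suite text
byte-identical for a fixed seed. Non-English and metaphoric families are
curated-input-only: no generator can synthesize them faithfully, so
without an input list they are skipped with a warning.

Each entry is run as its own one-phrase document and scored with the same
exact-boundary alignment as gold corpora, aggregated per criterion and
per top-level category.

## Normalization resources and defaults

All resources are plain-text, versioned with the package and replaceable
per run: `stopwords.txt`, `derivational.tsv` (surface → normal form),
`irregular_plurals.tsv`, `quality_nouns.txt`. The stop-word default is
the six prepositions ubiquitous in ontology labels plus articles, plus
the filler words "some" and "involving": HPO writes "Synostosis involving
the carpal bones" where text writes "synostosis of some carpal bones",
and treating these connectors as content tokens would block exactly the
label/mention pairs the signature is meant to unify. Plural stripping is
rule-based (-s/-es/-ies with -ss/-us/-is guards) with an irregular table;
normalization is idempotent by construction (table targets are fixed
points and the rules never create a new strippable suffix). Roman-numeral
flagging is limited to upper-case I–XX.

## What the fixtures emulate — and what they do not

The fixture ontology is a synthetic miniature (35 terms, 9 top-level
categories) carrying the labels, synonyms and multi-parent structure the
worked examples need; the fixture corpus is six single-sentence documents
exercising the annotation conventions (canonical mentions, both
coordination cases, negation, a non-canonical mention left unannotated).
Passing on them shows the machinery implements the conventions exactly;
it does *not* show real-corpus performance. Real abstracts add acronyms
(no acronym expansion is attempted), missing synonyms, semantic
ambiguity, complex conjunctions requiring human interpretation, and
hedging — on such data dictionary systems of this family score far below
the fixture's perfect marks. Problem sizes used by the default test run
and the acceptance script (a ~100-entry generated suite, six-document
corpus) were chosen as the smallest sets that exercise every code path;
the generator scales to the full HPO, where candidate coordination pairs
are discovered by grouping surfaces on first/last content tokens to stay
near-linear in the lexicon.

## Known limitations

* Scan windows do not cross punctuation, so labels containing commas are
  only found verbatim if the comma survives tokenization as a single
  token boundary ("Hemiplegia/hemiparesis" works; "X, Y"-shaped labels
  match only their exact surface).
* Coordination enumeration is bounded (≤ 4 conjuncts, conjunct/tail/
  qualifier lengths ≤ 4/4/5 tokens); longer constructions fall back to
  plain scanning.
* Non-canonical qualifiers are single tokens; "nails were very
  hypoplastic" is not rewritten.
* The quality-noun list is a heuristic; a tail noun missing from it makes
  a qualifier-succeeding coordination come out as one full span.
* Derivational coverage is whatever the table contains; it ships with
  common -plasia/-trophy pairs and is meant to be extended.
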