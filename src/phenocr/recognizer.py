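"""Dictionary-based phenotype concept recognition.

The engine indexes every lexicon surface twice: under its exact normalized
token sequence and under its order-free signature.  Scanning a document is
a greedy longest-match sweep over token windows (bounded by the longest
label length in the ontology, 14 tokens for HPO), with three optional
refinements layered on top:

* order-invariant matching — a window whose content-token multiset equals
  a surface's signature matches even when the word order differs
  ("Brachydactyly type A1" vs the label "Type A1 brachydactyly");
* coordination decomposition — a conjunction compressing several atomic
  phenotypes is expanded into the concepts of its conjuncts, following the
  two annotation conventions: a qualifier *preceding* the conjunction
  ("synostosis of some carpal and tarsal bones") yields one full span
  carrying every resolved concept, while a qualifier *succeeding* the
  conjunction ("branchial arch, otic and renal malformations") yields
  nested suffix spans, one per conjunct;
* non-canonical phrases — shallow patterns rewrite verbal constructions
  ("fingers are short and broad") into canonical qualifier-entity form
  before lookup.

Negation is deliberately ignored: "no kidney anomalies were found" still
yields an annotation on "kidney anomalies", mirroring the convention that
negation handling belongs to a separate processing layer.

Overlap resolution prefers longer spans and, on identical spans, the more
specific (descendant) concept; hierarchically unrelated concepts sharing a
span are all kept, since multi-concept spans are legitimate (coordination).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .ontology import ConceptStore, LexiconEntry
from .textnorm import NormConfig, TokenSpan, default_config, tokenize

__all__ = [
    "Annotation",
    "RecognizerOptions",
    "Index",
    "build_index",
    "annotate",
    "decompose_coordination",
    "match_non_canonical",
    "resolve_overlaps",
    "EXACT_SURFACE",
    "ORDER_INVARIANT",
    "COORDINATION",
    "NON_CANONICAL",
]

EXACT_SURFACE = "EXACT_SURFACE"
ORDER_INVARIANT = "ORDER_INVARIANT"
COORDINATION = "COORDINATION"
NON_CANONICAL = "NON_CANONICAL"

_MATCH_PRIORITY = {EXACT_SURFACE: 0, ORDER_INVARIANT: 1, COORDINATION: 2, NON_CANONICAL: 3}

_CONJ = frozenset({"and", "or"})
_COPULAS = frozenset({"is", "are", "was", "were", "appear", "appears", "appeared"})

# enumeration bounds for coordination decomposition
_MAX_CONJUNCT_TOKENS = 4
_MAX_QUALIFIER_TOKENS = 5
_MAX_TAIL_TOKENS = 4
_MAX_MIDDLE_CONJUNCTS = 2


@dataclass(frozen=True)
class Annotation:
    """A character span bound to one concept.

    Offsets are 0-based, half-open, character-based; one span may carry
    several annotation instances (one per concept).  ``coord_group`` ties
    together the spans emitted by one coordination (or one non-canonical
    clause) so that its intentionally nested spans survive overlap
    resolution.
    """

    doc_id: str
    start: int
    end: int
    matched_text: str
    concept_id: str
    match_type: str = EXACT_SURFACE
    coord_group: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def instance(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.concept_id)


@dataclass(frozen=True)
class RecognizerOptions:
    order_invariant: bool = True
    coordination: bool = True
    non_canonical: bool = False
    max_window_tokens: int = 14
    #: with strict ambiguity, a window whose signature maps to several
    #: unrelated concepts yields no annotation instead of all candidates
    strict_ambiguity: bool = False

    def __post_init__(self):
        if self.max_window_tokens < 1:
            raise ValueError("max_window_tokens must be >= 1")


class Index:
    """Lexicon index: exact normalized sequences and order-free signatures."""

    def __init__(
        self,
        lexicon: list[LexiconEntry],
        store: ConceptStore | None = None,
        config: NormConfig | None = None,
    ):
        if not lexicon:
            raise ValueError("cannot index an empty lexicon")
        self.store = store
        self.config = config or default_config()
        self.exact: dict[tuple[str, ...], list[LexiconEntry]] = {}
        self.sig: dict[tuple[str, ...], list[LexiconEntry]] = {}
        for entry in lexicon:
            seq = tuple(
                t.norm for t in tokenize(entry.surface, self.config) if t.is_word
            )
            self.exact.setdefault(seq, []).append(entry)
            self.sig.setdefault(entry.signature, []).append(entry)

    def concepts_for_signature(self, key: tuple[str, ...]) -> list[str]:
        return sorted({e.concept_id for e in self.sig.get(key, [])})

    def concepts_for_sequence(self, seq: tuple[str, ...]) -> list[str]:
        return sorted({e.concept_id for e in self.exact.get(seq, [])})


def build_index(
    lexicon: list[LexiconEntry],
    store: ConceptStore | None = None,
    config: NormConfig | None = None,
) -> Index:
    return Index(lexicon, store=store, config=config)


# ---------------------------------------------------------------------------
# sentence segmentation


def segment_sentences(tokens: list[TokenSpan]) -> list[list[TokenSpan]]:
    """Split a token stream on [.?!] followed by an uppercase word."""
    sentences: list[list[TokenSpan]] = []
    cur: list[TokenSpan] = []
    for i, t in enumerate(tokens):
        cur.append(t)
        if not t.is_word and t.text in ".?!":
            nxt = next((u for u in tokens[i + 1 :] if u.is_word), None)
            if nxt is None or nxt.text[:1].isupper():
                sentences.append(cur)
                cur = []
    if cur:
        sentences.append(cur)
    return sentences


# ---------------------------------------------------------------------------
# window scan


def _content_key(tokens: list[TokenSpan]) -> tuple[str, ...]:
    return tuple(sorted(t.norm for t in tokens if t.is_content))


def _scan(
    doc_id: str,
    text: str,
    tokens: list[TokenSpan],
    index: Index,
    opts: RecognizerOptions,
) -> list[Annotation]:
    """Greedy longest-match sweep.  Windows never cross punctuation; they
    may cross a conjunction for exact-sequence lookup (some labels contain
    "and"), but order-free signature lookup is conjunction-free, since
    coordinations are decomposed by their own pass."""
    out: list[Annotation] = []
    n = len(tokens)
    i = 0
    while i < n:
        if not tokens[i].is_content:
            i += 1
            continue
        window: list[TokenSpan] = []
        j = i
        while j < n and len(window) < opts.max_window_tokens:
            t = tokens[j]
            if not t.is_word:
                break
            window.append(t)
            j += 1
        consumed = 0
        for length in range(len(window), 0, -1):
            win = window[:length]
            if not win[-1].is_content:
                continue
            seq = tuple(t.norm for t in win)
            concepts = index.concepts_for_sequence(seq)
            mtype = EXACT_SURFACE
            if not concepts and opts.order_invariant and not any(
                t.norm in _CONJ for t in win
            ):
                concepts = index.concepts_for_signature(_content_key(win))
                mtype = ORDER_INVARIANT
            if concepts:
                if opts.strict_ambiguity and len(concepts) > 1:
                    consumed = length
                    break
                for cid in concepts:
                    out.append(
                        Annotation(
                            doc_id,
                            win[0].start,
                            win[-1].end,
                            text[win[0].start : win[-1].end],
                            cid,
                            mtype,
                        )
                    )
                consumed = length
                break
        i += consumed if consumed else 1
    return out


# ---------------------------------------------------------------------------
# coordination decomposition


def _left_segments(tokens: list[TokenSpan], k: int) -> list[list[TokenSpan]] | None:
    """Walk left from the conjunction at index k, splitting conjunct
    segments at commas.  Returns [first_full, middle_1, ..., middle_m]
    ordered left to right, or None if the shape is unusable."""
    segments: list[list[TokenSpan]] = []
    cur: list[TokenSpan] = []
    i = k - 1
    while i >= 0:
        t = tokens[i]
        if t.is_word and t.norm not in _CONJ:
            cur.insert(0, t)
            if len(cur) > 10:
                break
        elif not t.is_word and t.text == ",":
            if not cur:
                return None
            segments.insert(0, cur)
            cur = []
            if len(segments) > _MAX_MIDDLE_CONJUNCTS:
                break
        else:
            break
        i -= 1
    if not cur:
        return None
    segments.insert(0, cur)
    return segments


def _right_run(tokens: list[TokenSpan], k: int) -> list[TokenSpan]:
    run: list[TokenSpan] = []
    for t in tokens[k + 1 :]:
        if not t.is_word or t.norm in _CONJ or len(run) >= 8:
            break
        run.append(t)
    return run


def _valid_chunk(chunk: list[TokenSpan]) -> bool:
    return bool(chunk) and chunk[0].is_content and chunk[-1].is_content


def _enumerate_splits(
    first_full: list[TokenSpan],
    middles: list[list[TokenSpan]],
    right: list[TokenSpan],
    index: Index,
    best,
):
    """Enumerate (qualifier, conjuncts, tail) splits around one conjunction
    and keep the highest-scoring one resolving at least two combinations."""
    for c1_len in range(1, min(_MAX_CONJUNCT_TOKENS, len(first_full)) + 1):
        c1 = first_full[-c1_len:]
        if not _valid_chunk(c1):
            continue
        remaining = first_full[:-c1_len]
        q_lens = [0] + list(range(1, min(_MAX_QUALIFIER_TOKENS, len(remaining)) + 1))
        for q_len in q_lens:
            qual = remaining[-q_len:] if q_len else []
            if qual and not qual[0].is_content:
                continue
            if not any(t.is_content for t in qual):
                qual = []
                if q_len > 1:
                    continue
            for cn_len in range(1, min(_MAX_CONJUNCT_TOKENS, len(right)) + 1):
                cn = right[:cn_len]
                if not _valid_chunk(cn):
                    continue
                rest = right[cn_len:]
                for t_len in range(0, min(_MAX_TAIL_TOKENS, len(rest)) + 1):
                    tail = rest[:t_len]
                    if tail and not tail[-1].is_content:
                        continue
                    conjuncts = [c1] + middles + [cn]
                    resolved = []
                    for c in conjuncts:
                        key = _content_key(qual + c + tail)
                        concepts = index.concepts_for_signature(key) if key else []
                        if concepts:
                            resolved.append((c, concepts))
                    if len(resolved) < 2:
                        continue
                    span_start = qual[0].start if qual else c1[0].start
                    span_end = tail[-1].end if tail else cn[-1].end
                    score = (
                        len(resolved),
                        span_end - span_start,
                        q_len,
                        t_len,
                        c1_len,
                        cn_len,
                    )
                    if best is None or score > best[0]:
                        best = (score, (qual, conjuncts, resolved, tail))
    return best


def decompose_coordination(
    tokens: list[TokenSpan],
    index: Index,
    doc_id: str = "",
    text: str = "",
    group_start: int = 0,
) -> list[Annotation]:
    """Expand conjunct lists joined by ","/"and"/"or" into atomic concepts.

    For every conjunction token the decomposer enumerates bounded splits of
    the surrounding tokens into (qualifier prefix Q, conjuncts c_1..c_n,
    shared tail T) and keeps the split resolving the most combinations
    Q + c_i + T in the lexicon (at least two are required).  The emitted
    shape then follows the annotation conventions:

    * Q non-empty (qualifier precedes)      -> one full span, one instance
      per resolved conjunct;
    * Q empty, T headed by a quality noun   -> qualifier succeeds: nested
      suffix spans, span_i running from c_i's start to T's end;
    * Q empty, T an entity tail             -> conjoined qualifiers before
      an entity ("short and broad fingers"): one full span, as above.

    Conjuncts that resolve to no concept are skipped.
    """
    cfg = index.config
    out: list[Annotation] = []
    group = group_start
    for k, tok in enumerate(tokens):
        if not (tok.is_word and tok.norm in _CONJ):
            continue
        segments = _left_segments(tokens, k)
        if segments is None:
            continue
        right = _right_run(tokens, k)
        if not right:
            continue
        best = None  # (score, parts)
        # a comma left of the conjunction may separate conjuncts or merely
        # precede the whole coordination ("diagnosed, with aplastic or
        # hypoplastic nails"); enumerate both readings and let lexicon
        # resolution decide
        for drop in range(len(segments)):
            first_full, middles = segments[drop], segments[drop + 1 :]
            if any(
                not _valid_chunk(m) or len(m) > _MAX_CONJUNCT_TOKENS for m in middles
            ):
                continue
            best = _enumerate_splits(first_full, middles, right, index, best)
        if best is None:
            continue
        qual, conjuncts, resolved, tail = best[1]
        if not qual and not tail:
            continue  # no shared material: nothing to decompose
        tail_content = [t for t in tail if t.is_content]
        qualifier_succeeds = (
            not qual and tail_content and tail_content[-1].norm in cfg.quality_nouns
        )
        if qualifier_succeeds:
            # nested suffix spans, one per resolved conjunct
            span_end = tail[-1].end
            for chunk, concepts in resolved:
                for cid in concepts:
                    s = chunk[0].start
                    out.append(
                        Annotation(doc_id, s, span_end, text[s:span_end], cid,
                                   COORDINATION, group)
                    )
        else:
            span_start = qual[0].start if qual else conjuncts[0][0].start
            span_end = tail[-1].end if tail else conjuncts[-1][-1].end
            for _chunk, concepts in resolved:
                for cid in concepts:
                    out.append(
                        Annotation(doc_id, span_start, span_end,
                                   text[span_start:span_end], cid,
                                   COORDINATION, group)
                    )
        group += 1
    return out


# ---------------------------------------------------------------------------
# non-canonical phrases


def match_non_canonical(
    tokens: list[TokenSpan],
    index: Index,
    doc_id: str = "",
    text: str = "",
    group_start: int = 1000,
) -> list[Annotation]:
    """Recognize verbal phenotype constructions via shallow rewriting.

    Pattern: ENTITY copula QUALIFIER [(, QUALIFIER)* (and|or) QUALIFIER].
    Each qualifier is rewritten in front of the entity and resolved through
    the order-free index; the emitted span covers the whole clause.
    """
    out: list[Annotation] = []
    group = group_start
    for k, tok in enumerate(tokens):
        if not (tok.is_word and tok.norm in _COPULAS):
            continue
        # qualifier list after the copula: single content tokens separated
        # by commas or a conjunction
        quals: list[TokenSpan] = []
        expect_item = True
        for t in tokens[k + 1 :]:
            if expect_item:
                if t.is_content:
                    quals.append(t)
                    expect_item = False
                else:
                    break
            else:
                if t.is_word and t.norm in _CONJ or (not t.is_word and t.text == ","):
                    expect_item = True
                else:
                    break
        if not quals:
            continue
        # entity: longest resolving suffix of the word tokens before the copula
        left: list[TokenSpan] = []
        i = k - 1
        while i >= 0 and tokens[i].is_word and len(left) < 3:
            left.insert(0, tokens[i])
            i -= 1
        emitted = False
        for e_len in range(len(left), 0, -1):
            entity = left[-e_len:]
            if not _valid_chunk(entity):
                continue
            resolved = []
            for q in quals:
                concepts = index.concepts_for_signature(_content_key([q] + entity))
                if concepts:
                    resolved.append((q, concepts))
            if not resolved:
                continue
            span_start, span_end = entity[0].start, quals[-1].end
            for _q, concepts in resolved:
                for cid in concepts:
                    out.append(
                        Annotation(doc_id, span_start, span_end,
                                   text[span_start:span_end], cid,
                                   NON_CANONICAL, group)
                    )
            group += 1
            emitted = True
            break
        if emitted:
            continue
    return out


# ---------------------------------------------------------------------------
# overlap resolution


def _overlaps(a: Annotation, b: Annotation) -> bool:
    return a.start < b.end and b.start < a.end


def resolve_overlaps(
    candidates: list[Annotation], store: ConceptStore | None = None
) -> list[Annotation]:
    """Suppress redundant candidates.

    Identical (span, concept) duplicates collapse to one instance (keeping
    the most direct match type).  Among overlapping candidates whose
    concepts are hierarchically related, the longer span wins; on identical
    spans the more specific (descendant) concept wins.  Unrelated concepts
    are never suppressed, and the nested spans emitted by one coordination
    group are exempt from suppression against each other.
    """
    dedup: dict[tuple[int, int, str], Annotation] = {}
    for a in candidates:
        prev = dedup.get(a.instance)
        if prev is None:
            dedup[a.instance] = a
            continue
        # merge duplicates: keep the most direct match type but retain any
        # coordination-group membership so nested spans stay exempt
        group = prev.coord_group if prev.coord_group is not None else a.coord_group
        chosen = (
            a
            if _MATCH_PRIORITY[a.match_type] < _MATCH_PRIORITY[prev.match_type]
            else prev
        )
        dedup[a.instance] = replace(chosen, coord_group=group)

    def related(a: Annotation, b: Annotation) -> bool:
        if a.concept_id == b.concept_id:
            return True
        if store is None or a.concept_id not in store or b.concept_id not in store:
            return False
        return store.related(a.concept_id, b.concept_id)

    def depth(a: Annotation) -> int:
        if store is None or a.concept_id not in store:
            return 0
        return store.depth(a.concept_id)

    ordered = sorted(
        dedup.values(),
        key=lambda a: (-(a.end - a.start), -depth(a), a.concept_id, a.start),
    )
    kept: list[Annotation] = []
    for a in ordered:
        suppressed = False
        for b in kept:
            if (
                a.coord_group is not None
                and a.coord_group == b.coord_group
            ):
                continue
            if _overlaps(a, b) and related(a, b):
                suppressed = True
                break
        if not suppressed:
            kept.append(a)
    return sorted(kept, key=lambda a: (a.start, a.end, a.concept_id))


# ---------------------------------------------------------------------------
# document annotation


def annotate(
    doc_id: str,
    text: str,
    index: Index,
    opts: RecognizerOptions | None = None,
) -> list[Annotation]:
    """Annotate one document; output sorted by (start, end, concept_id)."""
    opts = opts or RecognizerOptions()
    if not text.strip():
        return []
    tokens = tokenize(text, index.config)
    candidates: list[Annotation] = []
    group = 0
    for sentence in segment_sentences(tokens):
        candidates += _scan(doc_id, text, sentence, index, opts)
        if opts.coordination:
            coord = decompose_coordination(sentence, index, doc_id, text, group)
            group += len({a.coord_group for a in coord})
            candidates += coord
        if opts.non_canonical:
            nc = match_non_canonical(tokens=sentence, index=index, doc_id=doc_id,
                                     text=text, group_start=group + 1000)
            group += len({a.coord_group for a in nc})
            candidates += nc
    return resolve_overlaps(candidates, index.store)
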