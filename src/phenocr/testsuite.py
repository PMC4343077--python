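"""Stratified test-suite generation and execution for concept recognizers.

Following the software-engineering test-suite methodology, each criterion
groups ontology labels sharing one lexical property (token length,
punctuation, numerals, stop words, inflection, token ordering, synonymy,
coordination).  Each generated entry is a one-phrase document: the entry
text IS the whole input, and the expected annotation is the exact span of
the (possibly transformed) label bound to its concept.  Running a suite
scores an annotator per criterion and per top-level category with the
same exact-boundary alignment used for gold corpora.

Transformation families come in mirror pairs constructed from the same
sampled labels — {singular, plural} and {canonical order, canonical order
transformed} — so that a capable system should score symmetrically on the
two halves of a pair.

Curated-only families (non-English and metaphoric labels) are never
synthesized; they require an input list.
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass, field

from .evaluation import EvalCounts, EvalReport, GoldDocument, StratumScore, align, prf
from .ontology import (
    CategoryMap,
    Concept,
    ConceptStore,
    LexiconEntry,
    assign_categories,
    build_lexicon,
)
from .recognizer import Annotation
from .textnorm import (
    ARABIC_NUMERAL,
    CORE_STOPWORDS,
    ROMAN_NUMERAL,
    NormConfig,
    default_config,
    normalize_token,
    signature_key,
    tokenize,
)

__all__ = [
    "TestCaseEntry",
    "Criterion",
    "CriterionRegistry",
    "default_registry",
    "classify_label",
    "transform_canonical_order",
    "vary_lexically",
    "inflect_label",
    "synthesize_coordination",
    "generate",
    "run_testsuite",
    "suite_to_tsv",
    "suite_from_tsv",
    "SINGULAR",
    "PLURAL",
]

SINGULAR = "SINGULAR"
PLURAL = "PLURAL"

MAX_LABEL_TOKENS = 14  # HPO label lengths span 1..14 tokens


@dataclass(frozen=True)
class TestCaseEntry:
    """One criterion-tagged phrase with its expected annotations.

    ``input_text`` is the entire document; ``expected`` holds
    (start, end, concept_id) instances within it.
    """

    criterion_id: str
    category: str
    input_text: str
    expected: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        for start, end, _cid in self.expected:
            if not (0 <= start < end <= len(self.input_text)):
                raise ValueError(
                    f"expected span {start}:{end} outside entry text"
                )


@dataclass(frozen=True)
class Criterion:
    id: str
    family: str
    parameters: tuple = ()
    curated: tuple[TestCaseEntry, ...] = ()


@dataclass
class CriterionRegistry:
    criteria: list[Criterion]

    def __post_init__(self):
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("criterion ids must be unique")

    def __iter__(self):
        return iter(self.criteria)


def default_registry(
    curated: dict[str, tuple[TestCaseEntry, ...]] | None = None
) -> CriterionRegistry:
    """Length bins 1..14 plus the lexical, ordering, synonym and
    coordination families; curated-only families take their entries from
    the ``curated`` mapping (family name -> entries)."""
    curated = curated or {}
    crits = [Criterion(f"length_{k}", "LENGTH", (k,)) for k in range(1, MAX_LABEL_TOKENS + 1)]
    crits += [
        Criterion("punctuation", "PUNCTUATION"),
        Criterion("arabic_numeral", "ARABIC_NUMERAL"),
        Criterion("roman_numeral", "ROMAN_NUMERAL"),
        Criterion("stopword", "STOPWORD"),
        Criterion("singular", "SINGULAR"),
        Criterion("plural", "PLURAL"),
        Criterion("lexical_variation", "LEXICAL_VARIATION"),
        Criterion("canonical_order", "CANONICAL_ORDER"),
        Criterion("canonical_order_transformed", "CANONICAL_ORDER_TRANSFORMED"),
        Criterion("synonym", "SYNONYM"),
        Criterion("coordination", "COORDINATION"),
        Criterion("non_english", "NON_ENGLISH", (), curated.get("NON_ENGLISH", ())),
        Criterion("metaphoric", "METAPHORIC", (), curated.get("METAPHORIC", ())),
    ]
    return CriterionRegistry(crits)


# ---------------------------------------------------------------------------
# label classification and transformations


def classify_label(entry: LexiconEntry, config: NormConfig | None = None) -> set[str]:
    """Deterministic membership of a surface in the property families."""
    cfg = config or default_config()
    out: set[str] = set()
    if 1 <= entry.token_count <= MAX_LABEL_TOKENS:
        out.add(f"length_{entry.token_count}")
    if re.search(r"[^\w\s\-]", entry.surface):
        out.add("punctuation")
    tokens = tokenize(entry.surface, cfg)
    words = [t for t in tokens if t.is_word]
    if any(t.text.lower() in CORE_STOPWORDS for t in words):
        out.add("stopword")
    if any(ARABIC_NUMERAL in t.flags for t in words):
        out.add("arabic_numeral")
    if any(ROMAN_NUMERAL in t.flags for t in words):
        out.add("roman_numeral")
    return out


_OF_RE = re.compile(r"^(?P<x>.+?) of (?:the )?(?P<y>.+)$", re.IGNORECASE)
_TYPE_HEAD_RE = re.compile(r"^type (?P<q>\S+) (?P<rest>.+)$", re.IGNORECASE)
_TYPE_TAIL_RE = re.compile(r"^(?P<rest>.+) type (?P<q>\S+)$", re.IGNORECASE)


def _cap(text: str) -> str:
    return text[:1].upper() + text[1:] if text else text


def transform_canonical_order(
    label: str, config: NormConfig | None = None
) -> str | None:
    """Reorder a label into a fluent variant with the same signature.

    Recognized patterns: "X of (the) Y" <-> "Y X" and rotation of a
    trailing/leading "type <qualifier>" component.  Returns None when no
    pattern applies (the label is then skipped by the generator).
    """
    cfg = config or default_config()
    words = label.split()
    if len(words) < 2 or any(w.lower() in ("and", "or") for w in words):
        return None
    candidate = None
    if m := _TYPE_HEAD_RE.match(label):
        candidate = f"{_cap(m.group('rest'))} type {m.group('q')}"
    elif m := _TYPE_TAIL_RE.match(label):
        candidate = f"Type {m.group('q')} {m.group('rest').lower()}"
    elif m := _OF_RE.match(label):
        candidate = f"{_cap(m.group('y'))} {m.group('x').lower()}"
    if candidate is None or candidate.lower() == label.lower():
        return None
    if signature_key(candidate, cfg) != signature_key(label, cfg):
        return None
    return candidate


def _reverse_derivational(cfg: NormConfig) -> dict[str, str]:
    """noun normal form -> one adjective surface (first alphabetically)."""
    rev: dict[str, str] = {}
    for adj in sorted(cfg.derivational):
        noun = cfg.derivational[adj]
        rev.setdefault(noun, adj)
    return rev


def vary_lexically(label: str, config: NormConfig | None = None) -> str | None:
    """Noun <-> adjective variation keeping the signature fixed, e.g.
    "Hypoplasia of the optic nerve" -> "Hypoplastic optic nerve"."""
    cfg = config or default_config()
    rev = _reverse_derivational(cfg)
    if m := _OF_RE.match(label):
        head = m.group("x")
        noun = normalize_token(head, cfg)
        if " " not in head and noun in rev:
            candidate = f"{_cap(rev[noun])} {m.group('y')}"
            if signature_key(candidate, cfg) == signature_key(label, cfg):
                return candidate
    words = label.split()
    if len(words) >= 2 and words[0].lower() in cfg.derivational:
        noun = cfg.derivational[words[0].lower()]
        candidate = f"{_cap(noun)} of the {' '.join(words[1:]).lower()}"
        if signature_key(candidate, cfg) == signature_key(label, cfg):
            return candidate
    if len(words) >= 2:
        noun = normalize_token(words[-1], cfg)
        if noun in rev:  # "Optic nerve hypoplasia" -> "Hypoplastic optic nerve"
            candidate = f"{_cap(rev[noun])} {' '.join(words[:-1]).lower()}"
            if signature_key(candidate, cfg) == signature_key(label, cfg):
                return candidate
    return None


_IRREGULAR_SINGULAR_TO_PLURAL: dict[str, str] | None = None


def _pluralize_word(word: str, cfg: NormConfig) -> str:
    low = word.lower()
    rev = {v: k for k, v in cfg.irregular_plurals.items()}
    if low in rev:
        plural = rev[low]
    elif low.endswith(("s", "x", "z", "ch", "sh")):
        plural = low + "es"
    elif low.endswith("y") and len(low) > 1 and low[-2] not in "aeiou":
        plural = low[:-1] + "ies"
    else:
        plural = low + "s"
    return _cap(plural) if word[:1].isupper() else plural


def _singularize_word(word: str, cfg: NormConfig) -> str:
    low = word.lower()
    if low in cfg.irregular_plurals:
        sing = cfg.irregular_plurals[low]
    else:
        from .textnorm import _strip_plural

        sing = _strip_plural(low)
    return _cap(sing) if word[:1].isupper() else sing


def inflect_label(
    label: str, direction: str, config: NormConfig | None = None
) -> str | None:
    """Inflect the head noun (final non-stopword token) of a label.

    Returns None when the label is already in the target number or the
    head is not an inflectable alphabetic noun.
    """
    cfg = config or default_config()
    if direction not in (SINGULAR, PLURAL):
        raise ValueError(f"direction must be SINGULAR or PLURAL, got {direction!r}")
    words = label.split()
    head_idx = None
    for i in range(len(words) - 1, -1, -1):
        if words[i].lower() not in cfg.stopwords:
            head_idx = i
            break
    if head_idx is None:
        return None
    head = words[head_idx]
    if not head.isalpha() or head.isupper() and len(head) > 1:
        return None  # acronyms / numerals are not inflected
    singular = _singularize_word(head, cfg)
    is_plural = singular.lower() != head.lower()
    if direction == SINGULAR:
        if not is_plural:
            return None
        new_head = singular
    else:
        if is_plural:
            return None
        new_head = _pluralize_word(head, cfg)
        if _singularize_word(new_head, cfg).lower() != head.lower():
            return None  # pluralization would not normalize back
    return " ".join(words[:head_idx] + [new_head] + words[head_idx + 1 :])


# ---------------------------------------------------------------------------
# coordination synthesis


def _content_tokens(surface: str, cfg: NormConfig) -> list[tuple[str, str]]:
    return [(t.text, t.norm) for t in tokenize(surface, cfg) if t.is_content]


def _try_coordination(
    surface_a: str,
    cid_a: str,
    surface_b: str,
    cid_b: str,
    mode: str,
    conj: str,
    cfg: NormConfig,
) -> TestCaseEntry | None:
    ta, tb = _content_tokens(surface_a, cfg), _content_tokens(surface_b, cfg)
    if not ta or not tb:
        return None
    pre = 0
    while pre < min(len(ta), len(tb)) and ta[pre][1] == tb[pre][1]:
        pre += 1
    post = 0
    while (
        post < min(len(ta), len(tb)) - pre
        and ta[len(ta) - 1 - post][1] == tb[len(tb) - 1 - post][1]
    ):
        post += 1
    mid_a = ta[pre : len(ta) - post]
    mid_b = tb[pre : len(tb) - post]
    if not (1 <= len(mid_a) <= 2 and 1 <= len(mid_b) <= 2):
        return None
    if {n for _, n in mid_a} == {n for _, n in mid_b}:
        return None
    pre_toks, post_toks = ta[:pre], ta[len(ta) - post :]
    pre_quality = any(n in cfg.quality_nouns for _, n in pre_toks)
    post_quality = any(n in cfg.quality_nouns for _, n in post_toks)
    sa = " ".join(t for t, _ in mid_a).lower()
    sb = " ".join(t for t, _ in mid_b).lower()

    if mode == "QUAL_FIRST":
        if pre_toks and pre_quality:
            phrase = " ".join(
                [" ".join(t for t, _ in pre_toks).lower(), "of", sa, conj, sb]
                + ([" ".join(t for t, _ in post_toks).lower()] if post_toks else [])
            )
        elif post_toks and not post_quality and not pre_toks:
            phrase = f"{sa} {conj} {sb} " + " ".join(t for t, _ in post_toks).lower()
        else:
            return None
        expected = ((0, len(phrase), cid_a), (0, len(phrase), cid_b))
        return TestCaseEntry("coordination", "", phrase, tuple(sorted(expected)))

    if mode == "QUAL_LAST":
        if pre_toks or not post_toks or not post_quality:
            return None
        tail_words = [t for t, _ in post_toks]
        tail_words[-1] = _pluralize_word(tail_words[-1].lower(), cfg)
        tail = " ".join(w.lower() for w in tail_words)
        phrase = f"{sa} {conj} {sb} {tail}"
        b_start = len(sa) + 1 + len(conj) + 1
        expected = ((0, len(phrase), cid_a), (b_start, len(phrase), cid_b))
        return TestCaseEntry("coordination", "", phrase, tuple(sorted(expected)))

    raise ValueError(f"unknown mode {mode!r}")


def synthesize_coordination(
    a: Concept,
    b: Concept,
    mode: str = "QUAL_FIRST",
    conj: str = "and",
    config: NormConfig | None = None,
) -> TestCaseEntry | None:
    """Compose two concepts into one coordinated phrase with its expected
    decomposition, or None when they share no component.

    QUAL_FIRST produces a single full span carrying both concepts (shared
    qualifier precedes, or conjoined qualifiers before a shared entity);
    QUAL_LAST produces the nested suffix spans of a succeeding qualifier.
    Labels and EXACT synonyms are both tried as lexical groundings.
    """
    cfg = config or default_config()
    if conj not in ("and", "or"):
        raise ValueError("conj must be 'and' or 'or'")

    def surfaces(c: Concept) -> list[str]:
        return [c.label] + [s for s, scope in c.synonyms if scope == "EXACT"]

    for sa in surfaces(a):
        for sb in surfaces(b):
            entry = _try_coordination(sa, a.id, sb, b.id, mode, conj, cfg)
            if entry is not None:
                return entry
    return None


# ---------------------------------------------------------------------------
# generation


def _with_category(entry: TestCaseEntry, cids: list[str],
                   category_map: CategoryMap | None) -> TestCaseEntry:
    cats: set[str] = set()
    for cid in cids:
        if category_map is not None:
            cats |= category_map.category_of.get(cid, frozenset())
    category = sorted(cats)[0] if cats else "uncategorized"
    return TestCaseEntry(entry.criterion_id, category, entry.input_text, entry.expected)


def _identity_entry(criterion_id: str, surface: str, cid: str) -> TestCaseEntry:
    return TestCaseEntry(criterion_id, "", surface, ((0, len(surface), cid),))


def _sample(items: list, rng: random.Random, quota: int) -> list:
    if quota >= len(items):
        return list(items)
    return sorted(rng.sample(items, quota), key=items.index)


def generate(
    store: ConceptStore,
    registry: CriterionRegistry | None = None,
    seed: int = 0,
    per_criterion_quota: int = 10,
    config: NormConfig | None = None,
    category_root: str = "HP:0000118",
) -> list[TestCaseEntry]:
    """Sample up to ``per_criterion_quota`` entries per criterion.

    Sampling is seeded per criterion, so output is byte-identical for a
    fixed seed.  Mirror pairs ({singular, plural}, {canonical order,
    canonical order transformed}) are drawn from one shared sample, so the
    two halves are in bijection.  Curated-only families without a curated
    list are skipped with a warning.
    """
    cfg = config or default_config()
    registry = registry or default_registry()
    category_map = (
        assign_categories(store, category_root) if category_root in store else None
    )
    lexicon = build_lexicon(store, config=cfg)
    labels = [e for e in lexicon if e.provenance == "LABEL"]
    exact_syns = [e for e in lexicon if e.provenance == "SYNONYM(EXACT)"]

    def rng_for(cid: str) -> random.Random:
        return random.Random(f"{seed}/{cid}")

    out: list[TestCaseEntry] = []
    handled_pairs: set[str] = set()

    by_family = {c.family: c for c in registry}

    def emit(entry: TestCaseEntry, cids: list[str]) -> None:
        out.append(_with_category(entry, cids, category_map))

    for crit in registry:
        if crit.family == "LENGTH":
            (k,) = crit.parameters
            eligible = [e for e in labels if e.token_count == k]
            for e in _sample(eligible, rng_for(crit.id), per_criterion_quota):
                emit(_identity_entry(crit.id, e.surface, e.concept_id), [e.concept_id])
        elif crit.family in ("PUNCTUATION", "ARABIC_NUMERAL", "ROMAN_NUMERAL", "STOPWORD"):
            eligible = [e for e in labels if crit.id in classify_label(e, cfg)]
            for e in _sample(eligible, rng_for(crit.id), per_criterion_quota):
                emit(_identity_entry(crit.id, e.surface, e.concept_id), [e.concept_id])
        elif crit.family in ("SINGULAR", "PLURAL"):
            if "number_pair" in handled_pairs:
                continue
            handled_pairs.add("number_pair")
            sing_c = by_family.get("SINGULAR")
            plur_c = by_family.get("PLURAL")
            eligible = []
            for e in labels:
                sing = inflect_label(e.surface, SINGULAR, cfg) or e.surface
                plur = inflect_label(e.surface, PLURAL, cfg) or e.surface
                if sing != plur and inflect_label(sing, PLURAL, cfg):
                    eligible.append((e, sing, plur))
            for e, sing, plur in _sample(eligible, rng_for("number_pair"),
                                         per_criterion_quota):
                if sing_c:
                    emit(_identity_entry(sing_c.id, sing, e.concept_id), [e.concept_id])
                if plur_c:
                    emit(_identity_entry(plur_c.id, plur, e.concept_id), [e.concept_id])
        elif crit.family in ("CANONICAL_ORDER", "CANONICAL_ORDER_TRANSFORMED"):
            if "order_pair" in handled_pairs:
                continue
            handled_pairs.add("order_pair")
            canon_c = by_family.get("CANONICAL_ORDER")
            trans_c = by_family.get("CANONICAL_ORDER_TRANSFORMED")
            eligible = [
                (e, t)
                for e in labels
                if (t := transform_canonical_order(e.surface, cfg)) is not None
            ]
            for e, t in _sample(eligible, rng_for("order_pair"), per_criterion_quota):
                if canon_c:
                    emit(_identity_entry(canon_c.id, e.surface, e.concept_id),
                         [e.concept_id])
                if trans_c:
                    emit(_identity_entry(trans_c.id, t, e.concept_id), [e.concept_id])
        elif crit.family == "LEXICAL_VARIATION":
            eligible = [
                (e, v)
                for e in labels
                if (v := vary_lexically(e.surface, cfg)) is not None
            ]
            for e, v in _sample(eligible, rng_for(crit.id), per_criterion_quota):
                emit(_identity_entry(crit.id, v, e.concept_id), [e.concept_id])
        elif crit.family == "SYNONYM":
            eligible = [e for e in exact_syns
                        if e.surface.lower() != store[e.concept_id].label.lower()]
            for e in _sample(eligible, rng_for(crit.id), per_criterion_quota):
                emit(_identity_entry(crit.id, e.surface, e.concept_id), [e.concept_id])
        elif crit.family == "COORDINATION":
            pairs = _coordination_pairs(store, cfg)
            rng = rng_for(crit.id)
            sampled = _sample(pairs, rng, per_criterion_quota)
            for i, (a, b, mode) in enumerate(sampled):
                conj = "and" if i % 2 == 0 else "or"
                entry = synthesize_coordination(store[a], store[b], mode, conj, cfg)
                if entry is not None:
                    emit(entry, [a, b])
        elif crit.curated:
            for entry in crit.curated:
                emit(
                    TestCaseEntry(crit.id, entry.category, entry.input_text,
                                  entry.expected),
                    [cid for _s, _e, cid in entry.expected],
                )
        else:
            warnings.warn(f"criterion {crit.id}: curated family without input list; skipped")
    return out


def _coordination_pairs(
    store: ConceptStore, cfg: NormConfig
) -> list[tuple[str, str, str]]:
    """Candidate (a, b, mode) triples: concept pairs sharing a component.

    Surfaces are grouped by first and last content token so candidate
    discovery stays linear in the lexicon rather than quadratic.
    """
    firsts: dict[str, list[str]] = {}
    lasts: dict[str, list[str]] = {}
    for c in store.concepts:
        if c.obsolete:
            continue
        for surface in [c.label] + [s for s, sc in c.synonyms if sc == "EXACT"]:
            toks = _content_tokens(surface, cfg)
            if not toks:
                continue
            firsts.setdefault(toks[0][1], []).append(c.id)
            lasts.setdefault(toks[-1][1], []).append(c.id)
    out: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    def add(groups: dict[str, list[str]], mode: str, cap: int = 20) -> None:
        for _norm, members in sorted(groups.items()):
            uniq = sorted(set(members))
            for i, a in enumerate(uniq[:cap]):
                for b in uniq[i + 1 : cap]:
                    key = (a, b, mode)
                    if key not in seen:
                        seen.add(key)
                        out.append(key)

    add(lasts, "QUAL_FIRST")  # shared tail: entity or preceding qualifier
    add(lasts, "QUAL_LAST")
    add(firsts, "QUAL_FIRST")  # shared leading qualifier noun
    return out


# ---------------------------------------------------------------------------
# running a suite


def run_testsuite(
    entries: list[TestCaseEntry],
    annotator,
    category_labels: dict[str, str] | None = None,
) -> dict[str, EvalReport]:
    """Score an annotator over a suite, one entry per document.

    ``annotator`` is any callable (doc_id, text) -> list[Annotation].
    Returns reports keyed "by_criterion" and "by_category", each an
    EvalReport whose strata are criteria resp. top-level categories.
    """
    overall = EvalCounts()
    per_crit: dict[str, EvalCounts] = {}
    per_cat: dict[str, EvalCounts] = {}
    for i, entry in enumerate(entries):
        doc_id = f"{entry.criterion_id}_{i:05d}"
        gold = GoldDocument(
            doc_id,
            entry.input_text,
            [
                Annotation(doc_id, s, e, entry.input_text[s:e], cid, "GOLD")
                for s, e, cid in entry.expected
            ],
        )
        counts = align(gold, annotator(doc_id, entry.input_text))
        overall = overall + counts
        per_crit[entry.criterion_id] = per_crit.get(entry.criterion_id, EvalCounts()) + counts
        cat = (category_labels or {}).get(entry.category, entry.category)
        per_cat[cat] = per_cat.get(cat, EvalCounts()) + counts

    def report(per: dict[str, EvalCounts]) -> EvalReport:
        def score(c: EvalCounts) -> StratumScore:
            p, r, f = prf(c)
            return StratumScore(c, p, r, f)

        return EvalReport(overall=score(overall),
                          per_stratum={k: score(v) for k, v in per.items()})

    return {"by_criterion": report(per_crit), "by_category": report(per_cat)}


# ---------------------------------------------------------------------------
# suite TSV I/O


def suite_to_tsv(entries: list[TestCaseEntry]) -> str:
    """criterion_id TAB category TAB input_text TAB start:end:CID;... lines."""
    lines = []
    for e in entries:
        expected = ";".join(f"{s}:{en}:{cid}" for s, en, cid in e.expected)
        lines.append(f"{e.criterion_id}\t{e.category}\t{e.input_text}\t{expected}")
    return "\n".join(lines) + ("\n" if lines else "")


def suite_from_tsv(text: str) -> list[TestCaseEntry]:
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"suite line {lineno}: expected 4 fields")
        criterion_id, category, input_text, expected_raw = parts
        expected = []
        if expected_raw:
            for item in expected_raw.split(";"):
                s, e, cid = item.split(":", 2)
                expected.append((int(s), int(e), cid))
        entries.append(
            TestCaseEntry(criterion_id, category, input_text, tuple(expected))
        )
    return entries
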