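"""Gold-corpus I/O, exact-boundary alignment and P/R/F computation.

A gold corpus is a directory of ``<doc_id>.txt`` plain-text documents with
``<doc_id>.ann`` standoff files (TSV: start, end, span text, concept id;
a span carrying k concepts appears on k lines, one instance per line).

Alignment is instance-level and exact: a predicted instance counts as a
true positive only when its start offset, end offset and concept id all
equal a gold instance, and every instance is matched at most once.  There
is no partial or overlap credit; systems that return only a nested part
of a gold span (e.g. the tail unit of a coordination) are penalized with
both a false positive and a false negative.

Scores can be stratified by top-level ontology category; an instance whose
concept belongs to several categories (multiple inheritance) contributes
to each of them, so per-stratum counts may sum to more than the overall.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .ontology import CategoryMap, ConceptStore
from .recognizer import Annotation

__all__ = [
    "GoldDocument",
    "EvalCounts",
    "StratumScore",
    "EvalReport",
    "GoldCorpusError",
    "read_gold",
    "write_gold",
    "align",
    "prf",
    "f_score",
    "stratify",
    "round2",
    "UNCATEGORIZED",
]

UNCATEGORIZED = "uncategorized"


class GoldCorpusError(ValueError):
    pass


@dataclass
class GoldDocument:
    doc_id: str
    text: str
    annotations: list[Annotation]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class StratumScore:
    counts: EvalCounts
    precision: float
    recall: float
    f_score: float


@dataclass
class EvalReport:
    overall: StratumScore
    per_stratum: dict[str, StratumScore] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def one(s: StratumScore) -> dict:
            return {
                "tp": s.counts.tp,
                "fp": s.counts.fp,
                "fn": s.counts.fn,
                "precision": s.precision,
                "recall": s.recall,
                "f_score": s.f_score,
            }

        return {
            "overall": one(self.overall),
            "per_stratum": {k: one(v) for k, v in sorted(self.per_stratum.items())},
        }


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), with 0/0 -> 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r, f_score(p, r)


def round2(x: float) -> float:
    """Presentation rounding: two decimals, half-up."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _score(counts: EvalCounts) -> StratumScore:
    p, r, f = prf(counts)
    return StratumScore(counts=counts, precision=p, recall=r, f_score=f)


def _dedupe(annotations: list[Annotation]) -> list[Annotation]:
    seen: set[tuple[int, int, str]] = set()
    out = []
    for a in annotations:
        if a.instance not in seen:
            seen.add(a.instance)
            out.append(a)
    return out


def align(gold: GoldDocument, predicted: list[Annotation]) -> EvalCounts:
    """Exact-boundary, exact-concept instance matching for one document.

    Duplicate identical predicted instances are collapsed before matching.
    """
    pred = Counter(a.instance for a in _dedupe(predicted))
    gold_c = Counter(a.instance for a in gold.annotations)
    tp = sum((pred & gold_c).values())
    return EvalCounts(
        tp=tp,
        fp=sum(pred.values()) - tp,
        fn=sum(gold_c.values()) - tp,
    )


def _strata_of(concept_id: str, category_map: CategoryMap | None) -> list[str]:
    if category_map is None:
        return [UNCATEGORIZED]
    cats = category_map.category_of.get(concept_id, frozenset())
    return sorted(cats) if cats else [UNCATEGORIZED]


def stratify(
    pairs: list[tuple[GoldDocument, list[Annotation]]],
    category_map: CategoryMap | None = None,
    stratum_labels: dict[str, str] | None = None,
) -> EvalReport:
    """Corpus-level report with per-top-level-category breakdown.

    Each gold and predicted instance contributes to every category of its
    concept; concepts outside the category root's subtree fall into the
    "uncategorized" stratum.  Per-stratum P/R/F are computed independently.
    """
    overall = EvalCounts()
    per: dict[str, EvalCounts] = {}

    def add(stratum: str, counts: EvalCounts) -> None:
        per[stratum] = per.get(stratum, EvalCounts()) + counts

    for gold, predicted in pairs:
        pred = _dedupe(predicted)
        overall = overall + align(gold, pred)
        strata = {
            s
            for a in gold.annotations + pred
            for s in _strata_of(a.concept_id, category_map)
        }
        for stratum in strata:
            g_sub = GoldDocument(
                gold.doc_id,
                gold.text,
                [a for a in gold.annotations
                 if stratum in _strata_of(a.concept_id, category_map)],
            )
            p_sub = [a for a in pred
                     if stratum in _strata_of(a.concept_id, category_map)]
            add(stratum, align(g_sub, p_sub))

    labels = stratum_labels or {}
    return EvalReport(
        overall=_score(overall),
        per_stratum={labels.get(k, k): _score(v) for k, v in per.items()},
    )


# ---------------------------------------------------------------------------
# corpus I/O


def read_gold(path: Path | str, store: ConceptStore | None = None) -> list[GoldDocument]:
    """Read a gold corpus directory of .txt/.ann file pairs.

    An annotation line whose text column does not equal the document slice
    at its offsets is a hard error (citing document and line); an unknown
    concept id is only warned about and kept.
    """
    import warnings

    root = Path(path)
    docs: list[GoldDocument] = []
    for txt in sorted(root.glob("*.txt")):
        doc_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        ann_path = txt.with_suffix(".ann")
        annotations: list[Annotation] = []
        if ann_path.exists():
            for lineno, line in enumerate(
                ann_path.read_text(encoding="utf-8").splitlines(), start=1
            ):
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise GoldCorpusError(
                        f"{ann_path.name}:{lineno}: expected 4 tab-separated fields"
                    )
                start, end, span_text, concept_id = parts
                start, end = int(start), int(end)
                if text[start:end] != span_text:
                    raise GoldCorpusError(
                        f"{ann_path.name}:{lineno}: text slice "
                        f"{text[start:end]!r} does not match {span_text!r}"
                    )
                if store is not None and concept_id not in store:
                    warnings.warn(
                        f"{ann_path.name}:{lineno}: unknown concept id {concept_id}"
                    )
                annotations.append(
                    Annotation(doc_id, start, end, span_text, concept_id, "GOLD")
                )
        docs.append(GoldDocument(doc_id, text, annotations))
    return docs


def write_predictions(annotations: list[Annotation], path: Path | str) -> None:
    """Write predictions as standoff TSV:
    doc_id, start, end, matched_text, concept_id, match_type."""
    lines = [
        f"{a.doc_id}\t{a.start}\t{a.end}\t{a.matched_text}\t{a.concept_id}\t{a.match_type}"
        for a in sorted(annotations, key=lambda a: (a.doc_id, a.instance))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_predictions(path: Path | str) -> dict[str, list[Annotation]]:
    """Read a predictions TSV back into per-document annotation lists."""
    out: dict[str, list[Annotation]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise GoldCorpusError(f"predictions line {lineno}: expected 6 fields")
        doc_id, start, end, matched_text, concept_id, match_type = parts
        out.setdefault(doc_id, []).append(
            Annotation(doc_id, int(start), int(end), matched_text, concept_id, match_type)
        )
    return out


def write_gold(docs: list[GoldDocument], path: Path | str) -> None:
    """Write a gold corpus directory (inverse of read_gold)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (root / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        lines = [
            f"{a.start}\t{a.end}\t{a.matched_text}\t{a.concept_id}"
            for a in sorted(doc.annotations, key=lambda a: a.instance)
        ]
        (root / f"{doc.doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )
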