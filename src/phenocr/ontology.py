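"""OBO ontology loading, hierarchy queries and lexicon construction.

A concept store wraps the subset of an OBO 1.2 flat file relevant to
concept recognition: term ids, preferred labels, scoped synonyms, is_a
parents and obsolescence.  On top of it this module builds

* the *lexicon*: one entry per matchable surface form (label or synonym)
  carrying its normalized token signature, and
* the *category map*: the assignment of every concept to the top-level
  categories (direct children of a configurable root, by default
  HP:0000118, Phenotypic abnormality) reachable from it through is_a.

Only is_a edges are traversed; HPO is is_a-structured for this purpose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import obonet

from .textnorm import NormConfig, default_config, signature_key

__all__ = [
    "Concept",
    "ConceptStore",
    "LexiconEntry",
    "CategoryMap",
    "OboParseError",
    "load_obo",
    "loads_obo",
    "serialize_obo",
    "ancestors",
    "assign_categories",
    "build_lexicon",
    "SYNONYM_SCOPES",
    "DEFAULT_MATCH_SCOPES",
]

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")
#: scopes whose synonyms feed the recognizer by default (labels always do)
DEFAULT_MATCH_SCOPES = frozenset({"EXACT"})

DEFAULT_CATEGORY_ROOT = "HP:0000118"

_SYNONYM_RE = re.compile(r'^"(?P<surface>.*)"\s*(?P<scope>[A-Z_]+)?')


class OboParseError(ValueError):
    pass


@dataclass(frozen=True)
class Concept:
    """One ontology class: CURIE id, preferred label, scoped synonyms,
    is_a parents and an obsolescence flag."""

    id: str
    label: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (surface, scope)
    parents: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass(frozen=True)
class LexiconEntry:
    """One matchable surface form with its order-free signature.

    provenance is "LABEL" or "SYNONYM(<scope>)"; token_count counts the
    whitespace-delimited tokens of the surface.
    """

    concept_id: str
    surface: str
    provenance: str
    signature: tuple[str, ...]  # canonical (sorted) serialization
    token_count: int


@dataclass
class CategoryMap:
    root: str
    category_of: dict[str, frozenset[str]]
    categories: tuple[str, ...]  # direct children of root, sorted

    def labels(self, store: "ConceptStore") -> dict[str, str]:
        return {c: store[c].label for c in self.categories}


class ConceptStore:
    """Id-keyed concept collection with a cached is_a graph."""

    def __init__(self, concepts: list[Concept], id_pattern: str = r"^HP:\d{7}$"):
        self._pattern = re.compile(id_pattern)
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise OboParseError(f"duplicate term id {c.id}")
            if not self._pattern.match(c.id):
                raise OboParseError(f"id {c.id!r} does not match {id_pattern}")
            if not c.label:
                raise OboParseError(f"term {c.id} has an empty label")
            if c.id in c.parents:
                raise OboParseError(f"term {c.id} lists itself as a parent")
            self._concepts[c.id] = c
        # child -> parent edges over is_a
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self._concepts)
        for c in concepts:
            for p in c.parents:
                self._graph.add_edge(c.id, p)

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self._concepts

    def __getitem__(self, cid: str) -> Concept:
        return self._concepts[cid]

    def __iter__(self):
        return iter(sorted(self._concepts))

    @property
    def concepts(self) -> list[Concept]:
        return [self._concepts[c] for c in sorted(self._concepts)]

    def ancestors(self, cid: str) -> frozenset[str]:
        return ancestors(self, cid)

    def depth(self, cid: str) -> int:
        """Number of distinct ancestors; proxy for specificity."""
        return len(self.ancestors(cid))

    def related(self, a: str, b: str) -> bool:
        """True if a and b are identical or one subsumes the other."""
        if a == b:
            return True
        return a in self.ancestors(b) or b in self.ancestors(a)


def ancestors(store: ConceptStore, cid: str) -> frozenset[str]:
    """Reflexive-free transitive closure over is_a.

    Raises on unknown ids and on cyclic input, naming the cycle.
    """
    if cid not in store:
        raise KeyError(f"unknown concept id {cid}")
    reachable = nx.descendants(store._graph, cid)  # child->parent direction
    sub = store._graph.subgraph(reachable | {cid})
    if not nx.is_directed_acyclic_graph(sub):
        cycle = [e[0] for e in nx.find_cycle(sub)]
        raise ValueError(f"is_a cycle detected: {' -> '.join(cycle + cycle[:1])}")
    return frozenset(reachable)


def assign_categories(
    store: ConceptStore, root: str = DEFAULT_CATEGORY_ROOT
) -> CategoryMap:
    """Map every concept to the top-level categories it falls under.

    A top-level category is a direct child of ``root``.  A concept with
    several ancestry paths may map to more than one category (e.g. a dense
    calvaria is both a skeletal and a head-and-neck abnormality); concepts
    with no path into the root's subtree map to the empty set.
    """
    if root not in store:
        raise KeyError(f"unknown category root {root}")
    tops = tuple(sorted(c.id for c in store.concepts if root in c.parents))
    topset = frozenset(tops)
    category_of = {}
    for c in store.concepts:
        up = store.ancestors(c.id) | {c.id}
        category_of[c.id] = frozenset(up & topset)
    return CategoryMap(root=root, category_of=category_of, categories=tops)


# ---------------------------------------------------------------------------
# OBO reading / writing


def _parse_synonym(raw: str) -> tuple[str, str]:
    m = _SYNONYM_RE.match(raw.strip())
    if not m or not m.group("surface"):
        raise OboParseError(f"unparseable synonym clause: {raw!r}")
    scope = m.group("scope") or "RELATED"
    if scope not in SYNONYM_SCOPES:
        scope = "RELATED"
    return m.group("surface"), scope


def _validate_obo_lines(text: str) -> None:
    """Light stanza validation so malformed input fails with a line number."""
    in_term = False
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            if not stripped.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {stripped!r}")
            in_term = stripped == "[Term]"
            continue
        if ":" not in stripped:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {stripped!r}")
        if in_term and stripped.startswith("id:"):
            tid = stripped[3:].strip()
            if tid in seen:
                raise OboParseError(f"line {lineno}: duplicate term id {tid}")
            seen.add(tid)


def loads_obo(text: str, id_pattern: str = r"^HP:\d{7}$") -> ConceptStore:
    """Parse OBO 1.2 flat-file text into a ConceptStore."""
    import io

    _validate_obo_lines(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    concepts = []
    for node_id in sorted(graph.nodes):
        data = graph.nodes[node_id]
        synonyms = tuple(_parse_synonym(s) for s in data.get("synonym", []))
        concepts.append(
            Concept(
                id=node_id,
                label=data.get("name", ""),
                synonyms=synonyms,
                parents=tuple(data.get("is_a", [])),
                obsolete=data.get("is_obsolete", "false") == "true",
            )
        )
    return ConceptStore(concepts, id_pattern=id_pattern)


def load_obo(path, id_pattern: str = r"^HP:\d{7}$") -> ConceptStore:
    """Read an OBO 1.2 flat file from ``path``."""
    from pathlib import Path

    return loads_obo(Path(path).read_text(encoding="utf-8"), id_pattern=id_pattern)


def serialize_obo(store: ConceptStore, ontology_name: str = "hp") -> str:
    """Deterministic OBO 1.2 serialization (terms sorted by id).

    ``loads_obo`` followed by ``serialize_obo`` is a fixed point on text
    this function produced.
    """
    lines = ["format-version: 1.2", f"ontology: {ontology_name}"]
    for c in store.concepts:
        lines += ["", "[Term]", f"id: {c.id}", f"name: {c.label}"]
        for surface, scope in c.synonyms:
            lines.append(f'synonym: "{surface}" {scope} []')
        for p in c.parents:
            label = store[p].label if p in store else ""
            lines.append(f"is_a: {p} ! {label}" if label else f"is_a: {p}")
        if c.obsolete:
            lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Lexicon


def build_lexicon(
    store: ConceptStore,
    synonym_scopes: tuple[str, ...] | frozenset[str] = SYNONYM_SCOPES,
    config: NormConfig | None = None,
) -> list[LexiconEntry]:
    """One LexiconEntry per label and per synonym of the requested scopes.

    Obsolete concepts contribute nothing.  With all scopes included the
    lexicon size is exactly sum(1 + n_synonyms) over non-obsolete concepts.
    """
    cfg = config or default_config()
    scopes = frozenset(synonym_scopes)
    entries: list[LexiconEntry] = []
    for c in store.concepts:
        if c.obsolete:
            continue
        surfaces = [(c.label, "LABEL")]
        surfaces += [
            (surf, f"SYNONYM({scope})") for surf, scope in c.synonyms if scope in scopes
        ]
        for surface, provenance in surfaces:
            entries.append(
                LexiconEntry(
                    concept_id=c.id,
                    surface=surface,
                    provenance=provenance,
                    signature=signature_key(surface, cfg),
                    token_count=len(surface.split()),
                )
            )
    return entries
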