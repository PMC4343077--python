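"""Tokenization and lexical normalization shared by indexing and matching.

Phenotype mentions rarely match ontology labels verbatim: they differ in
case ("Nails" / "nails"), number ("kidney anomalies" / "Kidney anomaly"),
derivation ("hypoplastic" / "hypoplasia") and word order ("Optic nerve
hypoplasia" / "Hypoplasia of the optic nerve").  This module provides the
single normalization pipeline both the lexicon indexer and the document
scanner run through, so that a surface form and a label land on the same
key whenever they are lexical variants of each other.

The order-free key is the *signature*: the multiset of normalized content
tokens, with stop words and punctuation removed.  Two phrases that are
content-token permutations of each other share a signature.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources as _resources
from pathlib import Path

__all__ = [
    "TokenSpan",
    "NormConfig",
    "default_config",
    "tokenize",
    "normalize_token",
    "signature",
    "signature_key",
    "STOPWORD",
    "ARABIC_NUMERAL",
    "ROMAN_NUMERAL",
    "PUNCT",
]

# token flags
STOPWORD = "STOPWORD"
ARABIC_NUMERAL = "ARABIC_NUMERAL"
ROMAN_NUMERAL = "ROMAN_NUMERAL"
PUNCT = "PUNCT"

# The six prepositions that the test-suite stop-word criterion keys on.
CORE_STOPWORDS = frozenset({"in", "of", "to", "by", "from", "with"})

_PUNCT_CHARS = set(string.punctuation)
# Hyphens are word-internal ("bell-shaped", "L4-S1"); never peeled.
_PEELABLE = _PUNCT_CHARS - {"-"}

_ARABIC_RE = re.compile(r"^\d+$")
# Roman numerals I..XX, upper case only (label context: "metacarpal IV").
_ROMAN_SET = frozenset(
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX".split()
)


def _load_tsv_map(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        if key and val:
            out[key.strip().lower()] = val.strip().lower()
    return out


def _load_wordlist(text: str) -> frozenset[str]:
    words = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line.lower())
    return frozenset(words)


def _resource_text(name: str) -> str:
    return (_resources.files("phenocr.resources") / name).read_text(encoding="utf-8")


@dataclass(frozen=True)
class NormConfig:
    """Resources driving normalization.

    stopwords        words excluded from signatures (prepositions, articles,
                     filler quantifiers/connectors)
    derivational     surface -> normal form, collapsing adjective/noun pairs
    irregular_plurals  plural -> singular exceptions to the -s/-es/-ies rules
    quality_nouns    normalized nouns that act as the abnormality head of a
                     phenotype phrase (used by coordination decomposition)
    """

    stopwords: frozenset[str]
    derivational: dict[str, str]
    irregular_plurals: dict[str, str]
    quality_nouns: frozenset[str]

    @staticmethod
    def from_files(
        stopwords: Path | None = None,
        derivational: Path | None = None,
        irregular_plurals: Path | None = None,
        quality_nouns: Path | None = None,
    ) -> "NormConfig":
        """Build a config from plain-text resource files, falling back to the
        bundled defaults for any path left unset."""

        def read(path: Path | None, name: str) -> str:
            return path.read_text(encoding="utf-8") if path else _resource_text(name)

        return NormConfig(
            stopwords=_load_wordlist(read(stopwords, "stopwords.txt")),
            derivational=_load_tsv_map(read(derivational, "derivational.tsv")),
            irregular_plurals=_load_tsv_map(read(irregular_plurals, "irregular_plurals.tsv")),
            quality_nouns=_load_wordlist(read(quality_nouns, "quality_nouns.txt")),
        )


_DEFAULT: NormConfig | None = None


def default_config() -> NormConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = NormConfig.from_files()
    return _DEFAULT


@dataclass
class TokenSpan:
    """One token with character offsets into its source text.

    Offsets are 0-based and half-open: ``source[start:end] == text``.
    """

    text: str
    start: int
    end: int
    norm: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_word(self) -> bool:
        return PUNCT not in self.flags

    @property
    def is_content(self) -> bool:
        return PUNCT not in self.flags and STOPWORD not in self.flags


def _strip_plural(token: str) -> str:
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("ses", "xes", "zes", "ches", "shes")):
        return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


def normalize_token(token: str, config: NormConfig | None = None) -> str:
    """Map a word token to its normal form.

    Case fold, then apply the irregular-plural and derivational exception
    tables, then rule-based plural stripping.  The pipeline is idempotent:
    table values are themselves fixed points, and the plural rules never
    produce a new strippable suffix.
    """
    cfg = config or default_config()
    t = token.lower()
    if t in cfg.irregular_plurals:
        t = cfg.irregular_plurals[t]
    if t in cfg.derivational:
        return cfg.derivational[t]
    t = _strip_plural(t)
    if t in cfg.derivational:
        return cfg.derivational[t]
    return t


def _flags_for(raw: str, norm: str, config: NormConfig) -> frozenset[str]:
    flags = set()
    if norm in config.stopwords:
        flags.add(STOPWORD)
    if _ARABIC_RE.match(raw):
        flags.add(ARABIC_NUMERAL)
    if raw in _ROMAN_SET:
        flags.add(ROMAN_NUMERAL)
    return frozenset(flags)


def tokenize(text: str, config: NormConfig | None = None) -> list[TokenSpan]:
    """Split text into word and punctuation tokens with exact offsets.

    Whitespace delimits tokens; leading/trailing punctuation is peeled off
    into one-character PUNCT tokens; word-internal punctuation (hyphens,
    slashes, periods in abbreviations) is kept, so "bell-shaped" and
    "L4-S1" remain single tokens.
    """
    cfg = config or default_config()
    out: list[TokenSpan] = []
    for m in re.finditer(r"\S+", text):
        raw, start = m.group(), m.start()
        lead = 0
        while lead < len(raw) and raw[lead] in _PEELABLE:
            lead += 1
        trail = len(raw)
        while trail > lead and raw[trail - 1] in _PEELABLE:
            trail -= 1
        for i in range(lead):
            out.append(
                TokenSpan(raw[i], start + i, start + i + 1, raw[i], frozenset({PUNCT}))
            )
        if trail > lead:
            word = raw[lead:trail]
            # lone punctuation run that survived peeling guards (e.g. "--")
            norm = normalize_token(word, cfg)
            out.append(
                TokenSpan(
                    word,
                    start + lead,
                    start + trail,
                    norm,
                    _flags_for(word, norm, cfg),
                )
            )
        for i in range(trail, len(raw)):
            out.append(
                TokenSpan(raw[i], start + i, start + i + 1, raw[i], frozenset({PUNCT}))
            )
    return out


def signature(
    tokens: list[TokenSpan] | str, config: NormConfig | None = None
) -> Counter[str]:
    """Multiset of normalized content tokens (order-free matching key)."""
    if isinstance(tokens, str):
        tokens = tokenize(tokens, config)
    return Counter(t.norm for t in tokens if t.is_content)


def signature_key(sig: Counter[str] | list[TokenSpan] | str,
                  config: NormConfig | None = None) -> tuple[str, ...]:
    """Canonical serialization of a signature: the sorted token sequence."""
    if not isinstance(sig, Counter):
        sig = signature(sig, config)
    return tuple(sorted(sig.elements()))
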