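"""Controlled vocabularies and exact-match annotation of MeSH descriptors.

A :class:`Vocabulary` is a named, categorised set of normalized terms
(optionally with aliases mapping alternate spellings onto canonical terms).
Matching against a record is *exact at the whole-descriptor level* after
normalization: no substring matching, no stemming, and no MeSH-tree expansion.
Qualifier suffixes (``"/methods"``) are stripped by normalization, so
``"Telemedicine/trends"`` matches the term ``telemedicine`` while
``"Telemedicine and Telehealth"`` does not.

Builtin lists ship for the digital-health terminology (26 MeSH descriptors,
from remote sensing technology to population surveillance), the MeSH age-group
bands (infant through aged 80 and over), and a small sample disease list; a
full disease vocabulary is expected to be user-supplied.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import IO, Iterable, Optional, Union

logger = logging.getLogger(__name__)

CATEGORIES = ("digital_health", "disease", "age_group", "gender")

_WS_RE = re.compile(r"\s+")
_DASHES = str.maketrans({"‐": "-", "‑": "-", "‒": "-",
                         "–": "-", "—": "-", "−": "-"})


def normalize_term(raw: str) -> str:
    """Normalize a term or descriptor for exact matching.

    Strips any ``/qualifier`` suffix and a leading major-topic asterisk,
    lowercases, maps typographic dashes to ASCII hyphens, and collapses runs of
    whitespace to single spaces. Idempotent.
    """
    text = raw.strip()
    text = text.split("/", 1)[0]
    text = text.lstrip("*")
    text = text.translate(_DASHES).lower()
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class Vocabulary:
    """A named set of normalized controlled terms with optional aliases."""

    name: str
    category: str
    terms: frozenset[str]
    aliases: dict[str, str] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if not self.terms:
            raise ValueError(f"vocabulary {self.name!r} has no terms")
        for term in self.terms:
            if normalize_term(term) != term:
                raise ValueError(f"term {term!r} is not normalized")
        for alias, target in self.aliases.items():
            if target not in self.terms:
                raise ValueError(
                    f"alias {alias!r} targets unknown term {target!r}"
                )

    def __contains__(self, probe: str) -> bool:
        return self.canonical(probe) is not None

    def canonical(self, probe: str) -> Optional[str]:
        """Canonical term matched by ``probe`` after normalization, or None."""
        norm = normalize_term(probe)
        if norm in self.terms:
            return norm
        return self.aliases.get(norm)

    def label(self, term: str) -> str:
        """Display label for a canonical term (original casing if known)."""
        return self.display.get(term, term)


@dataclass(frozen=True)
class AgeGroupDef:
    """A MeSH age band; ``hi_months`` is ``None`` for the open-ended top band."""

    label: str
    lo_months: int
    hi_months: Optional[int]

    def __post_init__(self) -> None:
        if self.hi_months is not None and not self.lo_months < self.hi_months:
            raise ValueError(f"band {self.label!r}: lo must be < hi")


# MeSH check-tag bands: infant 1-23 months; child, preschool 2-5 y; child
# 6-12 y; adolescent 13-18 y; adult 19-44 y; middle aged 45-64 y; aged
# 65-79 y; aged, 80 and over: open-ended.
_AGE_BANDS: tuple[tuple[str, int, Optional[int]], ...] = (
    ("Infant", 1, 23),
    ("Child, Preschool", 24, 71),
    ("Child", 72, 155),
    ("Adolescent", 156, 227),
    ("Adult", 228, 539),
    ("Middle Aged", 540, 779),
    ("Aged", 780, 959),
    ("Aged, 80 and over", 960, None),
)


def _vocab_from_display_terms(name: str, category: str,
                              raw_terms: Iterable[str],
                              aliases: Optional[dict[str, str]] = None) -> Vocabulary:
    display: dict[str, str] = {}
    for raw in raw_terms:
        norm = normalize_term(raw)
        if norm and norm not in display:
            display[norm] = raw.strip()
    return Vocabulary(name=name, category=category,
                      terms=frozenset(display),
                      aliases=aliases or {}, display=display)


def _read_builtin(filename: str) -> list[str]:
    text = resources.files("meshmine.data").joinpath(filename).read_text("utf-8")
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]


def builtin_digital_health_vocabulary() -> Vocabulary:
    """The 26 digital-health MeSH descriptors used to type approach nodes."""
    return _vocab_from_display_terms(
        "digital_health", "digital_health", _read_builtin("digital_health.txt"))


def builtin_disease_sample_vocabulary() -> Vocabulary:
    """A 10-disease sample vocabulary (tests/demos); real runs supply a full list."""
    return _vocab_from_display_terms(
        "disease_sample", "disease", _read_builtin("diseases_sample.txt"))


def builtin_age_group_vocabulary() -> tuple[Vocabulary, list[AgeGroupDef]]:
    """The eight MeSH age-group labels with their month bands."""
    vocab = _vocab_from_display_terms(
        "age_groups", "age_group", (label for label, _, _ in _AGE_BANDS))
    defs = [AgeGroupDef(label=normalize_term(label), lo_months=lo, hi_months=hi)
            for label, lo, hi in _AGE_BANDS]
    return vocab, defs


def load_vocabulary(source: Union[str, IO], name: str, category: str) -> Vocabulary:
    """Load a vocabulary from a text file.

    Plain dialect: one term per line, ``#`` comments allowed. CSV dialect: two
    columns ``alias,canonical-term`` define aliases (the canonical term is
    added to the vocabulary; the alias maps onto it). Terms are normalized and
    de-duplicated; an empty file (after comment stripping) is an error.
    """
    own = isinstance(source, str)
    fh: IO = open(source, encoding="utf-8") if own else source
    try:
        lines = [ln.rstrip("\n") for ln in fh]
    finally:
        if own:
            fh.close()

    display: dict[str, str] = {}
    aliases: dict[str, str] = {}
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        row = next(csv.reader(StringIO(stripped)))
        if len(row) >= 2 and row[1].strip():
            alias = normalize_term(row[0])
            target = normalize_term(row[1])
            display.setdefault(target, row[1].strip())
            if alias and alias != target:
                aliases[alias] = target
        else:
            norm = normalize_term(row[0])
            if norm:
                display.setdefault(norm, row[0].strip())
    if not display:
        raise ValueError(f"vocabulary source for {name!r} contains no terms")
    logger.info("loaded vocabulary %s: %d terms, %d aliases",
                name, len(display), len(aliases))
    return Vocabulary(name=name, category=category, terms=frozenset(display),
                      aliases=aliases, display=display)


def match_record(record, vocab: Vocabulary) -> set[str]:
    """Canonical vocabulary terms exact-matched by a record's descriptors.

    A term matches iff the normalized form of at least one descriptor equals
    the term (or one of its aliases). Returns a set: multiplicity within one
    record (e.g. qualifier variants of the same heading) is ignored.
    """
    matched: set[str] = set()
    for desc in record.descriptors:
        canon = vocab.canonical(desc)
        if canon is not None:
            matched.add(canon)
    return matched


def warn_on_overlap(vocabs: Iterable[Vocabulary]) -> dict[str, str]:
    """Map each term to its first-registered category, warning on overlaps."""
    categories: dict[str, str] = {}
    for vocab in vocabs:
        for term in vocab.terms:
            if term in categories and categories[term] != vocab.category:
                logger.warning(
                    "term %r appears in multiple vocabularies; keeping category %r",
                    term, categories[term])
            else:
                categories.setdefault(term, vocab.category)
    return categories
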