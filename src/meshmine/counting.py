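"""Occurrence, trend, group, and co-occurrence counting.

The counting unit is the *record*, binary per record: a term counts once per
record no matter how many descriptor variants repeat it, and an unordered term
pair counts once per record in which both terms are matched. Per-year tables
cover only records with a resolvable publication year; totals cover all
records. Rankings break ties by ascending lexicographic term so output is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Mapping, Optional, Union

import pandas as pd

from .corpus import Corpus
from .vocab import Vocabulary, match_record

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Lexicographically ordered pair key for symmetric storage."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CountTable:
    """Per-term record counts over a corpus.

    ``counts`` has an entry for every vocabulary term (zero-filled), so
    serialization always covers the full vocabulary. ``category`` and
    ``display`` carry the source vocabulary's node typing and original casing
    for downstream network construction.
    """

    vocab_name: str
    counts: dict[str, int]
    n_records: int
    category: str = "digital_health"
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.counts.items()
               if c < 0 or c > self.n_records}
        if bad:
            raise ValueError(f"counts outside [0, n_records]: {bad}")

    def __getitem__(self, term: str) -> int:
        return self.counts.get(term, 0)


@dataclass(frozen=True)
class YearCountTable:
    """Per-(term, year) record counts; ``years`` is the sorted covered span."""

    vocab_name: str
    counts: dict[tuple[str, int], int]
    years: tuple[int, ...]
    terms: tuple[str, ...] = ()

    def __getitem__(self, key: tuple[str, int]) -> int:
        return self.counts.get(key, 0)


@dataclass(frozen=True)
class CooccurrenceTable:
    """Symmetric per-record-binary pair counts (canonical pair keys only)."""

    counts: dict[Pair, int]
    left_vocab: str
    right_vocab: str

    def __post_init__(self) -> None:
        for (a, b), c in self.counts.items():
            if a >= b:
                raise ValueError(f"pair {(a, b)} is not in canonical order")
            if c <= 0:
                raise ValueError(f"non-positive pair count for {(a, b)}")

    def get(self, a: str, b: str) -> int:
        return self.counts.get(canonical_pair(a, b), 0)

    def __len__(self) -> int:
        return len(self.counts)


def count_occurrences(corpus: Corpus, vocab: Vocabulary) -> CountTable:
    """Number of records in which each vocabulary term is matched."""
    counts = dict.fromkeys(sorted(vocab.terms), 0)
    for rec in corpus:
        for term in match_record(rec, vocab):
            counts[term] += 1
    return CountTable(vocab_name=vocab.name, counts=counts,
                      n_records=len(corpus), category=vocab.category,
                      display=dict(vocab.display))


def count_by_year(corpus: Corpus, vocab: Vocabulary,
                  year_window: Optional[tuple[int, int]] = None) -> YearCountTable:
    """Per-year term counts over records with a known publication year.

    Records without a year are excluded here (they still count in
    :func:`count_occurrences` totals). ``year_window`` restricts and densifies
    the covered span; by default the span is the observed min..max year.
    """
    counts: dict[tuple[str, int], int] = {}
    observed: set[int] = set()
    for rec in corpus:
        if rec.year is None:
            continue
        if year_window and not (year_window[0] <= rec.year <= year_window[1]):
            continue
        observed.add(rec.year)
        for term in match_record(rec, vocab):
            key = (term, rec.year)
            counts[key] = counts.get(key, 0) + 1
    if year_window:
        years = tuple(range(year_window[0], year_window[1] + 1))
    elif observed:
        years = tuple(range(min(observed), max(observed) + 1))
    else:
        years = ()
    return YearCountTable(vocab_name=vocab.name, counts=counts, years=years,
                          terms=tuple(sorted(vocab.terms)))


def count_cooccurrences(corpus: Corpus, vocab_a: Vocabulary,
                        vocab_b: Vocabulary) -> CooccurrenceTable:
    """Record-level binary co-occurrence counts between two vocabularies.

    For each record, every unordered pair {a, b} with a matched from
    ``vocab_a``, b matched from ``vocab_b``, and a != b increments the pair
    once. The two vocabularies may be identical (within-vocabulary pairs) or
    distinct (cross-vocabulary pairs). Never-observed pairs are absent.
    """
    counts: dict[Pair, int] = {}
    same = vocab_a is vocab_b or (vocab_a.name == vocab_b.name
                                  and vocab_a.terms == vocab_b.terms)
    for rec in corpus:
        ta = match_record(rec, vocab_a)
        tb = ta if same else match_record(rec, vocab_b)
        if same:
            pairs = {canonical_pair(a, b) for a, b in combinations(sorted(ta), 2)}
        else:
            pairs = {canonical_pair(a, b) for a in ta for b in tb if a != b}
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return CooccurrenceTable(counts=counts, left_vocab=vocab_a.name,
                             right_vocab=vocab_b.name)


def aggregate_groups(corpus: Corpus, vocab: Vocabulary,
                     groups: Mapping[str, Iterable[str]]) -> CountTable:
    """Record counts for term groups under union semantics.

    A record counts once toward a group iff it matches at least one member
    term — recomputed from the corpus, *not* the sum of member counts, so
    records matching several members are not double-counted.
    """
    normalized: dict[str, set[str]] = {}
    for label, members in groups.items():
        member_set = set(members)
        unknown = member_set - set(vocab.terms)
        if unknown:
            raise ValueError(
                f"group {label!r} has members outside vocabulary "
                f"{vocab.name!r}: {sorted(unknown)}")
        normalized[label] = member_set
    counts = dict.fromkeys(sorted(normalized), 0)
    for rec in corpus:
        matched = match_record(rec, vocab)
        for label, members in normalized.items():
            if matched & members:
                counts[label] += 1
    return CountTable(vocab_name=f"{vocab.name}:groups", counts=counts,
                      n_records=len(corpus), category=vocab.category)


def top_k(table: CountTable, k: int) -> list[tuple[str, int]]:
    """The k highest-count terms, descending; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda tc: (-tc[1], tc[0]))
    return ranked[:k]


def wordcloud_frequencies(table: CountTable) -> list[tuple[str, int]]:
    """Nonzero term frequencies in ranking order (word-cloud input)."""
    nonzero = {t: c for t, c in table.counts.items() if c >= 1}
    if not nonzero:
        return []
    trimmed = CountTable(vocab_name=table.vocab_name, counts=nonzero,
                         n_records=table.n_records, category=table.category,
                         display=table.display)
    return top_k(trimmed, len(nonzero))


# ---------------------------------------------------------------------------
# Tidy TSV writers (UTF-8, header row, stable column and row order)
# ---------------------------------------------------------------------------

def _write_frame(frame: pd.DataFrame, sink: Union[str, IO]) -> None:
    frame.to_csv(sink, sep="\t", index=False, lineterminator="\n")


def write_count_tsv(table: CountTable, sink: Union[str, IO]) -> None:
    """``term<TAB>count`` over all vocabulary terms, in ranking order."""
    rows = sorted(table.counts.items(), key=lambda tc: (-tc[1], tc[0]))
    _write_frame(pd.DataFrame(rows, columns=["term", "count"]), sink)


def write_year_count_tsv(table: YearCountTable, sink: Union[str, IO]) -> None:
    """``term<TAB>year<TAB>count``, dense over the covered year span."""
    terms = table.terms or tuple(sorted({t for t, _ in table.counts}))
    rows = [(t, y, table[(t, y)]) for t in terms for y in table.years]
    _write_frame(pd.DataFrame(rows, columns=["term", "year", "count"]), sink)


def write_cooccurrence_tsv(table: CooccurrenceTable, sink: Union[str, IO]) -> None:
    """``term_a<TAB>term_b<TAB>count`` with term_a < term_b, sorted."""
    rows = [(a, b, c) for (a, b), c in sorted(table.counts.items())]
    _write_frame(pd.DataFrame(rows, columns=["term_a", "term_b", "count"]), sink)
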