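"""Shared test helpers: independent brute-force oracles and random corpora.

The oracles deliberately avoid the package's counting/matching code paths:
they use their own minimal normalizer and naive double loops, so agreement
with the library is a genuine cross-check.
"""

from __future__ import annotations

import random
from itertools import combinations

from meshmine import Corpus, PubMedRecord, Vocabulary

TERMS = ("alpha", "beta", "gamma", "delta", "epsilon",
         "zeta", "eta", "theta")

# surrounding whitespace is excluded: XML and nbib strip it on read, so such
# descriptors are not representable in the interchange formats
VARIANTS = (
    lambda t: t,
    lambda t: t.upper(),
    lambda t: t.title(),
    lambda t: t + "/methods",
    lambda t: t + "/methods/trends",
)


def oracle_normalize(desc: str) -> str:
    """Independent re-statement of descriptor normalization for the oracle."""
    head = desc.split("/")[0]
    return " ".join(head.lower().split())


def simple_vocabulary(terms=TERMS, category="digital_health") -> Vocabulary:
    return Vocabulary(name="test", category=category,
                      terms=frozenset(terms),
                      display={t: t.title() for t in terms})


def random_corpus(rng: random.Random, max_records: int = 50,
                  terms=TERMS, with_years: bool = True,
                  allow_missing_year: bool = True) -> Corpus:
    """A small random corpus with vocabulary-term variants and junk headings."""
    n = rng.randint(0, max_records)
    records = []
    for i in range(n):
        chosen = rng.sample(terms, rng.randint(0, len(terms)))
        descriptors = []
        seen = set()
        for t in chosen:
            raw = rng.choice(VARIANTS)(t)
            if raw not in seen:
                seen.add(raw)
                descriptors.append(raw)
        for _ in range(rng.randint(0, 3)):
            junk = f"Unrelated Heading {rng.randint(0, 30)}"
            if junk not in seen:
                seen.add(junk)
                descriptors.append(junk)
        if with_years:
            year = rng.choice([None, 2011, 2013, 2015, 2018, 2021]) \
                if allow_missing_year else rng.choice([2011, 2013, 2015, 2018, 2021])
        else:
            year = None
        records.append(PubMedRecord(
            pmid=f"R{i:04d}", year=year,
            has_abstract=rng.random() < 0.8,
            affiliations=(rng.choice(["University of Surrey, Guildford, UK",
                                      "Charité, Berlin, Germany"]),),
            descriptors=tuple(descriptors),
            title=None if rng.random() < 0.5 else f"Title {i}"))
    return Corpus(records=tuple(records), provenance="random-test")


def oracle_matched(record: PubMedRecord, terms) -> set[str]:
    out = set()
    for desc in record.descriptors:
        norm = oracle_normalize(desc)
        if norm in terms:
            out.add(norm)
    return out


def oracle_occurrences(corpus: Corpus, terms) -> dict[str, int]:
    counts = {t: 0 for t in terms}
    for rec in corpus:
        for t in oracle_matched(rec, terms):
            counts[t] += 1
    return counts


def oracle_by_year(corpus: Corpus, terms) -> dict[tuple[str, int], int]:
    counts: dict[tuple[str, int], int] = {}
    for rec in corpus:
        if rec.year is None:
            continue
        for t in oracle_matched(rec, terms):
            counts[(t, rec.year)] = counts.get((t, rec.year), 0) + 1
    return counts


def oracle_cooccurrences(corpus: Corpus, terms) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for rec in corpus:
        matched = sorted(oracle_matched(rec, terms))
        for a, b in combinations(matched, 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts
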