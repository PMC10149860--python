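"""Bibliographic corpus I/O: PubMed XML, MEDLINE nbib, filtering, caching.

A :class:`Corpus` is an ordered collection of :class:`PubMedRecord` objects, one
per publication, carrying only the fields this pipeline consumes: the PMID, the
publication year, whether an abstract is present, the raw affiliation strings,
and the raw MeSH descriptor strings (qualifier suffixes retained as read, e.g.
``"Telemedicine/methods"``). Everything else in a MEDLINE record (authors,
journal, grants, ...) is deliberately out of scope.

Two standard on-disk representations are supported for input — the
``PubmedArticleSet`` XML dialect served by E-utilities/EDirect, and the MEDLINE
tagged flat-file ("nbib") export — plus a plain TSV cache for lossless local
round trips. A :class:`QuerySpec` captures a search definition (phrases, date
window, affiliation restriction, abstract requirement) and can be rendered as a
PubMed boolean query string or applied as a post-hoc corpus filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from io import StringIO
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import Medline
from lxml import etree

logger = logging.getLogger(__name__)

_YEAR_RE = re.compile(r"\d{4}")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (XML, nbib, or TSV cache)."""


@dataclass(frozen=True)
class PubMedRecord:
    """One bibliographic record.

    ``descriptors`` is an ordered, duplicate-free tuple of raw MeSH descriptor
    strings; ``year`` is the 4-digit publication year or ``None`` when no date
    could be resolved.
    """

    pmid: str
    year: Optional[int] = None
    has_abstract: bool = False
    affiliations: tuple[str, ...] = ()
    descriptors: tuple[str, ...] = ()
    title: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("PubMedRecord requires a non-empty pmid")
        if self.year is not None and not (1000 <= self.year <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year!r}")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError(f"duplicate raw descriptors in record {self.pmid}")


@dataclass(frozen=True)
class Corpus:
    """An ordered set of records with unique PMIDs."""

    records: tuple[PubMedRecord, ...]
    provenance: str = ""
    retrieved_on: Optional[date] = None

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(set(pmids)) != len(pmids):
            seen: set[str] = set()
            dupes = {p for p in pmids if p in seen or seen.add(p)}  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate PMIDs in corpus: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PubMedRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        # provenance is metadata, not content
        return self.records == other.records


@dataclass(frozen=True)
class QuerySpec:
    """A search definition: phrases, a date window, and result filters."""

    terms: tuple[str, ...]
    date_from: date
    date_to: date
    affiliation_markers: tuple[str, ...] = ("United Kingdom", "UK")
    require_abstract: bool = True

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("QuerySpec requires at least one query term")
        if self.date_from > self.date_to:
            raise ValueError(
                f"date_from {self.date_from} is after date_to {self.date_to}"
            )


def _dedupe_keep_order(items: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return tuple(out)


def _first_year(text: Optional[str]) -> Optional[int]:
    """First 4-consecutive-digit substring of a free-text date, as an int."""
    if not text:
        return None
    m = _YEAR_RE.search(text)
    return int(m.group()) if m else None


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def _xml_text(elem: Optional[etree._Element]) -> str:
    if elem is None:
        return ""
    return "".join(elem.itertext()).strip()


def _record_from_article(article: etree._Element) -> Optional[PubMedRecord]:
    pmid = _xml_text(article.find(".//MedlineCitation/PMID"))
    if not pmid:
        pmid = _xml_text(article.find(".//PMID"))
    if not pmid:
        logger.warning("skipping article without a PMID")
        return None

    # Year precedence: structured PubDate/Year, then ArticleDate/Year, then the
    # first 4-digit run in any free-text date (MedlineDate).
    year: Optional[int] = None
    year_elem = article.find(".//Article/Journal/JournalIssue/PubDate/Year")
    if year_elem is not None:
        year = _first_year(_xml_text(year_elem))
    if year is None:
        adate = article.find(".//Article/ArticleDate/Year")
        if adate is not None:
            year = _first_year(_xml_text(adate))
    if year is None:
        mdate = article.find(".//Article/Journal/JournalIssue/PubDate/MedlineDate")
        year = _first_year(_xml_text(mdate))

    abstract = article.find(".//Article/Abstract")
    has_abstract = abstract is not None and bool(_xml_text(abstract))

    affiliations = _dedupe_keep_order(
        _xml_text(aff) for aff in article.findall(".//Affiliation") if _xml_text(aff)
    )

    descriptors: list[str] = []
    for heading in article.findall(".//MeshHeadingList/MeshHeading"):
        name = _xml_text(heading.find("DescriptorName"))
        if not name:
            continue
        quals = [_xml_text(q) for q in heading.findall("QualifierName")]
        raw = "/".join([name, *[q for q in quals if q]])
        descriptors.append(raw)

    title = _xml_text(article.find(".//Article/ArticleTitle")) or None
    return PubMedRecord(
        pmid=pmid,
        year=year,
        has_abstract=has_abstract,
        affiliations=affiliations,
        descriptors=_dedupe_keep_order(descriptors),
        title=title,
    )


def parse_pubmed_xml(stream: Union[str, IO], provenance: str = "pubmed-xml") -> Corpus:
    """Parse a ``PubmedArticleSet`` XML document into a :class:`Corpus`.

    ``stream`` may be a path, a file object, or an XML string. Articles without
    a PMID are skipped with a warning; malformed XML raises
    :class:`CorpusFormatError` naming the position reported by the parser.
    Duplicate PMIDs keep the first occurrence.
    """
    try:
        if isinstance(stream, str) and stream.lstrip().startswith("<"):
            root = etree.fromstring(stream.encode("utf-8"))
        else:
            root = etree.parse(stream).getroot()
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed PubMed XML: {exc}") from exc

    records: list[PubMedRecord] = []
    seen: set[str] = set()
    for article in root.iter("PubmedArticle"):
        rec = _record_from_article(article)
        if rec is None:
            continue
        if rec.pmid in seen:
            logger.warning("duplicate PMID %s: keeping first occurrence", rec.pmid)
            continue
        seen.add(rec.pmid)
        records.append(rec)
    return Corpus(records=tuple(records), provenance=provenance)


# ---------------------------------------------------------------------------
# MEDLINE nbib flat files
# ---------------------------------------------------------------------------

def parse_medline_nbib(stream: Union[str, IO], provenance: str = "medline-nbib") -> Corpus:
    """Parse a MEDLINE tagged flat file (nbib export) into a :class:`Corpus`.

    Field mapping mirrors :func:`parse_pubmed_xml`: ``MH`` lines become raw
    descriptors, ``DP`` yields the year (first 4-digit run), ``AB`` sets the
    abstract flag, ``AD`` the affiliations. Continuation lines are folded by
    the underlying MEDLINE parser. Blocks without a PMID are skipped.
    """
    if isinstance(stream, str) and "PMID-" in stream:
        handle: IO = StringIO(stream)
    elif isinstance(stream, str):
        handle = open(stream, encoding="utf-8")
    else:
        handle = stream

    records: list[PubMedRecord] = []
    seen: set[str] = set()
    try:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID", "").strip()
            if not pmid:
                logger.warning("skipping nbib block without a PMID- line")
                continue
            if pmid in seen:
                logger.warning("duplicate PMID %s: keeping first occurrence", pmid)
                continue
            seen.add(pmid)
            ad = rec.get("AD", [])
            affiliations = _dedupe_keep_order(
                [ad] if isinstance(ad, str) else list(ad)
            )
            mh = rec.get("MH", [])
            descriptors = _dedupe_keep_order([mh] if isinstance(mh, str) else list(mh))
            records.append(
                PubMedRecord(
                    pmid=pmid,
                    year=_first_year(rec.get("DP")),
                    has_abstract=bool(rec.get("AB", "").strip()),
                    affiliations=affiliations,
                    descriptors=descriptors,
                    title=rec.get("TI") or None,
                )
            )
    finally:
        if handle is not stream:
            handle.close()
    return Corpus(records=tuple(records), provenance=provenance)


# ---------------------------------------------------------------------------
# Filtering and query construction
# ---------------------------------------------------------------------------

def filter_corpus(corpus: Corpus, spec: QuerySpec) -> Corpus:
    """Apply a :class:`QuerySpec`'s filters to an in-memory corpus.

    Retains records whose year lies inside ``[date_from.year, date_to.year]``
    (records with no year are dropped), that have an abstract when required,
    and that have at least one affiliation containing any marker
    (case-insensitive substring). Input order is preserved.
    """
    markers = [m.lower() for m in spec.affiliation_markers]
    kept: list[PubMedRecord] = []
    for rec in corpus:
        if rec.year is None or not (spec.date_from.year <= rec.year <= spec.date_to.year):
            continue
        if spec.require_abstract and not rec.has_abstract:
            continue
        if markers:
            affs = [a.lower() for a in rec.affiliations]
            if not any(m in a for m in markers for a in affs):
                continue
        kept.append(rec)
    return Corpus(records=tuple(kept), provenance=corpus.provenance,
                  retrieved_on=corpus.retrieved_on)


def build_query(spec: QuerySpec) -> str:
    """Render a :class:`QuerySpec` as a PubMed-syntax boolean expression.

    OR-joins the quoted phrases, AND-joins the publication-date range, the
    abstract filter, and the affiliation clause. Deterministic for a given spec.
    """
    phrase_clause = " OR ".join(f'"{t}"' for t in spec.terms)
    d1 = spec.date_from.strftime("%Y/%m/%d")
    d2 = spec.date_to.strftime("%Y/%m/%d")
    clauses = [f"({phrase_clause})",
               f'("{d1}"[Date - Publication] : "{d2}"[Date - Publication])']
    if spec.require_abstract:
        clauses.append("hasabstract[text]")
    if spec.affiliation_markers:
        aff = " OR ".join(f'"{m}"[Affiliation]' for m in spec.affiliation_markers)
        clauses.append(f"({aff})")
    return " AND ".join(clauses)


def merge_corpora(*corpora: Corpus, provenance: str = "merged") -> Corpus:
    """Concatenate corpora, keeping the first record for any duplicate PMID."""
    seen: set[str] = set()
    records: list[PubMedRecord] = []
    for corpus in corpora:
        for rec in corpus:
            if rec.pmid in seen:
                logger.warning("duplicate PMID %s across sources: keeping first", rec.pmid)
                continue
            seen.add(rec.pmid)
            records.append(rec)
    return Corpus(records=tuple(records), provenance=provenance)


# ---------------------------------------------------------------------------
# TSV cache
# ---------------------------------------------------------------------------

_CACHE_COLUMNS = ["pmid", "year", "has_abstract", "descriptors", "affiliations", "title"]


def _escape(item: str) -> str:
    return (item.replace("\\", "\\\\").replace("|", "\\|")
            .replace("\t", "\\t").replace("\n", "\\n"))


def _unescape(item: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(item):
        ch = item[i]
        if ch == "\\" and i + 1 < len(item):
            nxt = item[i + 1]
            out.append({"\\": "\\", "|": "|", "t": "\t", "n": "\n"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _split_piped(value: str) -> tuple[str, ...]:
    if value == "":
        return ()
    parts: list[str] = []
    cur: list[str] = []
    i = 0
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value):
            cur.append(ch + value[i + 1])
            i += 2
        elif ch == "|":
            parts.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(ch)
            i += 1
    parts.append("".join(cur))
    return tuple(_unescape(p) for p in parts)


def write_corpus_tsv(corpus: Corpus, sink: Union[str, IO]) -> None:
    """Write a lossless TSV cache of the corpus (UTF-8, header row).

    Multi-valued columns (descriptors, affiliations) are pipe-separated with
    backslash escaping, so delimiters inside values survive the round trip.
    """
    own = isinstance(sink, str)
    fh: IO = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        fh.write("\t".join(_CACHE_COLUMNS) + "\n")
        for rec in corpus:
            row = [
                _escape(rec.pmid),
                "" if rec.year is None else str(rec.year),
                "1" if rec.has_abstract else "0",
                "|".join(_escape(d) for d in rec.descriptors),
                "|".join(_escape(a) for a in rec.affiliations),
                "" if rec.title is None else _escape(rec.title),
            ]
            fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()


def read_corpus_tsv(source: Union[str, IO], provenance: str = "tsv-cache") -> Corpus:
    """Read a corpus cache produced by :func:`write_corpus_tsv`."""
    own = isinstance(source, str)
    fh: IO = open(source, encoding="utf-8") if own else source
    try:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _CACHE_COLUMNS:
            raise CorpusFormatError(
                f"line 1: unexpected cache header {header!r}"
            )
        records: list[PubMedRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(_CACHE_COLUMNS):
                raise CorpusFormatError(
                    f"line {lineno}: expected {len(_CACHE_COLUMNS)} columns, got {len(cols)}"
                )
            pmid, year_s, abs_s, desc_s, aff_s, title_s = cols
            try:
                records.append(
                    PubMedRecord(
                        pmid=_unescape(pmid),
                        year=int(year_s) if year_s else None,
                        has_abstract=abs_s == "1",
                        descriptors=_split_piped(desc_s),
                        affiliations=_split_piped(aff_s),
                        title=_unescape(title_s) if title_s else None,
                    )
                )
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
        return Corpus(records=tuple(records), provenance=provenance)
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Writers for fixture generation (exercise the real parser paths)
# ---------------------------------------------------------------------------

def write_pubmed_xml(corpus: Corpus, sink: Union[str, IO]) -> None:
    """Emit a corpus as a minimal ``PubmedArticleSet`` XML document."""
    root = etree.Element("PubmedArticleSet")
    for rec in corpus:
        article = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        art = etree.SubElement(cit, "Article")
        journal = etree.SubElement(art, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.year is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.year)
        if rec.title:
            etree.SubElement(art, "ArticleTitle").text = rec.title
        if rec.has_abstract:
            abstract = etree.SubElement(art, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = "Abstract available."
        if rec.affiliations:
            authors = etree.SubElement(art, "AuthorList")
            author = etree.SubElement(authors, "Author")
            for aff in rec.affiliations:
                info = etree.SubElement(author, "AffiliationInfo")
                etree.SubElement(info, "Affiliation").text = aff
        if rec.descriptors:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for raw in rec.descriptors:
                heading = etree.SubElement(mhl, "MeshHeading")
                name, *quals = raw.split("/")
                etree.SubElement(heading, "DescriptorName").text = name
                for q in quals:
                    etree.SubElement(heading, "QualifierName").text = q
    payload = etree.tostring(root, pretty_print=True, encoding="unicode")
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(payload)
    else:
        sink.write(payload)


def write_medline_nbib(corpus: Corpus, sink: Union[str, IO]) -> None:
    """Emit a corpus as a MEDLINE tagged flat file (nbib)."""

    def tag(name: str, value: str) -> str:
        return f"{name:<4}- {value}\n"

    own = isinstance(sink, str)
    fh: IO = open(sink, "w", encoding="utf-8") if own else sink
    try:
        for rec in corpus:
            fh.write(tag("PMID", rec.pmid))
            if rec.year is not None:
                fh.write(tag("DP", str(rec.year)))
            if rec.title:
                fh.write(tag("TI", rec.title))
            if rec.has_abstract:
                fh.write(tag("AB", "Abstract available."))
            for aff in rec.affiliations:
                fh.write(tag("AD", aff))
            for desc in rec.descriptors:
                fh.write(tag("MH", desc))
            fh.write("\n")
    finally:
        if own:
            fh.close()
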