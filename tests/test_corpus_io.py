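"""Corpus parsing, filtering, query construction, and cache round trips."""

import io
import random
from datetime import date

import pytest

from meshmine import (Corpus, CorpusFormatError, PubMedRecord, QuerySpec,
                      build_query, filter_corpus, merge_corpora,
                      parse_medline_nbib, parse_pubmed_xml, read_corpus_tsv,
                      write_corpus_tsv, write_medline_nbib, write_pubmed_xml)
from _utils import random_corpus
from conftest import record

ONE_ARTICLE_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>123</PMID>
   <Article>
    <Journal><JournalIssue><PubDate><Year>2015</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>A telehealth study</ArticleTitle>
    <Abstract><AbstractText>Some abstract text.</AbstractText></Abstract>
    <AuthorList><Author><AffiliationInfo>
      <Affiliation>University of Surrey, Guildford, UK</Affiliation>
    </AffiliationInfo></Author></AuthorList>
   </Article>
   <MeshHeadingList>
    <MeshHeading><DescriptorName>Telemedicine</DescriptorName></MeshHeading>
    <MeshHeading><DescriptorName>Obesity</DescriptorName></MeshHeading>
   </MeshHeadingList>
  </MedlineCitation>
 </PubmedArticle>
</PubmedArticleSet>
"""

ONE_ARTICLE_NBIB = """PMID- 123
DP  - 2015
TI  - A telehealth study
AB  - Some abstract text.
AD  - University of Surrey, Guildford, UK
MH  - Telemedicine
MH  - Obesity

"""


class TestParsePubmedXml:
    def test_minimal_article(self):
        corpus = parse_pubmed_xml(ONE_ARTICLE_XML)
        assert len(corpus) == 1
        rec = corpus.records[0]
        assert rec.pmid == "123"
        assert rec.year == 2015
        assert rec.descriptors == ("Telemedicine", "Obesity")
        assert rec.has_abstract
        assert rec.affiliations == ("University of Surrey, Guildford, UK",)

    def test_empty_article_set(self):
        assert len(parse_pubmed_xml("<PubmedArticleSet/>")) == 0

    def test_medlinedate_year_fallback(self):
        xml = ONE_ARTICLE_XML.replace(
            "<Year>2015</Year>", "<MedlineDate>2012 Jan-Feb</MedlineDate>")
        assert parse_pubmed_xml(xml).records[0].year == 2012

    def test_article_without_pmid_is_skipped(self, caplog):
        xml = ONE_ARTICLE_XML.replace("<PMID>123</PMID>", "")
        with caplog.at_level("WARNING"):
            corpus = parse_pubmed_xml(xml)
        assert len(corpus) == 0

    def test_malformed_xml_raises(self):
        with pytest.raises(CorpusFormatError, match="line"):
            parse_pubmed_xml("<PubmedArticleSet><broken")

    def test_qualifiers_kept_as_read(self):
        xml = ONE_ARTICLE_XML.replace(
            "<MeshHeading><DescriptorName>Telemedicine</DescriptorName></MeshHeading>",
            "<MeshHeading><DescriptorName>Telemedicine</DescriptorName>"
            "<QualifierName>methods</QualifierName></MeshHeading>")
        rec = parse_pubmed_xml(xml).records[0]
        assert "Telemedicine/methods" in rec.descriptors


class TestParseMedlineNbib:
    def test_minimal_block(self):
        text = "PMID- 9\nDP  - 2019\nMH  - Telemedicine\nMH  - Asthma\n\n"
        corpus = parse_medline_nbib(io.StringIO(text))
        assert len(corpus) == 1
        rec = corpus.records[0]
        assert (rec.pmid, rec.year) == ("9", 2019)
        assert rec.descriptors == ("Telemedicine", "Asthma")
        assert not rec.has_abstract

    def test_continuation_lines_folded(self):
        text = ("PMID- 9\nAB  - A very long abstract that\n"
                "      continues on the next line.\n\n")
        rec = parse_medline_nbib(io.StringIO(text)).records[0]
        assert rec.has_abstract

    def test_block_without_pmid_skipped(self):
        text = "DP  - 2019\nMH  - Telemedicine\n\n"
        assert len(parse_medline_nbib(io.StringIO(text))) == 0

    def test_cross_format_equivalence(self):
        via_xml = parse_pubmed_xml(ONE_ARTICLE_XML)
        via_nbib = parse_medline_nbib(io.StringIO(ONE_ARTICLE_NBIB))
        assert via_xml == via_nbib

    def test_cross_format_on_generated_corpora(self):
        rng = random.Random(7)
        for _ in range(10):
            corpus = random_corpus(rng, max_records=20)
            xml_buf, nbib_buf = io.StringIO(), io.StringIO()
            write_pubmed_xml(corpus, xml_buf)
            write_medline_nbib(corpus, nbib_buf)
            nbib_buf.seek(0)
            assert parse_pubmed_xml(xml_buf.getvalue()) == corpus
            assert parse_medline_nbib(nbib_buf) == corpus


class TestFilterCorpus:
    SPEC = QuerySpec(terms=("telemedicine",), date_from=date(2011, 1, 1),
                     date_to=date(2021, 12, 27))

    def test_year_window(self):
        corpus = Corpus(records=(
            record("1", ["X"], year=2009), record("2", ["X"], year=2015),
            record("3", ["X"], year=2022)))
        kept = filter_corpus(corpus, self.SPEC)
        assert [r.pmid for r in kept] == ["2"]

    def test_abstract_required(self):
        corpus = Corpus(records=(record("1", has_abstract=False),))
        assert len(filter_corpus(corpus, self.SPEC)) == 0

    def test_affiliation_substring_match(self):
        uk = record("1", affiliations=["University of Surrey, Guildford, UK"])
        de = record("2", affiliations=["Charité, Berlin, Germany"])
        kept = filter_corpus(Corpus(records=(uk, de)), self.SPEC)
        assert [r.pmid for r in kept] == ["1"]

    def test_case_insensitive_marker(self):
        rec = record("1", affiliations=["Somewhere, united kingdom"])
        assert len(filter_corpus(Corpus(records=(rec,)), self.SPEC)) == 1

    def test_idempotent(self):
        rng = random.Random(11)
        for _ in range(10):
            corpus = random_corpus(rng, max_records=30)
            once = filter_corpus(corpus, self.SPEC)
            assert filter_corpus(once, self.SPEC) == once


class TestBuildQuery:
    FULL_TERMS = ("Mobile applications", "digital health", "telemedicine",
                  "digital intervention", "health app", "medical informatics",
                  "health informatics", "digital technology")

    def test_structure(self):
        spec = QuerySpec(terms=("telemedicine", "digital health"),
                         date_from=date(2011, 1, 1), date_to=date(2021, 12, 27))
        query = build_query(spec)
        assert '"telemedicine" OR "digital health"' in query
        assert query.count("[Date - Publication]") == 2
        assert "hasabstract" in query

    def test_deterministic(self):
        spec = QuerySpec(terms=self.FULL_TERMS, date_from=date(2011, 1, 1),
                         date_to=date(2021, 12, 27))
        assert build_query(spec) == build_query(spec)

    def test_full_search_contains_each_phrase_once(self):
        spec = QuerySpec(terms=self.FULL_TERMS, date_from=date(2011, 1, 1),
                         date_to=date(2021, 12, 27))
        query = build_query(spec)
        for phrase in self.FULL_TERMS:
            assert query.count(f'"{phrase}"') == 1

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            QuerySpec(terms=(), date_from=date(2011, 1, 1),
                      date_to=date(2021, 12, 27))

    def test_inverted_dates_rejected(self):
        with pytest.raises(ValueError):
            QuerySpec(terms=("x",), date_from=date(2021, 1, 1),
                      date_to=date(2011, 12, 27))


class TestCorpusCache:
    def test_round_trip_random_corpora(self):
        rng = random.Random(3)
        for _ in range(20):
            corpus = random_corpus(rng, max_records=30)
            buf = io.StringIO()
            write_corpus_tsv(corpus, buf)
            buf.seek(0)
            assert read_corpus_tsv(buf) == corpus

    def test_delimiters_inside_values_survive(self):
        rec = record("1", descriptors=["Odd|Term", "Tab\there", "Back\\slash"],
                     title="Title with\ttab")
        corpus = Corpus(records=(rec,))
        buf = io.StringIO()
        write_corpus_tsv(corpus, buf)
        buf.seek(0)
        assert read_corpus_tsv(buf) == corpus

    def test_empty_corpus_round_trip(self):
        buf = io.StringIO()
        write_corpus_tsv(Corpus(records=()), buf)
        buf.seek(0)
        assert len(read_corpus_tsv(buf)) == 0

    def test_malformed_line_names_line_number(self):
        buf = io.StringIO("pmid\tyear\thas_abstract\tdescriptors\taffiliations\ttitle\n"
                          "1\t2015\t1\n")
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus_tsv(buf)

    def test_bad_header_rejected(self):
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_corpus_tsv(io.StringIO("nope\n"))


class TestInvariants:
    def test_duplicate_pmids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Corpus(records=(record("1"), record("1")))

    def test_merge_keeps_first_duplicate(self):
        a = Corpus(records=(record("1", ["Telemedicine"]),))
        b = Corpus(records=(record("1", ["Obesity"]), record("2")))
        merged = merge_corpora(a, b)
        assert [r.pmid for r in merged] == ["1", "2"]
        assert merged.records[0].descriptors == ("Telemedicine",)

    def test_duplicate_descriptors_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PubMedRecord(pmid="1", descriptors=("A", "A"))

    def test_parser_output_satisfies_record_invariants(self):
        rng = random.Random(23)
        for _ in range(10):
            corpus = random_corpus(rng, max_records=15)
            buf = io.StringIO()
            write_pubmed_xml(corpus, buf)
            parsed = parse_pubmed_xml(buf.getvalue())
            pmids = [r.pmid for r in parsed]
            assert len(set(pmids)) == len(pmids)
            for rec in parsed:
                assert rec.pmid
                assert len(set(rec.descriptors)) == len(rec.descriptors)
                assert rec.year is None or 1000 <= rec.year <= 9999
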