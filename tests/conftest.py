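"""Shared fixtures: small hand-written corpora in both dialects."""

import datetime as dt

import pytest

from litmine.corpus_io import Corpus, PublicationRecord

PUBMED_XML_FIVE = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>101</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2005</Year><Month>Mar</Month><Day>12</Day></PubDate></JournalIssue></Journal>
        <ArticleTitle>Hippocampal volume in depression</ArticleTitle>
        <Abstract><AbstractText>Smaller hippocampal volume was observed in patients.</AbstractText></Abstract>
        <Language>eng</Language>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
        <AuthorList><Author><AffiliationInfo><Affiliation>Department of Radiology, West China Hospital, Chengdu, China</Affiliation></AffiliationInfo></Author></AuthorList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Hippocampus</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Magnetic Resonance Imaging</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Depressive Disorder, Major</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
    <PubmedData>
      <ReferenceList>
        <Reference><ArticleIdList><ArticleId IdType="pubmed">102</ArticleId></ArticleIdList></Reference>
      </ReferenceList>
    </PubmedData>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>102</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2006</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>fMRI of mood circuits</ArticleTitle>
        <Language>eng</Language>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>103</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><MedlineDate>2007 Jul-Aug</MedlineDate></PubDate></JournalIssue></Journal>
        <ArticleTitle>PET imaging review</ArticleTitle>
        <Abstract><AbstractText Label="BACKGROUND">Tracers vary.</AbstractText><AbstractText Label="RESULTS">Uptake differs.</AbstractText></Abstract>
        <Language>eng</Language>
        <PublicationTypeList><PublicationType>Review</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>104</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2010</Year><Month>11</Month></PubDate></JournalIssue></Journal>
        <ArticleTitle>Ein Beitrag zur Radiologie</ArticleTitle>
        <Language>ger</Language>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>105</PMID>
      <Article>
        <ArticleTitle>Undated note</ArticleTitle>
        <Language>eng</Language>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""

MEDLINE_TWO = """PMID- 201
DP  - 2010 Mar 15
TI  - Resting-state connectivity in late-life depression
AB  - Functional connectivity of the default mode network was measured in
      elderly patients with major depression and matched controls using
      resting-state functional magnetic resonance imaging.
LA  - eng
PT  - Journal Article
MH  - Depressive Disorder, Major
MH  - Magnetic Resonance Imaging
AD  - Department of Psychiatry, University Hospital, Utrecht, Netherlands

PMID- 202
DP  - 2011
TI  - Strukturelle Bildgebung bei Depression
AB  - Eine Untersuchung der grauen Substanz.
LA  - ger
PT  - Review
"""


@pytest.fixture
def pubmed_xml_five() -> str:
    return PUBMED_XML_FIVE


@pytest.fixture
def medline_two() -> str:
    return MEDLINE_TWO


def _rec(pmid, year=2010, title="A title", abstract="brain imaging study of depression",
         language="eng", pub_types=None, **kwargs):
    return PublicationRecord(
        pmid=str(pmid), title=title, abstract=abstract, language=language,
        pub_year=year, pub_types=pub_types or ["Journal Article"], **kwargs)


@pytest.fixture
def ten_record_corpus() -> Corpus:
    """2 News-typed, 1 missing year, 1 dated 2023, 6 retained."""
    records = [
        _rec(1, 2003), _rec(2, 2005), _rec(3, 2010), _rec(4, 2015),
        _rec(5, 2019), _rec(6, 2021),
        _rec(7, 2010, pub_types=["News"]),
        _rec(8, 2012, pub_types=["Journal Article", "News"]),
        _rec(9, None),
        _rec(10, 2023),
    ]
    return Corpus(records=records)


@pytest.fixture
def eight_record_corpus() -> Corpus:
    """2 German records and 1 empty abstract among 8 -> 5 pass the
    topic-model filters (with a 5-token completeness threshold)."""
    long_abstract = "resting state imaging of mood circuits in adult patients"
    records = [
        _rec(1, abstract=long_abstract), _rec(2, abstract=long_abstract),
        _rec(3, abstract=long_abstract), _rec(4, abstract=long_abstract),
        _rec(5, abstract=long_abstract),
        _rec(6, language="ger", abstract=long_abstract),
        _rec(7, language="ger", abstract=long_abstract),
        _rec(8, abstract=""),
    ]
    return Corpus(records=records)


def make_record(*args, **kwargs):
    return _rec(*args, **kwargs)
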