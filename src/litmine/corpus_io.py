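"""Reading, writing and filtering of PubMed-derived publication corpora.

Two on-disk dialects are supported: the PubMed article-set XML exported by
the NCBI E-utilities, and the MEDLINE tagged flat file (``PMID- ``,
``TI  - `` ... with continuation lines).  Both are mapped onto the same
:class:`PublicationRecord` model so that every downstream stage is
dialect-agnostic.  A plain TSV serialization is provided for intermediate
pipeline artifacts.

Filtering mirrors the two-stage inclusion cascade used in bibliometric
studies of PubMed corpora: a general stage (publication-date window,
excluded publication types, records with missing data) followed by a
topic-modelling stage (English language, sufficiently complete abstract).
Every exclusion is counted exactly once under a fixed rule precedence so
that ``n_input - sum(exclusions) == n_retained`` holds for every input.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PublicationRecord",
    "Corpus",
    "FilterReport",
    "CorpusParseError",
    "read_pubmed_xml",
    "write_pubmed_xml",
    "read_medline",
    "write_medline",
    "read_tsv",
    "write_tsv",
    "apply_inclusion_filters",
    "apply_lda_filters",
    "DEFAULT_EXCLUDED_TYPES",
    "DEFAULT_WINDOW",
]

#: Publication types excluded from the general analysis by default.
#: Matched case-insensitively against each record's publication types.
DEFAULT_EXCLUDED_TYPES = frozenset(
    {
        "meeting abstract",
        "proceeding paper",
        "book review",
        "news item",
        "congress",
        "news",
        "published erratum",
    }
)

#: Default half-open publication-date window [2002-01-01, 2022-01-01).
DEFAULT_WINDOW = (_dt.date(2002, 1, 1), _dt.date(2022, 1, 1))

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


class CorpusParseError(ValueError):
    """Raised when an input stream cannot be parsed as a corpus."""


def _dedupe_casefold(terms: Iterable[str]) -> list[str]:
    """Drop duplicate terms under case-folding, keeping first spelling."""
    seen: set[str] = set()
    out: list[str] = []
    for t in terms:
        key = t.casefold()
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


@dataclass
class PublicationRecord:
    """One parsed article.

    ``pub_date`` is the journal publication date; a year-only date is
    stored as January 1 of that year.  ``affiliations`` is ordered and the
    first entry is taken as the "first organization" in downstream
    geographic analyses.  ``references`` holds cited PMIDs, which may point
    outside the corpus.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    language: str = ""
    pub_year: int | None = None
    pub_date: _dt.date | None = None
    pub_types: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)
    total_citations: int | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("PublicationRecord requires a nonempty pmid")
        if self.pub_year is not None and not (1900 <= self.pub_year <= 2100):
            raise ValueError(f"pub_year {self.pub_year} outside [1900, 2100]")
        self.mesh_terms = _dedupe_casefold(self.mesh_terms)
        if self.pub_date is None and self.pub_year is not None:
            self.pub_date = _dt.date(self.pub_year, 1, 1)
        if self.pub_date is not None and self.pub_year is None:
            self.pub_year = self.pub_date.year

    def has_type(self, type_name: str) -> bool:
        name = type_name.casefold()
        return any(t.casefold() == name for t in self.pub_types)


@dataclass
class Corpus:
    """An ordered collection of unique-PMID publication records."""

    records: list[PublicationRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(pmids) != len(set(pmids)):
            raise ValueError("Corpus contains duplicate PMIDs")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def pmids(self) -> list[str]:
        return [r.pmid for r in self.records]


@dataclass
class FilterReport:
    """Accounting of one filter pass.

    Each excluded record is counted under exactly one rule, so the
    conservation identity ``n_input - sum(n_excluded_by_rule.values())
    == n_retained`` holds exactly.
    """

    n_input: int
    n_excluded_by_rule: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input - sum(self.n_excluded_by_rule.values()) != self.n_retained:
            raise ValueError(
                "FilterReport violates conservation: "
                f"{self.n_input} - {sum(self.n_excluded_by_rule.values())} "
                f"!= {self.n_retained}"
            )

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_rule.values())

    def to_json(self, stream: IO[str] | None = None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_excluded_by_rule": self.n_excluded_by_rule,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
        }
        text = json.dumps(payload, indent=2)
        if stream is not None:
            stream.write(text)
        return text


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def _parse_year_token(text: str) -> int | None:
    m = re.search(r"(19|20)\d{2}", text or "")
    return int(m.group(0)) if m else None


def _parse_pubdate(elem) -> tuple[int | None, _dt.date | None]:
    """Parse a <PubDate> element into (year, date).

    Year-only dates resolve to January 1; a MedlineDate string contributes
    its first four-digit year.
    """
    if elem is None:
        return None, None
    year_el = elem.findtext("Year")
    if year_el:
        year = _parse_year_token(year_el)
        if year is None:
            return None, None
        month_txt = (elem.findtext("Month") or "").strip().casefold()
        month = _MONTHS.get(month_txt[:3], None)
        if month is None and month_txt.isdigit():
            month = int(month_txt)
        day_txt = (elem.findtext("Day") or "").strip()
        day = int(day_txt) if day_txt.isdigit() else 1
        try:
            return year, _dt.date(year, month or 1, day)
        except ValueError:
            return year, _dt.date(year, month or 1, 1)
    medline_date = elem.findtext("MedlineDate")
    if medline_date:
        year = _parse_year_token(medline_date)
        if year is not None:
            return year, _dt.date(year, 1, 1)
    return None, None


def _record_from_article(article) -> PublicationRecord | None:
    citation = article.find("MedlineCitation")
    if citation is None:
        return None
    pmid = (citation.findtext("PMID") or "").strip()
    if not pmid:
        return None
    art = citation.find("Article")
    title = abstract = language = ""
    pub_types: list[str] = []
    affiliations: list[str] = []
    year: int | None = None
    date: _dt.date | None = None
    if art is not None:
        title = "".join(art.find("ArticleTitle").itertext()).strip() if art.find("ArticleTitle") is not None else ""
        abs_el = art.find("Abstract")
        if abs_el is not None:
            parts = []
            for txt in abs_el.findall("AbstractText"):
                label = txt.get("Label")
                body = "".join(txt.itertext()).strip()
                parts.append(f"{label}: {body}" if label else body)
            abstract = " ".join(p for p in parts if p)
        language = (art.findtext("Language") or "").strip()
        year, date = _parse_pubdate(art.find("Journal/JournalIssue/PubDate"))
        pub_types = [
            "".join(pt.itertext()).strip()
            for pt in art.findall("PublicationTypeList/PublicationType")
        ]
        for aff in art.findall("AuthorList/Author/AffiliationInfo/Affiliation"):
            text = "".join(aff.itertext()).strip()
            if text:
                affiliations.append(text)
    mesh_terms = []
    for heading in citation.findall("MeshHeadingList/MeshHeading"):
        desc = heading.findtext("DescriptorName")
        if desc:
            mesh_terms.append(desc.strip())
        for qual in heading.findall("QualifierName"):
            if qual.text and qual.text.strip():
                mesh_terms.append(qual.text.strip())
    references = []
    pubmed_data = article.find("PubmedData")
    if pubmed_data is not None:
        for ref in pubmed_data.findall("ReferenceList/Reference"):
            rid = ref.findtext("ArticleIdList/ArticleId[@IdType='pubmed']")
            if rid and rid.strip():
                references.append(rid.strip())
    return PublicationRecord(
        pmid=pmid,
        title=title,
        abstract=abstract,
        language=language,
        pub_year=year,
        pub_date=date,
        pub_types=pub_types,
        mesh_terms=mesh_terms,
        affiliations=affiliations,
        references=references,
    )


def read_pubmed_xml(stream: IO[bytes] | IO[str] | str, provenance: str = "pubmed-xml") -> Corpus:
    """Parse a PubMed article-set XML stream into a :class:`Corpus`.

    Missing fields map to empty values; a duplicate PMID logs a warning
    and the last record wins.  Malformed XML raises
    :class:`CorpusParseError` carrying the reported position.
    """
    if isinstance(stream, str):
        data = stream.encode("utf-8")
    else:
        data = stream.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed PubMed XML: {exc}") from exc
    by_pmid: dict[str, PublicationRecord] = {}
    order: list[str] = []
    for article in root.iter("PubmedArticle"):
        rec = _record_from_article(article)
        if rec is None:
            continue
        if rec.pmid in by_pmid:
            logger.warning("duplicate PMID %s: keeping last occurrence", rec.pmid)
        else:
            order.append(rec.pmid)
        by_pmid[rec.pmid] = rec
    return Corpus(records=[by_pmid[p] for p in order], provenance=provenance)


def write_pubmed_xml(corpus: Corpus, stream: IO[str] | None = None) -> str:
    """Serialize a corpus to PubMed article-set XML."""
    root = etree.Element("PubmedArticleSet")
    for rec in corpus:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = rec.pmid
        art = etree.SubElement(citation, "Article")
        journal = etree.SubElement(art, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.pub_date is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.pub_date.year)
            etree.SubElement(pubdate, "Month").text = str(rec.pub_date.month)
            etree.SubElement(pubdate, "Day").text = str(rec.pub_date.day)
        etree.SubElement(art, "ArticleTitle").text = rec.title
        if rec.abstract:
            abs_el = etree.SubElement(art, "Abstract")
            etree.SubElement(abs_el, "AbstractText").text = rec.abstract
        if rec.language:
            etree.SubElement(art, "Language").text = rec.language
        if rec.pub_types:
            ptl = etree.SubElement(art, "PublicationTypeList")
            for pt in rec.pub_types:
                etree.SubElement(ptl, "PublicationType").text = pt
        if rec.affiliations:
            authors = etree.SubElement(art, "AuthorList")
            author = etree.SubElement(authors, "Author")
            for aff in rec.affiliations:
                info = etree.SubElement(author, "AffiliationInfo")
                etree.SubElement(info, "Affiliation").text = aff
        if rec.mesh_terms:
            mhl = etree.SubElement(citation, "MeshHeadingList")
            for term in rec.mesh_terms:
                heading = etree.SubElement(mhl, "MeshHeading")
                etree.SubElement(heading, "DescriptorName").text = term
        if rec.references:
            pubmed_data = etree.SubElement(article, "PubmedData")
            ref_list = etree.SubElement(pubmed_data, "ReferenceList")
            for rid in rec.references:
                ref = etree.SubElement(ref_list, "Reference")
                idl = etree.SubElement(ref, "ArticleIdList")
                aid = etree.SubElement(idl, "ArticleId")
                aid.set("IdType", "pubmed")
                aid.text = rid
    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# MEDLINE tagged flat file
# ---------------------------------------------------------------------------

# Dialect note: standard MEDLINE has no cited-reference or citation-count
# fields; RF (reference PMID, one per line) and TC (total citations) are
# emitted as round-trip extensions and ignored by other consumers.
_TAG_RE = re.compile(r"^([A-Z]{2,4})\s*- (.*)$")


def _medline_records(lines: Iterable[str]) -> Iterator[list[tuple[str, str]]]:
    current: list[tuple[str, str]] = []
    for raw in lines:
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            if current:
                yield current
                current = []
            continue
        if line.startswith("      ") and current:
            tag, value = current[-1]
            current[-1] = (tag, value + " " + line.strip())
            continue
        m = _TAG_RE.match(line)
        if m:
            current.append((m.group(1), m.group(2).strip()))
    if current:
        yield current


def _parse_dp(value: str) -> tuple[int | None, _dt.date | None]:
    parts = value.split()
    year = _parse_year_token(parts[0]) if parts else None
    if year is None:
        return None, None
    month = day = None
    if len(parts) > 1:
        month = _MONTHS.get(parts[1][:3].casefold())
    if len(parts) > 2 and parts[2].isdigit():
        day = int(parts[2])
    try:
        return year, _dt.date(year, month or 1, day or 1)
    except ValueError:
        return year, _dt.date(year, 1, 1)


def read_medline(stream: IO[str] | str, provenance: str = "medline") -> Corpus:
    """Parse MEDLINE tagged flat-file records into a :class:`Corpus`.

    Continuation lines (six leading spaces) are joined with single spaces.
    A record lacking a PMID is skipped with a logged warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    by_pmid: dict[str, PublicationRecord] = {}
    order: list[str] = []
    for fields in _medline_records(stream):
        tags: dict[str, list[str]] = {}
        for tag, value in fields:
            tags.setdefault(tag, []).append(value)
        pmid = tags.get("PMID", [""])[0].strip()
        if not pmid:
            logger.warning("MEDLINE record without PMID skipped")
            continue
        year, date = (None, None)
        if "DP" in tags:
            year, date = _parse_dp(tags["DP"][0])
        tc = tags.get("TC", [None])[0]
        rec = PublicationRecord(
            pmid=pmid,
            title=tags.get("TI", [""])[0],
            abstract=tags.get("AB", [""])[0],
            language=tags.get("LA", [""])[0],
            pub_year=year,
            pub_date=date,
            pub_types=tags.get("PT", []),
            mesh_terms=tags.get("MH", []),
            affiliations=tags.get("AD", []),
            references=tags.get("RF", []),
            total_citations=int(tc) if tc and tc.isdigit() else None,
        )
        if rec.pmid in by_pmid:
            logger.warning("duplicate PMID %s: keeping last occurrence", rec.pmid)
        else:
            order.append(rec.pmid)
        by_pmid[rec.pmid] = rec
    return Corpus(records=[by_pmid[p] for p in order], provenance=provenance)


def _wrap_medline(tag: str, value: str, width: int = 80) -> list[str]:
    # Wrapped lines are rejoined with single spaces on read, so values are
    # space-normalized here to keep the round trip lossless.
    prefix = f"{tag:<4}- "
    words = value.split()
    if not words:
        return [prefix]
    lines: list[str] = []
    current = prefix + words[0]
    for word in words[1:]:
        if len(current) + 1 + len(word) > width:
            lines.append(current)
            current = "      " + word
        else:
            current += " " + word
    lines.append(current)
    return lines


def write_medline(corpus: Corpus, stream: IO[str] | None = None) -> str:
    """Serialize a corpus to the MEDLINE tagged flat-file dialect."""
    out: list[str] = []
    for rec in corpus:
        out.extend(_wrap_medline("PMID", rec.pmid))
        if rec.pub_date is not None:
            month = [k for k, v in _MONTHS.items() if v == rec.pub_date.month][0].capitalize()
            out.extend(_wrap_medline("DP", f"{rec.pub_date.year} {month} {rec.pub_date.day}"))
        if rec.title:
            out.extend(_wrap_medline("TI", rec.title))
        if rec.abstract:
            out.extend(_wrap_medline("AB", rec.abstract))
        if rec.language:
            out.extend(_wrap_medline("LA", rec.language))
        for pt in rec.pub_types:
            out.extend(_wrap_medline("PT", pt))
        for mh in rec.mesh_terms:
            out.extend(_wrap_medline("MH", mh))
        for ad in rec.affiliations:
            out.extend(_wrap_medline("AD", ad))
        for rid in rec.references:
            out.extend(_wrap_medline("RF", rid))
        if rec.total_citations is not None:
            out.extend(_wrap_medline("TC", str(rec.total_citations)))
        out.append("")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# TSV serialization (pipeline intermediate)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "pmid", "title", "abstract", "language", "pub_year", "pub_date",
    "pub_types", "mesh_terms", "affiliations", "references", "total_citations",
]


def write_tsv(corpus: Corpus, stream: IO[str]) -> None:
    """Write one record per line; list fields are pipe-delimited."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for rec in corpus:
        writer.writerow([
            rec.pmid,
            rec.title,
            rec.abstract,
            rec.language,
            rec.pub_year if rec.pub_year is not None else "",
            rec.pub_date.isoformat() if rec.pub_date is not None else "",
            "|".join(rec.pub_types),
            "|".join(rec.mesh_terms),
            "|".join(rec.affiliations),
            "|".join(rec.references),
            rec.total_citations if rec.total_citations is not None else "",
        ])


def read_tsv(stream: IO[str], provenance: str = "tsv") -> Corpus:
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header != _TSV_COLUMNS:
        raise CorpusParseError(f"unexpected TSV header: {header!r}")
    records = []
    for row in reader:
        vals = dict(zip(_TSV_COLUMNS, row))
        records.append(PublicationRecord(
            pmid=vals["pmid"],
            title=vals["title"],
            abstract=vals["abstract"],
            language=vals["language"],
            pub_year=int(vals["pub_year"]) if vals["pub_year"] else None,
            pub_date=_dt.date.fromisoformat(vals["pub_date"]) if vals["pub_date"] else None,
            pub_types=vals["pub_types"].split("|") if vals["pub_types"] else [],
            mesh_terms=vals["mesh_terms"].split("|") if vals["mesh_terms"] else [],
            affiliations=vals["affiliations"].split("|") if vals["affiliations"] else [],
            references=vals["references"].split("|") if vals["references"] else [],
            total_citations=int(vals["total_citations"]) if vals["total_citations"] else None,
        ))
    return Corpus(records=records, provenance=provenance)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_inclusion_filters(
    corpus: Corpus,
    window: tuple[_dt.date, _dt.date] = DEFAULT_WINDOW,
    excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES,
) -> tuple[Corpus, FilterReport]:
    """General-analysis filter: date window, excluded types, missing data.

    ``window`` is half-open ``[start, end)`` on the journal publication
    date.  Missing data means an empty title or no parseable year.  Each
    excluded record is counted under the first matching rule in the fixed
    precedence date -> type -> missing-data; a record without a parseable
    date falls through the date rule to the missing-data rule.
    """
    start, end = window
    excluded = {t.casefold() for t in excluded_types}
    counts = {"date": 0, "type": 0, "missing_data": 0}
    kept: list[PublicationRecord] = []
    for rec in corpus:
        if rec.pub_date is not None and not (start <= rec.pub_date < end):
            counts["date"] += 1
            continue
        if any(t.casefold() in excluded for t in rec.pub_types):
            counts["type"] += 1
            continue
        if not rec.title or rec.pub_date is None:
            counts["missing_data"] += 1
            continue
        kept.append(rec)
    report = FilterReport(len(corpus), counts, len(kept))
    return Corpus(records=kept, provenance=corpus.provenance), report


def apply_lda_filters(
    corpus: Corpus,
    min_abstract_tokens: int = 50,
) -> tuple[Corpus, FilterReport]:
    """Topic-modelling filter: English language, complete abstract.

    Language is matched case-insensitively and only ``eng`` counts as
    English.  An abstract is incomplete when it has fewer than
    ``min_abstract_tokens`` whitespace-separated tokens (an empty abstract
    always is).  Precedence: language -> incomplete-abstract.
    """
    counts = {"language": 0, "incomplete_abstract": 0}
    kept: list[PublicationRecord] = []
    for rec in corpus:
        if rec.language.casefold() != "eng":
            counts["language"] += 1
            continue
        if len(rec.abstract.split()) < min_abstract_tokens:
            counts["incomplete_abstract"] += 1
            continue
        kept.append(rec)
    report = FilterReport(len(corpus), counts, len(kept))
    return Corpus(records=kept, provenance=corpus.provenance), report
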