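"""Publication-level analytics: trends, types, MeSH, geography, citations.

The centerpiece is the exponential growth model for yearly publication
counts, y = a * e^(b*x) with x = year - first_year + 1, fitted by ordinary
least squares on the log scale (the convention of spreadsheet exponential
trendlines, which makes the fitted (a, b) directly comparable to values
reported alongside such charts).  Everything else is careful counting:
per-year tallies, per-type trends in multi-year bins, MeSH descriptor
frequencies, country extraction from first-affiliation strings, and
internal-citation rankings over the within-corpus reference graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import Corpus

__all__ = [
    "TrendTable",
    "GrowthFit",
    "yearly_counts",
    "fit_exponential_growth",
    "summarize_trend",
    "publication_type_trends",
    "mesh_frequency",
    "extract_country",
    "country_counts",
    "internal_citations",
    "topic_year_matrix",
    "DEFAULT_GAZETTEER",
    "AGE_GROUP_MESH",
    "BRAIN_STRUCTURE_MESH",
]


@dataclass
class TrendTable:
    """Per-year publication counts over a contiguous year range."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.counts:
            years = sorted(self.counts)
            full = range(years[0], years[-1] + 1)
            self.counts = {y: int(self.counts.get(y, 0)) for y in full}

    @property
    def years(self) -> list[int]:
        return sorted(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def series(self) -> pd.Series:
        return pd.Series(self.counts, name="publications").sort_index()


def yearly_counts(corpus: Corpus, window: tuple[int, int] | None = None) -> TrendTable:
    """Exact per-year tallies, zero-filled for empty years in the window."""
    counts: dict[int, int] = {}
    for rec in corpus:
        if rec.pub_year is None:
            continue
        if window and not (window[0] <= rec.pub_year <= window[1]):
            continue
        counts[rec.pub_year] = counts.get(rec.pub_year, 0) + 1
    if window:
        for y in range(window[0], window[1] + 1):
            counts.setdefault(y, 0)
    return TrendTable(counts)


@dataclass
class GrowthFit:
    """Exponential trend y = a * e^(b*x), x = year - first_year + 1.

    ``r_squared`` is the coefficient of determination of the log-linear
    fit (on ln y).  ``zero_variance`` flags a constant input series, whose
    R^2 is reported as 1 by convention (the flat fit is exact).
    """

    a: float
    b: float
    r_squared: float
    first_year: int
    n_years_fit: int
    zero_variance: bool = False
    x_convention: str = "x = year - first_year + 1"

    def predict(self, year: int) -> float:
        x = year - self.first_year + 1
        return self.a * math.exp(self.b * x)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "r_squared": self.r_squared,
            "first_year": self.first_year, "n_years_fit": self.n_years_fit,
            "zero_variance": self.zero_variance, "x_convention": self.x_convention,
        }


def fit_exponential_growth(trend: TrendTable) -> GrowthFit:
    """Log-linear least squares for the exponential growth law.

    Zero-count years are excluded (their log is undefined) with a
    warning; at least three positive years are required.
    """
    years = np.array(trend.years)
    counts = np.array([trend.counts[y] for y in years], dtype=float)
    positive = counts > 0
    if (~positive).any():
        warnings.warn(f"{int((~positive).sum())} zero-count years excluded from fit")
    years, counts = years[positive], counts[positive]
    if len(years) < 3:
        raise ValueError("need at least three years with positive counts")
    first_year = int(trend.years[0])
    x = years - first_year + 1
    logy = np.log(counts)
    b, log_a = np.polyfit(x, logy, 1)
    resid = logy - (log_a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    zero_variance = ss_tot == 0.0
    r2 = 1.0 if zero_variance else 1.0 - ss_res / ss_tot
    return GrowthFit(a=float(np.exp(log_a)), b=float(b), r_squared=float(r2),
                     first_year=first_year, n_years_fit=len(years),
                     zero_variance=zero_variance)


def summarize_trend(trend: TrendTable) -> dict:
    """Mean annual output and growth rates of a yearly count series.

    ``mean_growth_rate`` is the arithmetic mean of the year-over-year
    relative changes (years following a zero count are skipped with a
    flag); ``compound_growth_rate`` is the geometric endpoint rate
    (y_end / y_start)^(1/(n-1)) - 1.  Both are reported because the two
    conventions differ on noisy series.
    """
    years = trend.years
    if not years:
        raise ValueError("empty trend table")
    values = [trend.counts[y] for y in years]
    growth_rates: dict[int, float] = {}
    skipped = []
    for prev_y, y in zip(years, years[1:]):
        prev = trend.counts[prev_y]
        if prev == 0:
            skipped.append(y)
            continue
        growth_rates[y] = (trend.counts[y] - prev) / prev
    compound = None
    if len(years) > 1 and values[0] > 0 and values[-1] > 0:
        compound = (values[-1] / values[0]) ** (1.0 / (len(years) - 1)) - 1.0
    return {
        "total": trend.total,
        "n_years": len(years),
        "mean_annual": trend.total / len(years),
        "growth_rates": growth_rates,
        "mean_growth_rate": (sum(growth_rates.values()) / len(growth_rates)
                             if growth_rates else None),
        "compound_growth_rate": compound,
        "skipped_zero_base_years": skipped,
    }


def publication_type_trends(
    corpus: Corpus,
    type_whitelist: list[str],
    bin_width_years: int = 5,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Counts per (publication type, year bin).

    A record carrying several whitelisted types counts once under each;
    bins are ``bin_width_years`` wide from the window start, the last bin
    truncated if the width does not divide the window.
    """
    if not type_whitelist:
        return pd.DataFrame(columns=["type", "bin", "count"])
    years = [r.pub_year for r in corpus if r.pub_year is not None]
    if window is None:
        if not years:
            return pd.DataFrame(columns=["type", "bin", "count"])
        window = (min(years), max(years))
    start, end = window
    bins = []
    lo = start
    while lo <= end:
        hi = min(lo + bin_width_years - 1, end)
        bins.append((lo, hi))
        lo = hi + 1
    rows = []
    for t in type_whitelist:
        for (lo, hi) in bins:
            n = sum(1 for r in corpus
                    if r.pub_year is not None and lo <= r.pub_year <= hi
                    and r.has_type(t))
            rows.append({"type": t, "bin": f"{lo}-{hi}", "count": n})
    return pd.DataFrame(rows)


#: MeSH descriptors for the age-group sub-analysis.
AGE_GROUP_MESH = ["Infant", "Child", "Adolescent", "Young Adult", "Adult",
                  "Middle Aged", "Aged", "Aged, 80 and over"]

#: MeSH descriptors for the brain-structure sub-analysis.
BRAIN_STRUCTURE_MESH = ["Cerebral Cortex", "Prefrontal Cortex", "Hippocampus",
                        "Amygdala", "Thalamus", "Gyrus Cinguli", "Brain Stem",
                        "Corpus Callosum", "Basal Ganglia", "Hypothalamus"]


def mesh_frequency(
    corpus: Corpus,
    term_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Ranked (term, count) table of MeSH descriptor frequencies.

    A descriptor counts once per record bearing it (case-folded);
    ``term_subset`` restricts the table to a named list such as
    :data:`AGE_GROUP_MESH`, preserving zero-count members.
    """
    counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for rec in corpus:
        for term in rec.mesh_terms:   # already deduplicated per record
            key = term.casefold()
            counts[key] = counts.get(key, 0) + 1
            display.setdefault(key, term)
    if term_subset is not None:
        rows = [{"term": t, "count": counts.get(t.casefold(), 0)}
                for t in term_subset]
    else:
        rows = [{"term": display[k], "count": n} for k, n in counts.items()]
    df = pd.DataFrame(rows, columns=["term", "count"])
    return df.sort_values(["count", "term"], ascending=[False, True],
                          ignore_index=True)


#: Country alias -> canonical name, matched case-insensitively against
#: comma-separated affiliation segments scanned right to left.
DEFAULT_GAZETTEER = {
    "usa": "USA", "united states": "USA", "united states of america": "USA",
    "u.s.a": "USA",
    "china": "China", "p.r. china": "China", "pr china": "China",
    "people's republic of china": "China",
    "uk": "United Kingdom", "united kingdom": "United Kingdom",
    "england": "United Kingdom", "scotland": "United Kingdom",
    "wales": "United Kingdom", "northern ireland": "United Kingdom",
    "japan": "Japan", "germany": "Germany", "netherlands": "Netherlands",
    "the netherlands": "Netherlands", "canada": "Canada", "france": "France",
    "italy": "Italy", "australia": "Australia",
    "south korea": "South Korea", "republic of korea": "South Korea",
    "korea": "South Korea", "spain": "Spain", "brazil": "Brazil",
    "india": "India", "switzerland": "Switzerland", "sweden": "Sweden",
    "turkey": "Turkey", "greece": "Greece", "belgium": "Belgium",
    "austria": "Austria", "norway": "Norway", "denmark": "Denmark",
    "finland": "Finland", "poland": "Poland", "portugal": "Portugal",
    "ireland": "Ireland", "israel": "Israel", "taiwan": "Taiwan",
    "singapore": "Singapore", "new zealand": "New Zealand",
    "mexico": "Mexico", "russia": "Russia", "iran": "Iran",
    "egypt": "Egypt", "south africa": "South Africa",
}


def _normalize_segment(segment: str) -> str:
    return " ".join(
        segment.replace(".", " ").replace(";", " ").split()
    ).casefold().strip()


def extract_country(
    affiliation_text: str,
    gazetteer: dict[str, str] | None = None,
) -> str:
    """Country of an affiliation string, or ``"Unknown"``.

    Comma-separated segments are scanned right to left (countries sit at
    the end of PubMed affiliations); the first segment that matches a
    gazetteer alias — as the whole segment, after stripping digits/zip
    codes, or as its trailing words — wins.
    """
    gaz = DEFAULT_GAZETTEER if gazetteer is None else gazetteer
    for segment in reversed(affiliation_text.split(",")):
        norm = _normalize_segment(segment)
        if not norm:
            continue
        if norm in gaz:
            return gaz[norm]
        words = [w for w in norm.split() if not any(ch.isdigit() for ch in w)]
        # try trailing word runs: "st louis usa" -> "usa"; "mo 63110 usa"
        for start in range(len(words)):
            tail = " ".join(words[start:])
            if tail in gaz:
                return gaz[tail]
    return "Unknown"


def country_counts(
    corpus: Corpus,
    gazetteer: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Country distribution over first affiliations.

    One country per record (its first organization); percentages are over
    records with a known country, and the Unknown tally is reported as a
    separate row with a blank percentage for transparency.
    """
    counts: dict[str, int] = {}
    for rec in corpus:
        country = (extract_country(rec.affiliations[0], gazetteer)
                   if rec.affiliations else "Unknown")
        counts[country] = counts.get(country, 0) + 1
    n_known = sum(n for c, n in counts.items() if c != "Unknown")
    if n_known == 0 and counts:
        warnings.warn("no record yielded a known country")
    rows = []
    for country, n in counts.items():
        rows.append({
            "country": country,
            "count": n,
            "percent": (100.0 * n / n_known
                        if country != "Unknown" and n_known else np.nan),
        })
    df = pd.DataFrame(rows, columns=["country", "count", "percent"])
    return df.sort_values(["count", "country"], ascending=[False, True],
                          ignore_index=True)


def internal_citations(corpus: Corpus) -> pd.DataFrame:
    """Within-corpus citation ranking.

    The internal count of a record is the number of *other* corpus records
    whose reference lists include its PMID (self-citations ignored, a
    citing record counted once).  Rows are ranked by descending count,
    ties by ascending PMID.
    """
    pmids = set(corpus.pmids)
    counts = {p: 0 for p in pmids}
    for rec in corpus:
        for cited in set(rec.references):
            if cited in pmids and cited != rec.pmid:
                counts[cited] += 1
    df = pd.DataFrame(
        [{"pmid": r.pmid, "internal_citations": counts[r.pmid],
          "total_citations": r.total_citations} for r in corpus],
        columns=["pmid", "internal_citations", "total_citations"],
    )
    return df.sort_values(["internal_citations", "pmid"],
                          ascending=[False, True], ignore_index=True)


def topic_year_matrix(
    primary_topics: list[int],
    years: list[int],
    n_topics: int,
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Topics x years matrix of primary-topic document counts.

    Entry (k, y) counts documents whose primary topic is k published in
    year y; row index 0..n_topics-1, columns the contiguous year range.
    """
    if len(primary_topics) != len(years):
        raise ValueError("primary_topics and years must align")
    if year_range is None:
        if not years:
            return pd.DataFrame(index=range(n_topics))
        year_range = (min(years), max(years))
    cols = list(range(year_range[0], year_range[1] + 1))
    mat = np.zeros((n_topics, len(cols)), dtype=np.int64)
    for k, y in zip(primary_topics, years):
        if year_range[0] <= y <= year_range[1]:
            mat[k, y - year_range[0]] += 1
    return pd.DataFrame(mat, index=range(n_topics), columns=cols)
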