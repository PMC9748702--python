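"""Trend fitting, tallies, geography and citation analytics."""

import numpy as np
import pytest

from litmine.bibliometrics import (
    AGE_GROUP_MESH,
    TrendTable,
    country_counts,
    extract_country,
    fit_exponential_growth,
    internal_citations,
    mesh_frequency,
    publication_type_trends,
    summarize_trend,
    topic_year_matrix,
    yearly_counts,
)
from litmine.corpus_io import Corpus

from conftest import make_record


class TestYearlyCounts:
    def test_zero_filled_years(self):
        corpus = Corpus(records=[make_record(i, 2005) for i in range(3)]
                        + [make_record(9, 2007)])
        trend = yearly_counts(corpus)
        assert trend.counts == {2005: 3, 2006: 0, 2007: 1}

    def test_empty_corpus(self):
        trend = yearly_counts(Corpus(), window=(2002, 2004))
        assert trend.counts == {2002: 0, 2003: 0, 2004: 0}
        assert trend.total == 0

    def test_equals_brute_force_group_by(self):
        rng = np.random.default_rng(0)
        years = rng.integers(2002, 2022, size=60)
        corpus = Corpus(records=[make_record(i, int(y))
                                 for i, y in enumerate(years)])
        trend = yearly_counts(corpus)
        for y in trend.years:
            assert trend.counts[y] == int((years == y).sum())
        assert trend.total == 60


class TestGrowthFit:
    def test_noiseless_exponential_recovered_exactly(self):
        years = range(2002, 2022)
        counts = {y: 70 * np.exp(0.11 * (y - 2002 + 1)) for y in years}
        trend = TrendTable({y: counts[y] for y in years})
        # TrendTable stores ints; build values that stay exact on the log
        # scale by bypassing integer rounding
        trend.counts = counts
        fit = fit_exponential_growth(trend)
        assert fit.a == pytest.approx(70.0, abs=1e-9)
        assert fit.b == pytest.approx(0.11, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.predict(2002) == pytest.approx(70 * np.exp(0.11), abs=1e-6)

    def test_constant_series_zero_slope_flagged(self):
        trend = TrendTable({y: 42 for y in range(2010, 2015)})
        fit = fit_exponential_growth(trend)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.a == pytest.approx(42.0, rel=1e-12)
        assert fit.r_squared == 1.0
        assert fit.zero_variance

    def test_zero_years_excluded_with_warning(self):
        trend = TrendTable({2010: 10, 2011: 0, 2012: 12, 2013: 15})
        with pytest.warns(UserWarning):
            fit = fit_exponential_growth(trend)
        assert fit.n_years_fit == 3

    def test_noisy_series_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        years = np.arange(2002, 2022)
        x = years - 2002 + 1
        counts = np.round(70 * np.exp(0.11 * x) * np.exp(rng.normal(0, 0.1, 20)))
        trend = TrendTable({int(y): int(c) for y, c in zip(years, counts)})
        fit = fit_exponential_growth(trend)
        # independent closed-form OLS solve on (x, ln y)
        logy = np.log(counts)
        X = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(X.T @ X, X.T @ logy)
        assert fit.a == pytest.approx(np.exp(coef[0]), rel=1e-9)
        assert fit.b == pytest.approx(coef[1], rel=1e-9)

    def test_too_few_positive_years_errors(self):
        with pytest.raises(ValueError):
            fit_exponential_growth(TrendTable({2010: 5, 2011: 6}))


class TestSummarizeTrend:
    def test_hand_arithmetic_series(self):
        summary = summarize_trend(TrendTable({2000: 100, 2001: 110, 2002: 121}))
        assert summary["growth_rates"] == {
            2001: pytest.approx(0.10), 2002: pytest.approx(0.10)}
        assert summary["mean_growth_rate"] == pytest.approx(0.10)
        assert summary["compound_growth_rate"] == pytest.approx(0.10)
        assert summary["mean_annual"] == pytest.approx(331 / 3)

    def test_zero_base_year_skipped(self):
        summary = summarize_trend(TrendTable({2000: 0, 2001: 5, 2002: 10}))
        assert summary["skipped_zero_base_years"] == [2001]
        assert summary["growth_rates"] == {2002: pytest.approx(1.0)}


class TestPublicationTypeTrends:
    def _corpus(self):
        return Corpus(records=[
            make_record(1, 2003, pub_types=["Review", "Multicenter Study"]),
            make_record(2, 2004, pub_types=["Review"]),
            make_record(3, 2009, pub_types=["Case Reports"]),
            make_record(4, 2009, pub_types=["Review"]),
        ])

    def test_multi_type_record_counts_in_each_row(self):
        table = publication_type_trends(
            self._corpus(), ["Review", "Multicenter Study"],
            bin_width_years=5, window=(2002, 2011))
        by = {(r["type"], r["bin"]): r["count"] for _, r in table.iterrows()}
        assert by[("Review", "2002-2006")] == 2
        assert by[("Multicenter Study", "2002-2006")] == 1
        assert by[("Review", "2007-2011")] == 1

    def test_empty_whitelist(self):
        assert publication_type_trends(self._corpus(), []).empty

    def test_truncated_last_bin(self):
        table = publication_type_trends(self._corpus(), ["Review"],
                                        bin_width_years=5, window=(2002, 2009))
        assert list(table["bin"]) == ["2002-2006", "2007-2009"]


class TestMeshFrequency:
    def test_once_per_record(self):
        corpus = Corpus(records=[
            make_record(i, mesh_terms=["Hippocampus"]) for i in range(3)])
        table = mesh_frequency(corpus)
        assert table.iloc[0]["term"] == "Hippocampus"
        assert table.iloc[0]["count"] == 3

    def test_case_folded_duplicates_count_once(self):
        corpus = Corpus(records=[
            make_record(1, mesh_terms=["Hippocampus", "hippocampus", "Adult"])])
        table = mesh_frequency(corpus)
        assert dict(zip(table["term"], table["count"])) == {
            "Hippocampus": 1, "Adult": 1}

    def test_subset_preserves_zero_counts(self):
        corpus = Corpus(records=[make_record(1, mesh_terms=["Adult"])])
        table = mesh_frequency(corpus, term_subset=AGE_GROUP_MESH)
        by = dict(zip(table["term"], table["count"]))
        assert by["Adult"] == 1
        assert by["Child"] == 0

    def test_equals_brute_force_multiset_count(self):
        rng = np.random.default_rng(2)
        pool = ["Adult", "Aged", "Brain", "Sleep"]
        corpus = Corpus(records=[
            make_record(i, mesh_terms=list(rng.choice(pool, size=2, replace=False)))
            for i in range(30)])
        table = mesh_frequency(corpus)
        brute = {}
        for rec in corpus:
            for t in set(m.casefold() for m in rec.mesh_terms):
                brute[t] = brute.get(t, 0) + 1
        assert {t.casefold(): c for t, c in zip(table["term"], table["count"])} == brute


class TestExtractCountry:
    def test_affiliations_with_trailing_country(self):
        assert extract_country(
            "Huaxi MR Research Center (HMRRC), Department of Radiology, "
            "West China Hospital of Sichuan University, Chengdu, China") == "China"
        assert extract_country(
            "Department of Psychological & Brain Sciences, Washington "
            "University in St. Louis, USA") == "USA"

    def test_zip_code_segment(self):
        assert extract_country(
            "Massachusetts General Hospital, Charlestown, MA 02129, USA") == "USA"

    def test_unknown(self):
        assert extract_country("Institute of Nowhere") == "Unknown"

    def test_alias_normalization(self):
        assert extract_country("Some Lab, P.R. China") == "China"
        assert extract_country("A Hospital, The Netherlands") == "Netherlands"


class TestCountryCounts:
    def test_known_country_denominator(self):
        corpus = Corpus(records=[
            make_record(1, affiliations=["Lab, Beijing, China"]),
            make_record(2, affiliations=["Lab, Shanghai, China"]),
            make_record(3, affiliations=["Lab, Boston, USA"]),
            make_record(4, affiliations=["Institute of Nowhere"]),
        ])
        table = country_counts(corpus)
        by = {r["country"]: r for _, r in table.iterrows()}
        assert by["China"]["percent"] == pytest.approx(200 / 3)
        assert by["USA"]["percent"] == pytest.approx(100 / 3)
        assert by["Unknown"]["count"] == 1
        assert np.isnan(by["Unknown"]["percent"])

    def test_all_unknown_warns(self):
        corpus = Corpus(records=[make_record(1, affiliations=["Nowhere"])])
        with pytest.warns(UserWarning):
            table = country_counts(corpus)
        assert table.iloc[0]["country"] == "Unknown"

    def test_first_affiliation_only(self):
        corpus = Corpus(records=[make_record(
            1, affiliations=["Lab, Tokyo, Japan", "Lab, Berlin, Germany"])])
        table = country_counts(corpus)
        assert list(table["country"]) == ["Japan"]


class TestInternalCitations:
    def test_external_references_ignored(self):
        corpus = Corpus(records=[
            make_record(1, references=["2", "EXT999"]),
            make_record(2),
        ])
        table = internal_citations(corpus)
        by = dict(zip(table["pmid"], table["internal_citations"]))
        assert by == {"2": 1, "1": 0}

    def test_no_references_all_zero(self):
        corpus = Corpus(records=[make_record(i) for i in range(4)])
        table = internal_citations(corpus)
        assert (table["internal_citations"] == 0).all()

    def test_self_citation_ignored(self):
        corpus = Corpus(records=[make_record(1, references=["1"])])
        assert internal_citations(corpus)["internal_citations"].sum() == 0

    def test_counts_equal_in_degrees_of_generated_dag(self):
        from litmine.synthetic import GeneratorConfig, generate_corpus
        config = GeneratorConfig(K_true=3, V=30, n_docs=60, doc_length=10,
                                 citation_density=2.0,
                                 external_ref_fraction=0.3, seed=21)
        corpus, _ = generate_corpus(config)
        table = internal_citations(corpus)
        indeg = {p: 0 for p in corpus.pmids}
        n_edges = 0
        for rec in corpus:
            for ref in rec.references:
                if ref in indeg:
                    indeg[ref] += 1
                    n_edges += 1
        assert dict(zip(table["pmid"], table["internal_citations"])) == indeg
        assert table["internal_citations"].sum() == n_edges


class TestTopicYearMatrix:
    def test_single_cell(self):
        df = topic_year_matrix([3, 3], [2010, 2010], n_topics=5)
        assert df.loc[3, 2010] == 2
        assert df.values.sum() == 2

    def test_conservation_and_brute_force_crosstab(self):
        rng = np.random.default_rng(7)
        topics = list(rng.integers(0, 4, size=50))
        years = list(rng.integers(2005, 2010, size=50))
        df = topic_year_matrix(topics, years, n_topics=4)
        assert df.values.sum() == 50
        for k, y in zip(topics, years):
            assert df.loc[k, y] == sum(
                1 for kk, yy in zip(topics, years) if kk == k and yy == y)
        # column sums are yearly totals
        for y in df.columns:
            assert df[y].sum() == years.count(y)
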