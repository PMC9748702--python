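# Methods

This note documents the models, conventions and numerical choices behind
`litmine`, and what the synthetic-data tests do and do not establish about
behaviour on real PubMed corpora.

## Record model and filter cascade

A `PublicationRecord` carries the fields a bibliometric pipeline consumes:
PMID, title, abstract, language code, publication date, publication types,
MeSH descriptors, ordered affiliations (the first entry is the "first
organization"), cited PMIDs and an optional total-citation count. Year
binning uses the journal publication date; a year-only date resolves to
January 1. MeSH descriptors are de-duplicated per record under
case-folding, so frequency analyses count presence, not repetition —
matching how PubMed lists each descriptor once.

Filtering is two-staged. The **inclusion stage** retains records inside a
half-open date window (default [2002-01-01, 2022-01-01), which expresses
"between January 1 of the start year and January 1 of the end year"
without double-counting the boundary), drops configured publication types
(meeting abstracts, proceedings, book reviews, news items and close PubMed
variants), and drops missing-data records. "Missing data" is
operationalized as an empty title or no parseable year — the concept has
no standard definition, and these two fields are the ones every later
stage requires. The **topic-model stage** keeps English records (`eng`
only, case-insensitive) with an abstract of at least 50 whitespace tokens
(configurable); very short abstracts carry too little text to inform a
topic model and behave like missing data.

Each excluded record is counted under exactly one rule in the fixed
precedence *date → type → missing-data*. A record with no parseable date
cannot be judged by the date rule and falls through to missing-data. The
conservation identity `n_input − Σ exclusions = n_retained` is enforced in
the `FilterReport` constructor itself, so a violated report cannot even be
built.

MEDLINE is parsed with the standard tag/continuation-line grammar
(wrapped lines are rejoined with single spaces, so whitespace inside
values is normalized on a round trip). Two extension tags, `RF` (cited
PMID) and `TC` (total citations), let the flat-file dialect round-trip
fields that standard MEDLINE does not carry; other consumers ignore them.

## Preprocessing

Tokenization is deliberately minimal: case-fold, split on every
non-alphanumeric character, drop tokens shorter than 2 characters and
tokens on a fixed English stop-word list that ships frozen inside the
package (importing a live list from another library would tie results to
that library's version). No stemming by default — unstemmed tokens are
easier to audit in topic-term lists — with a crude plural stripper behind
a flag. Titles are excluded by default and can be concatenated in by flag;
abstract-only is the conservative reading when the source of the text
matters.

The vocabulary keeps terms with document frequency in [min_df,
max_df_fraction·n_docs] (defaults 5 and 0.5 — conventional topic-model
hygiene: singletons carry no co-occurrence signal, near-ubiquitous terms
behave like stop-words) and indexes the survivors lexicographically, so a
given corpus always yields the same matrix. Documents whose tokens all
fall outside the vocabulary are kept as empty rows and flagged, preserving
row alignment with the corpus.

## Collapsed-Gibbs LDA

The sampler integrates out θ and φ and resamples each token's topic from
its conditional. Defaults: α = 50/K and β = 0.01 (the classic heuristic
when the application itself dictates nothing), 1,000 sweeps with 500
burn-in. Sweep order is fixed (documents in matrix order, tokens by
ascending word index) and all randomness comes from one explicit
generator, one uniform variate per token per sweep — runs are bitwise
reproducible for a given seed regardless of how the inner loop is
compiled (the hot loop is numba-compiled for throughput).

θ and φ are computed from the post-burn-in *averaged* counts by default,
which smooths single-sample chain noise; the final-sweep state is
available behind a flag. Empty documents are never visited, contribute
nothing to the likelihood and receive uniform θ.

Perplexity is exp(−Σ_d Σ_tokens log Σ_k θ_dk φ_kw / Σ_d N_d). Held-out
documents get θ by fold-in: Gibbs sweeps over the held-out tokens with φ
frozen (default 200 sweeps, 100 burn-in). `select_topic_count` reports
held-out perplexity and redundancy (mean pairwise cosine similarity of φ
rows; 0 by convention at K = 1) per candidate K. It deliberately makes no
automatic choice: in practice the topic count is chosen jointly on
perplexity, redundancy and whether a human finds the topics legible, and
the last criterion cannot be scored mechanically.

Correctness is established two ways. On corpora small enough to enumerate
(≤ 6 tokens), empirical state frequencies over 50,000 post-burn-in sweeps
sit within total-variation distance 0.05 of the exact collapsed posterior
computed by brute force from the Dirichlet-multinomial marginal
likelihood. On generated corpora, the fitted φ is compared to the
generating φ after optimal one-to-one topic matching (Hungarian
assignment on the pairwise total-variation matrix): at 5 topics,
separation 0.9, 400 documents of mean length 60, the mean matched TV
distance is ≈ 0.03, comfortably under the 0.10 recovery bar.

## Topic network and communities

Each document's two highest-probability topics (ties broken toward the
lower index; pairs stored smaller-index-first) define the network:
node size = number of documents with that primary topic, edge weight
(j,k) = number of documents whose top-2 set is {j,k}. No probability
floor is applied — a near-uniform θ row still contributes — because any
threshold would be arbitrary and the conservation identities
(Σ sizes = assigned documents, Σ weights = documents with a pair) are
more valuable for auditing.

Modularity is the weighted Newman–Girvan form with a resolution
parameter multiplying the expectation term (resolution 1.0 by default,
matching common network tooling; coarser partitions of many-topic graphs
need lower values, and the parameter is exposed). The Louvain optimizer
implements the classic two phases — greedy local moves to the best
positive ΔQ with ties broken toward the lowest community id, then
aggregation of communities into super-nodes — iterated to a fixed point.
Because the greedy search is order-dependent and can lodge in local
optima (the 6-node path graph is a minimal example, where a fixed
ascending visit order yields Q = 0.26 against an optimum of 0.30), the
optimizer runs seeded random-restart searches (default 50 restarts; the
first uses the deterministic ascending order) and keeps the best-Q
partition. The result is deterministic for a given seed. Reported Q is
always recomputed from the definition on the original graph. On the
test-suite graphs (≤ 8 nodes) the restart search attains the exhaustively
verified maximum; this is *not* a general guarantee of the algorithm.

## Trend and metadata analytics

The growth model is y = a·e^(bx) with x = year − first_year + 1, fitted
by ordinary least squares on (x, ln y) — the convention of spreadsheet
exponential trendlines, so fitted coefficients are directly comparable to
values reported alongside such charts. R² is computed on the log scale.
Zero-count years are excluded from the fit with a warning (their log is
undefined); a constant series gets b = 0, a = the constant, and R²
reported as 1 with a `zero_variance` flag, since the flat fit is exact.
`predict(year)` uses the same x convention and documents it in the
result object.

`summarize_trend` reports both the arithmetic mean of year-over-year
growth rates and the compound (geometric endpoint) rate, labelled — the
two conventions genuinely differ on noisy series and published "average
annual growth" figures rarely state which was used.

Country extraction scans comma-separated affiliation segments right to
left (countries end PubMed affiliations), matching each segment — whole,
digit-stripped, or by trailing word runs (handles "MA 02129, USA") —
against a gazetteer of country aliases; no hit yields `Unknown`. Only the
first affiliation is used, one country per record. Percentages are taken
over records with a known country, with the Unknown tally reported
alongside, so the denominator is explicit.

Internal citations count, for each record, the number of *other* corpus
records citing it (per citing record, duplicates and self-citations
ignored); the total equals the number of within-corpus reference edges.
Rankings break ties by ascending PMID.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:

- **Text** from the LDA generative process over a pseudo-word vocabulary
  (`w0017`-style, zero-padded so lexicographic order equals index
  order). Topic-word distributions are Dirichlet draws on structured
  supports: each topic owns an exclusive word block and shares a common
  pool, sized so the exclusive fraction equals `topic_separation`
  (fully disjoint supports at 1.0). Document lengths are Poisson.
  An optional stop-word "salt" interleaves English function words to
  exercise stop-word removal.
- **Growth**: yearly counts Poisson with intensity a·e^(bx) (or a fixed
  total multinomially spread over the same intensity). Defaults a = 70,
  b = 0.11 over 2002–2021, the scale of the emulated field (~5.4k
  documents over 20 years).
- **Metadata**: categorical country/publication-type/MeSH draws. Default
  country shares put USA at 21.5% and China at 20.6% with 10% of records
  carrying no recognizable country; publication types mix the eight
  standard PubMed study categories; MeSH descriptors follow roughly
  Zipfian weights headed by the field's most frequent headings.
- **Citations**: each (citing, strictly-earlier-cited) pair is included
  with probability chosen so the expected internal out-degree equals
  `(1 − external_fraction)·citation_density`; external references come
  from a disjoint `EXT`-prefixed PMID namespace. The internal graph is a
  DAG by construction.

What passing tests on this generator show: the sampler, the estimators,
the network construction and every tally are correct, and the pipeline
recovers planted structure under realistic sizes. What they do not show:
behaviour on real abstracts (no natural-language morphology, synonymy or
topic drift), real affiliation strings (free-text noise far beyond
"Department, City, Country"), or real citation behaviour (no preferential
attachment, no topical correlation). Conclusions about a real corpus
still require the human topic-labelling and legibility judgements the
package deliberately leaves to the analyst.

## Problem sizes in routine runs

The bundled test and reproduction runs use scaled study conditions chosen
to exercise every code path at sizes a laptop handles interactively:
topic recovery at 5 topics × 400 documents × mean length 60, sampler
enumeration on ≤ 6-token corpora with 50k samples, exhaustive modularity
search on ≤ 8-node graphs (Bell-number enumeration grows too fast beyond
that), and metadata analytics on 2,000-record corpora. The generator's
defaults remain at the full emulated scale (50 topics, ~5.4k documents)
for users who want field-sized corpora.

## Known limitations

- The Gibbs sampler is single-chain and single-threaded; no convergence
  diagnostics beyond perplexity are computed.
- Louvain restarts make small-instance optimality empirical, not proven;
  large graphs inherit the usual resolution-limit caveats of modularity.
- The MEDLINE writer normalizes internal whitespace (a consequence of
  line wrapping), so byte-exact round trips require single-spaced input.
- Country extraction is gazetteer-bound; affiliations naming only a city
  or institute resolve to Unknown rather than being geocoded.
- Organization analytics use exact first-affiliation strings; no
  institution-name disambiguation is attempted.
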