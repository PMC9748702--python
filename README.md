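# litmine

Topic-model bibliometrics for PubMed-derived corpora.

`litmine` is for researchers who want to map how a biomedical field has
evolved from its literature alone: which themes the abstracts contain, how
those themes cluster and co-occur, and how publication activity, study
types, MeSH usage, geography and within-field citations have shifted over
time. It was built around corpora of the "depression AND radiology" kind —
a few thousand PubMed records spanning two decades — but applies to any
PubMed XML or MEDLINE download.

## What it computes

**Topic model.** Latent Dirichlet allocation fitted by collapsed Gibbs
sampling, implemented from scratch. Each document *d* mixes *K* topics
(θ_d ~ Dirichlet(α)); each topic *k* is a distribution over the vocabulary
(φ_k ~ Dirichlet(β)). With θ and φ integrated out, each token's topic is
resampled from

    P(z_i = k | z_-i, w)  ∝  (n_dk + α) · (n_kw + β) / (n_k + V β)

and point estimates are read off the (post-burn-in averaged) counts:
θ_dk = (n_dk + α)/(N_d + Kα), φ_kw = (n_kw + β)/(n_k + Vβ). Model quality
is summarized by perplexity, exp(−mean per-token log-likelihood), with
held-out evaluation via fold-in sampling; `select_topic_count` reports
perplexity and topic redundancy per candidate *K* and leaves the final
choice — which also weighs topic legibility — to the analyst.

**Topic network.** Each document contributes its two highest-probability
topics: the primary topic sizes the nodes, the unordered top-2 pair
increments an edge weight. Communities come from a from-scratch Louvain
optimizer of weighted Newman–Girvan modularity
Q = Σ_c [Σ_in/2m − (Σ_tot/2m)²], with seeded random-restart search.

**Bibliometrics.** Yearly counts with an exponential trend fit
y = a·e^(bx) (log-linear least squares, x = year − first year + 1),
publication-type trends in multi-year bins, MeSH descriptor frequencies
(with age-group and brain-structure subsets), country extraction from
first-affiliation strings, and internal-citation rankings over the
within-corpus reference graph.

**Filter cascade.** The standard two-stage inclusion pipeline: a date
window with excluded publication types and missing-data rules, then an
English-language / complete-abstract stage for topic modelling — with
exact, audited accounting (`n_input − Σ exclusions = n_retained` always).

**Synthetic corpora.** A generator that emits PubMed-XML/MEDLINE/TSV
corpora drawn from the LDA generative process with known ground truth
(φ, θ, token assignments), exponentially growing yearly counts,
categorical country/type/MeSH metadata and a backward-in-time citation
graph — so every stage is testable without any download.

## Worked example

```python
from litmine import (GeneratorConfig, generate_corpus, vectorize,
                     LdaHyperparams, fit_lda, doc_topic_distribution,
                     topic_word_distribution, match_topics, top_terms,
                     top2_assignments, build_cooccurrence_graph, louvain)
from litmine.synthetic import true_vocabulary
from litmine.bibliometrics import yearly_counts, fit_exponential_growth

config = GeneratorConfig(K_true=12, V=600, n_docs=600, doc_length=60,
                         topic_separation=0.9, alpha_true=0.3, seed=42)
corpus, truth = generate_corpus(config)
dtm = vectorize(corpus, true_vocabulary(config, corpus))

model = fit_lda(dtm, LdaHyperparams(K=12, alpha=0.3, beta=0.01,
                                    n_iterations=800, n_burnin=400, seed=0))
phi = topic_word_distribution(model)
matching, mean_tv = match_topics(phi, truth.phi_true)
print(f"mean matched TV: {mean_tv:.3f}")
print("topic 0 top terms:", ", ".join(top_terms(model, 0, 5)))

theta = doc_topic_distribution(model)
graph = build_cooccurrence_graph(top2_assignments(theta), n_topics=12)
comms = louvain(graph, seed=0)
print(f"{graph.number_of_edges()} edges, {comms.n_communities} communities, "
      f"Q = {comms.modularity:.3f}")

fit = fit_exponential_growth(yearly_counts(corpus))
print(f"y = {fit.a:.1f} e^({fit.b:.3f} x), R2={fit.r_squared:.2f}")
```

Output:

```
mean matched TV: 0.029
topic 0 top terms: w0589, w0554, w0587, w0598, w0570
66 edges, 2 communities, Q = 0.013
y = 7.3 e^(0.114 x), R2=0.94
```

The fitted topic-word distributions sit within mean total-variation
distance 0.029 of the generating ones after optimal (Hungarian) topic
matching — the sampler recovered the planted topics. Topic 0's top terms
are the pseudo-words of its exclusive support block. The 12-topic
co-occurrence graph splits into 2 communities at low modularity (mixtures
here are drawn symmetrically, so topic pairs co-occur nearly uniformly —
real corpora show stronger block structure). The yearly counts, drawn from
an exponential intensity, are refitted with growth rate b = 0.114 and
R² = 0.94; `a` is scaled down because the example fixes the total corpus
size rather than the intensity's absolute level.

## Command line

The same pipeline is scriptable via subcommands — `simulate`, `ingest`,
`filter`, `preprocess`, `fit`, `select-k`, `network`, `trends`, and
`report`, which chains everything and writes a manifest:

```bash
litmine report --config config.json --out results/ --seed 1
```

Every stage logs its boundary counts, writes only plain-text formats
(TSV, MatrixMarket, JSON, GEXF/GraphML) and records the resolved
configuration next to its outputs.

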