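"""Synthetic PubMed-like corpora with known ground truth.

Documents are drawn from the latent-Dirichlet-allocation generative
process (per-document topic mixture theta_d ~ Dirichlet(alpha); per-token
topic z ~ Cat(theta_d); word w ~ Cat(phi_z)) over a pseudo-word vocabulary
("w0017"-style tokens), so topic-recovery and perplexity behaviour can be
tested against the exact generating distributions.  Around the text sits
the metadata a bibliometric pipeline consumes: publication dates whose
yearly counts follow an exponential intensity a*e^(b*x), categorical
country / publication-type / MeSH draws, and a strictly-backward-in-time
citation graph.

Defaults emulate the depression-and-radiology PubMed corpus this package
was built around: 50 topics, a 2002-2021 window, and yearly growth
70*e^(0.11*x) (about 5.4k documents over 20 years).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, PublicationRecord
from .preprocess import Vocabulary

__all__ = [
    "GeneratorConfig",
    "TrueModel",
    "generate_corpus",
    "generate_citation_graph",
    "true_vocabulary",
    "DEFAULT_COUNTRY_PROBS",
    "DEFAULT_PUBTYPE_PROBS",
    "DEFAULT_MESH_POOL",
]

#: Country shares, top entries matching the reported distribution of the
#: emulated corpus (USA 21.5%, China 20.6%, Japan 6.4%, ...); the residual
#: mass is emitted as an affiliation with no recognizable country.
DEFAULT_COUNTRY_PROBS = {
    "USA": 0.215, "China": 0.206, "Japan": 0.064, "Germany": 0.054,
    "Netherlands": 0.046, "United Kingdom": 0.045, "Canada": 0.040,
    "France": 0.035, "Italy": 0.030, "Australia": 0.025,
    "South Korea": 0.025, "Spain": 0.020, "Brazil": 0.020, "India": 0.020,
    "Switzerland": 0.015, "Sweden": 0.015, "Turkey": 0.015, "Greece": 0.010,
    None: 0.100,
}

#: PubMed publication-type mix (every record also carries Journal Article).
DEFAULT_PUBTYPE_PROBS = {
    "Journal Article": 0.45, "Case Reports": 0.12, "Review": 0.10,
    "Comparative Study": 0.10, "Randomized Controlled Trial": 0.06,
    "Clinical Trial": 0.05, "Multicenter Study": 0.04,
    "Meta-Analysis": 0.04, "Systematic Review": 0.04,
}

#: MeSH descriptor pool with roughly Zipfian weights, headed by the
#: descriptors most frequent in the emulated field.
_MESH_TERMS = [
    "Diagnostic Imaging", "Magnetic Resonance Imaging", "Physiopathology",
    "Adult", "Aged", "Middle Aged", "Depressive Disorder, Major",
    "Depression", "Brain", "Adolescent", "Cerebral Cortex",
    "Prefrontal Cortex", "Hippocampus", "Functional Neuroimaging",
    "Child", "Amygdala", "Thalamus", "Sleep", "Breast Neoplasms",
    "Coronary Artery Disease", "Gyrus Cinguli", "Positron-Emission Tomography",
    "Neural Pathways", "Anxiety", "Cognition",
]
DEFAULT_MESH_POOL = {t: 1.0 / (i + 1) for i, t in enumerate(_MESH_TERMS)}


def _normalize(probs: dict) -> tuple[list, np.ndarray]:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("probabilities must be nonnegative with positive sum")
    return keys, p / p.sum()


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``n_docs``: explicit document count (years then drawn from the
    normalized exponential intensity) or ``None`` to draw each year's
    count as Poisson(growth_a * e^(growth_b * x)), x = year - start + 1.
    ``topic_separation`` in [0, 1] is the fraction of each topic's word
    support that is exclusive to it; at 1.0 topic supports are fully
    disjoint (requires V >= K_true).
    """

    K_true: int = 50
    V: int = 2000
    alpha_true: float = 1.0
    beta_true: float = 0.1
    n_docs: int | None = None
    growth_a: float = 70.0
    growth_b: float = 0.11
    doc_length: float = 100.0
    topic_separation: float = 0.8
    year_range: tuple[int, int] = (2002, 2021)
    country_probs: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    pubtype_probs: dict = field(default_factory=lambda: dict(DEFAULT_PUBTYPE_PROBS))
    mesh_pool: dict = field(default_factory=lambda: dict(DEFAULT_MESH_POOL))
    mesh_per_doc: float = 8.0
    citation_density: float = 3.0
    external_ref_fraction: float = 0.3
    stopword_salt: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if not (0.0 <= self.topic_separation <= 1.0):
            raise ValueError("topic_separation must lie in [0, 1]")
        if self.topic_separation == 1.0 and self.V < self.K_true:
            raise ValueError("topic_separation=1 requires V >= K_true")
        if self.V < 1 or self.alpha_true <= 0 or self.beta_true <= 0:
            raise ValueError("V >= 1 and positive Dirichlet concentrations required")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must be <= end")


@dataclass
class TrueModel:
    """Ground truth of one generated corpus: phi, theta, token assignments."""

    phi_true: np.ndarray          # K_true x V, row-stochastic
    theta_true: np.ndarray        # n_docs x K_true, row-stochastic
    z_tokens: list[np.ndarray]    # per document, topic of each token
    w_tokens: list[np.ndarray]    # per document, word index of each token
    terms: list[str]              # word index -> pseudo-word

    @property
    def n_tokens(self) -> int:
        return int(sum(len(z) for z in self.z_tokens))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "phi_true.tsv", self.phi_true, delimiter="\t")
        np.savetxt(directory / "theta_true.tsv", self.theta_true, delimiter="\t")
        meta = {
            "K_true": int(self.phi_true.shape[0]),
            "V": int(self.phi_true.shape[1]),
            "n_docs": int(self.theta_true.shape[0]),
            "n_tokens": self.n_tokens,
            "terms": self.terms,
        }
        (directory / "truth.json").write_text(json.dumps(meta))


def _pseudo_words(V: int) -> list[str]:
    width = max(4, len(str(V - 1)))
    return [f"w{i:0{width}d}" for i in range(V)]


def _topic_supports(K: int, V: int, separation: float) -> list[np.ndarray]:
    """Partition word indices into per-topic exclusive blocks plus a shared
    pool so that the exclusive fraction of each support equals
    ``separation`` (up to rounding)."""
    if separation >= 1.0:
        # fully disjoint: spread all V words over the K topics
        bounds = np.linspace(0, V, K + 1).astype(int)
        return [np.arange(bounds[k], bounds[k + 1]) for k in range(K)]
    m = V / (K * separation + 1.0 - separation)   # support size per topic
    d = int(round(separation * m))                # exclusive words per topic
    d = min(d, V // K)
    shared = np.arange(K * d, V)
    return [np.concatenate([np.arange(k * d, (k + 1) * d), shared]) for k in range(K)]


def _sample_phi(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    phi = np.zeros((config.K_true, config.V))
    for k, support in enumerate(_topic_supports(config.K_true, config.V,
                                                config.topic_separation)):
        if len(support) == 0:
            raise ValueError("a topic received an empty word support; increase V")
        phi[k, support] = rng.dirichlet(np.full(len(support), config.beta_true))
    return phi


def _sample_years(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    start, end = config.year_range
    years = np.arange(start, end + 1)
    x = years - start + 1
    intensity = config.growth_a * np.exp(config.growth_b * x)
    if config.n_docs is not None:
        counts = rng.multinomial(config.n_docs, intensity / intensity.sum())
    else:
        counts = rng.poisson(intensity)
    return np.repeat(years, counts)


_SALT_WORDS = ["the", "and", "of", "in", "with", "for"]


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, TrueModel]:
    """Draw a corpus and its ground truth from the generative process.

    Deterministic under ``config.seed``.  Records are ordered
    chronologically; abstracts are space-joined pseudo-words (plus an
    optional English stop-word salt that is excluded from the ground-truth
    token record).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    terms = _pseudo_words(config.V)
    phi = _sample_phi(rng, config)
    doc_years = np.sort(_sample_years(rng, config))
    n_docs = len(doc_years)
    theta = rng.dirichlet(np.full(config.K_true, config.alpha_true), size=n_docs) \
        if n_docs else np.zeros((0, config.K_true))

    countries, p_country = _normalize(config.country_probs)
    pubtypes, p_pubtype = _normalize(config.pubtype_probs)
    mesh_terms_pool, p_mesh = _normalize(config.mesh_pool)

    records: list[PublicationRecord] = []
    z_tokens: list[np.ndarray] = []
    w_tokens: list[np.ndarray] = []
    for d in range(n_docs):
        length = int(rng.poisson(config.doc_length))
        z = rng.choice(config.K_true, size=length, p=theta[d])
        w = np.empty(length, dtype=np.int64)
        for k in np.unique(z):
            mask = z == k
            w[mask] = rng.choice(config.V, size=int(mask.sum()), p=phi[k])
        z_tokens.append(z)
        w_tokens.append(w)
        words = [terms[j] for j in w]
        if config.stopword_salt > 0 and length:
            salted = []
            for token in words:
                salted.append(token)
                if rng.random() < config.stopword_salt:
                    salted.append(_SALT_WORDS[int(rng.integers(len(_SALT_WORDS)))])
            words = salted
        year = int(doc_years[d])
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        country = countries[int(rng.choice(len(countries), p=p_country))]
        if country is None:
            affiliation = f"Department of Radiology, Hospital {d % 20}, Springfield"
        else:
            affiliation = (f"Department of Radiology, Hospital {d % 20}, "
                           f"City {d % 7}, {country}")
        ptype = pubtypes[int(rng.choice(len(pubtypes), p=p_pubtype))]
        pub_types = [ptype] if ptype == "Journal Article" else ["Journal Article", ptype]
        n_mesh = min(int(rng.poisson(config.mesh_per_doc)), len(mesh_terms_pool))
        mesh = list(rng.choice(mesh_terms_pool, size=n_mesh, replace=False,
                               p=p_mesh)) if n_mesh else []
        records.append(PublicationRecord(
            pmid=f"SYN{d:06d}",
            title=f"Synthetic study {d} on topic mixture",
            abstract=" ".join(words),
            language="eng",
            pub_year=year,
            pub_date=_dt.date(year, month, day),
            pub_types=pub_types,
            mesh_terms=mesh,
            affiliations=[affiliation],
        ))
    corpus = Corpus(records=records,
                    provenance=f"synthetic seed={config.seed} K={config.K_true}")
    truth = TrueModel(phi_true=phi, theta_true=theta,
                      z_tokens=z_tokens, w_tokens=w_tokens, terms=terms)
    if config.citation_density > 0 and n_docs:
        corpus = generate_citation_graph(
            corpus, config.citation_density,
            seed=int(rng.integers(2**31 - 1)),
            external_fraction=config.external_ref_fraction,
        )
    return corpus, truth


def generate_citation_graph(
    corpus: Corpus,
    citation_density: float,
    seed: int = 0,
    external_fraction: float = 0.0,
) -> Corpus:
    """Attach reference lists so documents cite only strictly earlier ones.

    Internal references are Bernoulli per (citing, earlier-cited) pair with
    probability chosen so the expected internal out-degree is
    ``(1 - external_fraction) * citation_density`` whenever enough earlier
    documents exist; external references (Poisson with the complementary
    mean) use a disjoint ``EXT``-prefixed PMID namespace.  The resulting
    internal graph is a DAG by construction.
    """
    rng = np.random.default_rng(seed)
    dated = [(r.pub_date, i) for i, r in enumerate(corpus)]
    internal_mean = (1.0 - external_fraction) * citation_density
    external_mean = external_fraction * citation_density
    ext_counter = 0
    new_records = []
    for i, rec in enumerate(corpus):
        earlier = [corpus[j].pmid for date, j in dated
                   if date is not None and rec.pub_date is not None
                   and date < rec.pub_date]
        refs: list[str] = []
        if earlier and internal_mean > 0:
            p = min(1.0, internal_mean / len(earlier))
            hits = rng.random(len(earlier)) < p
            refs.extend(pm for pm, h in zip(earlier, hits) if h)
        if external_mean > 0:
            for _ in range(int(rng.poisson(external_mean))):
                refs.append(f"EXT{ext_counter:08d}")
                ext_counter += 1
        new_records.append(PublicationRecord(
            pmid=rec.pmid, title=rec.title, abstract=rec.abstract,
            language=rec.language, pub_year=rec.pub_year, pub_date=rec.pub_date,
            pub_types=list(rec.pub_types), mesh_terms=list(rec.mesh_terms),
            affiliations=list(rec.affiliations), references=refs,
            total_citations=rec.total_citations,
        ))
    return Corpus(records=new_records, provenance=corpus.provenance)


def true_vocabulary(config: GeneratorConfig, corpus: Corpus | None = None) -> Vocabulary:
    """Vocabulary over the full generator word list (lexicographic order
    coincides with word-index order thanks to zero padding), with document
    frequencies computed from ``corpus`` when given."""
    terms = _pseudo_words(config.V)
    df = {t: 0 for t in terms}
    if corpus is not None:
        for rec in corpus:
            for t in set(rec.abstract.split()):
                if t in df:
                    df[t] += 1
    return Vocabulary(terms=terms, doc_freq=df)
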