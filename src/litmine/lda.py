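"""Collapsed-Gibbs latent Dirichlet allocation.

The sampler integrates out the document-topic mixtures theta and the
topic-word distributions phi, resampling each token's topic from its
conditional given all other assignments.  Point estimates are read off the
count state:

    theta_dk = (n_dk + alpha) / (N_d + K alpha)
    phi_kw   = (n_kw + beta)  / (n_k + V beta)

By default the counts are averaged over the post-burn-in sweeps, which
smooths the single-sample noise of the chain; the last-sample state is
available behind a flag.  Model selection reports held-out perplexity
(fold-in estimation of theta for unseen documents) and a topic-redundancy
score per candidate K; the final choice of K is left to the analyst, since
topic legibility cannot be scored mechanically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._gibbs import foldin_sweep, gibbs_sweep
from .preprocess import DocumentTermMatrix, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "LdaHyperparams",
    "LdaModel",
    "fit_lda",
    "doc_topic_distribution",
    "topic_word_distribution",
    "perplexity",
    "infer_theta",
    "select_topic_count",
    "top_terms",
    "match_topics",
]


@dataclass
class LdaHyperparams:
    """Sampler configuration.

    ``alpha`` defaults to the classic 50/K heuristic and ``beta`` to 0.01
    when left unset.  ``average_state`` selects averaged post-burn-in
    counts (default) versus the final sweep's state for theta/phi.
    """

    K: int
    alpha: float | None = None
    beta: float = 0.01
    n_iterations: int = 1000
    n_burnin: int = 500
    seed: int = 0
    average_state: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha is None:
            self.alpha = 50.0 / self.K
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("need 0 <= n_burnin < n_iterations")


@dataclass
class LdaModel:
    """Fitted sampler state.

    ``n_dk``/``n_kw``/``n_k`` are the final-sweep integer counts (always
    consistent with ``z``); ``mean_n_dk``/``mean_n_kw`` are the post-burn-in
    averages used for theta/phi when ``average_state`` is on.
    """

    hyperparams: LdaHyperparams
    vocabulary: Vocabulary
    doc_ids: list[str]
    doc_of: np.ndarray
    word_of: np.ndarray
    z: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    mean_n_dk: np.ndarray
    mean_n_kw: np.ndarray

    @property
    def n_docs(self) -> int:
        return self.n_dk.shape[0]

    @property
    def n_terms(self) -> int:
        return self.n_kw.shape[1]

    @property
    def doc_lengths(self) -> np.ndarray:
        return self.n_dk.sum(axis=1)

    def check_consistency(self) -> None:
        """Verify the count state against the raw assignments."""
        K, V = self.n_kw.shape
        n_dk = np.zeros_like(self.n_dk)
        n_kw = np.zeros_like(self.n_kw)
        np.add.at(n_dk, (self.doc_of, self.z), 1)
        np.add.at(n_kw, (self.z, self.word_of), 1)
        if not (np.array_equal(n_dk, self.n_dk) and np.array_equal(n_kw, self.n_kw)
                and np.array_equal(self.n_kw.sum(axis=1), self.n_k)):
            raise AssertionError("LDA count state inconsistent with assignments")


def _expand_tokens(dtm: DocumentTermMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the count matrix into per-token (doc, word) arrays, in
    document order then ascending word index — the fixed sweep order."""
    coo = dtm.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    doc_of = np.repeat(coo.row[order].astype(np.int64), coo.data[order])
    word_of = np.repeat(coo.col[order].astype(np.int64), coo.data[order])
    return doc_of, word_of


def fit_lda(dtm: DocumentTermMatrix, hyperparams: LdaHyperparams) -> LdaModel:
    """Run the collapsed Gibbs sampler on a document-term matrix.

    Empty documents carry no tokens and are simply never visited; an
    all-empty matrix is an error.  Deterministic under the seed.
    """
    if dtm.n_tokens == 0:
        raise ValueError("cannot fit LDA on an all-empty document-term matrix")
    hp = hyperparams
    doc_of, word_of = _expand_tokens(dtm)
    n_tokens = doc_of.shape[0]
    K, V = hp.K, dtm.n_terms
    rng = np.random.default_rng(hp.seed)
    z = rng.integers(0, K, size=n_tokens).astype(np.int64)
    n_dk = np.zeros((dtm.n_docs, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, word_of), 1)
    n_k = n_kw.sum(axis=1)
    cum = np.empty(K, dtype=np.float64)
    sum_n_dk = np.zeros((dtm.n_docs, K), dtype=np.float64)
    sum_n_kw = np.zeros((K, V), dtype=np.float64)
    n_kept = 0
    for sweep in range(hp.n_iterations):
        uniforms = rng.random(n_tokens)
        gibbs_sweep(doc_of, word_of, z, n_dk, n_kw, n_k,
                    float(hp.alpha), float(hp.beta), uniforms, cum)
        if sweep >= hp.n_burnin:
            sum_n_dk += n_dk
            sum_n_kw += n_kw
            n_kept += 1
    return LdaModel(
        hyperparams=hp,
        vocabulary=dtm.vocabulary,
        doc_ids=list(dtm.doc_ids),
        doc_of=doc_of,
        word_of=word_of,
        z=z,
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_k,
        mean_n_dk=sum_n_dk / n_kept,
        mean_n_kw=sum_n_kw / n_kept,
    )


def sample_posterior(
    dtm: DocumentTermMatrix,
    hyperparams: LdaHyperparams,
    n_samples: int,
) -> np.ndarray:
    """Post-burn-in topic-assignment snapshots of the collapsed chain.

    Runs ``hyperparams.n_burnin`` warm-up sweeps and then ``n_samples``
    further sweeps, recording the full assignment vector after each: a
    ``(n_samples, n_tokens)`` array whose empirical state frequencies
    converge to the exact collapsed posterior P(z | w).  Intended for
    sampler validation on tiny corpora.
    """
    hp = hyperparams
    doc_of, word_of = _expand_tokens(dtm)
    n_tokens = doc_of.shape[0]
    rng = np.random.default_rng(hp.seed)
    z = rng.integers(0, hp.K, size=n_tokens).astype(np.int64)
    n_dk = np.zeros((dtm.n_docs, hp.K), dtype=np.int64)
    n_kw = np.zeros((hp.K, dtm.n_terms), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, word_of), 1)
    n_k = n_kw.sum(axis=1)
    cum = np.empty(hp.K, dtype=np.float64)
    states = np.empty((n_samples, n_tokens), dtype=np.int64)
    for sweep in range(hp.n_burnin + n_samples):
        uniforms = rng.random(n_tokens)
        gibbs_sweep(doc_of, word_of, z, n_dk, n_kw, n_k,
                    float(hp.alpha), float(hp.beta), uniforms, cum)
        if sweep >= hp.n_burnin:
            states[sweep - hp.n_burnin] = z
    return states


def _state_counts(model: LdaModel) -> tuple[np.ndarray, np.ndarray]:
    if model.hyperparams.average_state:
        return model.mean_n_dk, model.mean_n_kw
    return model.n_dk.astype(float), model.n_kw.astype(float)


def doc_topic_distribution(model: LdaModel) -> np.ndarray:
    """theta (docs x K): (n_dk + alpha) / (N_d + K alpha); empty documents
    get the uniform vector."""
    hp = model.hyperparams
    n_dk, _ = _state_counts(model)
    lengths = n_dk.sum(axis=1, keepdims=True)
    theta = (n_dk + hp.alpha) / (lengths + hp.K * hp.alpha)
    empty = lengths.ravel() == 0
    theta[empty] = 1.0 / hp.K
    return theta


def topic_word_distribution(model: LdaModel) -> np.ndarray:
    """phi (K x V): (n_kw + beta) / (n_k + V beta)."""
    hp = model.hyperparams
    _, n_kw = _state_counts(model)
    n_k = n_kw.sum(axis=1, keepdims=True)
    return (n_kw + hp.beta) / (n_k + model.n_terms * hp.beta)


def infer_theta(
    model: LdaModel,
    dtm: DocumentTermMatrix,
    n_iterations: int = 200,
    n_burnin: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Fold-in estimation of theta for unseen documents under fixed phi."""
    if dtm.n_terms != model.n_terms:
        raise ValueError("vocabulary size mismatch between model and matrix")
    hp = model.hyperparams
    phi = topic_word_distribution(model)
    doc_of, word_of = _expand_tokens(dtm)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, hp.K, size=doc_of.shape[0]).astype(np.int64)
    n_dk = np.zeros((dtm.n_docs, hp.K), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    cum = np.empty(hp.K, dtype=np.float64)
    acc = np.zeros_like(n_dk, dtype=np.float64)
    kept = 0
    for sweep in range(n_iterations):
        uniforms = rng.random(z.shape[0])
        foldin_sweep(doc_of, word_of, z, n_dk, phi, float(hp.alpha), uniforms, cum)
        if sweep >= n_burnin:
            acc += n_dk
            kept += 1
    acc /= max(kept, 1)
    lengths = acc.sum(axis=1, keepdims=True)
    theta = (acc + hp.alpha) / (lengths + hp.K * hp.alpha)
    theta[lengths.ravel() == 0] = 1.0 / hp.K
    return theta


def perplexity(
    model: LdaModel,
    dtm: DocumentTermMatrix,
    theta: np.ndarray | None = None,
) -> float:
    """exp(- sum_d sum_tokens log sum_k theta_dk phi_kw / total tokens).

    When ``theta`` is omitted the model's own document mixtures are used,
    which requires ``dtm`` to be the training matrix (same documents in the
    same order); held-out evaluation passes a folded-in theta.
    """
    if dtm.n_terms != model.n_terms:
        raise ValueError("vocabulary size mismatch between model and matrix")
    if theta is None:
        if dtm.n_docs != model.n_docs:
            raise ValueError(
                "document count mismatch: pass theta (e.g. from infer_theta) "
                "to evaluate a matrix other than the training one"
            )
        theta = doc_topic_distribution(model)
    phi = topic_word_distribution(model)
    coo = dtm.counts.tocoo()
    token_prob = np.einsum("ij,ij->i", theta[coo.row], phi[:, coo.col].T)
    n_tokens = int(coo.data.sum())
    if n_tokens == 0:
        raise ValueError("cannot compute perplexity of an empty matrix")
    log_lik = float(np.dot(coo.data, np.log(token_prob)))
    return float(np.exp(-log_lik / n_tokens))


def select_topic_count(
    dtm: DocumentTermMatrix,
    K_grid: list[int],
    holdout_fraction: float = 0.2,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-K held-out perplexity and topic redundancy, as a report.

    Redundancy is the mean pairwise cosine similarity between phi rows
    (lower means less redundant; 0 by convention for K=1).  No K is chosen
    automatically: the report supports a human judgement that also weighs
    topic legibility.
    """
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    base = dict(hyperparams or {})
    rng = np.random.default_rng(seed)
    n = dtm.n_docs
    n_hold = max(1, int(round(holdout_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    hold_idx = np.sort(perm[:n_hold])
    train_idx = np.sort(perm[n_hold:])
    train = DocumentTermMatrix(
        doc_ids=[dtm.doc_ids[i] for i in train_idx],
        counts=dtm.counts[train_idx],
        vocabulary=dtm.vocabulary,
    )
    held = DocumentTermMatrix(
        doc_ids=[dtm.doc_ids[i] for i in hold_idx],
        counts=dtm.counts[hold_idx],
        vocabulary=dtm.vocabulary,
    ) if n_hold else None
    rows = []
    for K in sorted(K_grid):
        if K > train.n_tokens:
            warnings.warn(f"K={K} exceeds training token count; skipped")
            continue
        hp = LdaHyperparams(K=K, seed=int(rng.integers(2**31 - 1)), **base)
        model = fit_lda(train, hp)
        phi = topic_word_distribution(model)
        if K == 1:
            redundancy = 0.0
        else:
            norms = phi / np.linalg.norm(phi, axis=1, keepdims=True)
            sims = norms @ norms.T
            redundancy = float((sims.sum() - K) / (K * (K - 1)))
        row = {
            "K": K,
            "train_perplexity": perplexity(model, train),
            "redundancy": redundancy,
        }
        if held is not None:
            theta_h = infer_theta(model, held, seed=int(rng.integers(2**31 - 1)))
            row["heldout_perplexity"] = perplexity(model, held, theta=theta_h)
        rows.append(row)
    return pd.DataFrame(rows)


def top_terms(model: LdaModel, topic: int, n: int = 10) -> list[str]:
    """The n highest-phi terms of one topic, ties broken lexicographically."""
    phi_k = topic_word_distribution(model)[topic]
    terms = model.vocabulary.terms
    order = sorted(range(len(terms)), key=lambda j: (-phi_k[j], terms[j]))
    return [terms[j] for j in order[:n]]


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal one-to-one topic matching by total-variation distance.

    Returns ``(matching, mean_tv)`` where ``matching[k_est] = k_true`` is
    the assignment minimizing the summed TV distance (Hungarian
    algorithm), and ``mean_tv`` the mean distance over matched pairs.
    """
    phi_est = np.asarray(phi_est, dtype=float)
    phi_true = np.asarray(phi_true, dtype=float)
    if phi_est.shape != phi_true.shape:
        raise ValueError(f"shape mismatch: {phi_est.shape} vs {phi_true.shape}")
    tv = 0.5 * np.abs(phi_est[:, None, :] - phi_true[None, :, :]).sum(axis=2)
    row, col = linear_sum_assignment(tv)
    matching = np.empty(phi_est.shape[0], dtype=np.int64)
    matching[row] = col
    return matching, float(tv[row, col].mean())
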