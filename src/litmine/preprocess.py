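"""Abstract text -> sparse document-term matrix.

Tokenization is deliberately simple and fully deterministic: case-fold,
split on non-alphanumeric characters, drop short tokens and stop-words.
Vocabulary construction applies the usual topic-model hygiene (document
frequency thresholds) and indexes surviving terms lexicographically so
that a given corpus always yields the same matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus_io import Corpus
from .stopwords import ENGLISH_STOPWORDS

__all__ = [
    "tokenize",
    "Vocabulary",
    "DocumentTermMatrix",
    "build_vocabulary",
    "vectorize",
    "record_tokens",
]

_SPLIT_RE = re.compile(r"[^0-9a-z]+")


def tokenize(
    text: str,
    min_length: int = 2,
    stopwords: frozenset[str] = ENGLISH_STOPWORDS,
    stem: bool = False,
) -> list[str]:
    """Case-fold, split on non-alphanumerics, drop short and stop tokens.

    ``stem`` applies a crude suffix stripper (plural ``s``); it is off by
    default because unstemmmed tokens are easier to audit in topic-term
    lists.
    """
    tokens = [t for t in _SPLIT_RE.split(text.casefold()) if t]
    tokens = [t for t in tokens if len(t) >= min_length and t not in stopwords]
    if stem:
        tokens = [t[:-1] if len(t) > 3 and t.endswith("s") and not t.endswith("ss") else t
                  for t in tokens]
    return tokens


def record_tokens(record, include_title: bool = False, **kwargs) -> list[str]:
    """Tokens of one record's abstract (optionally prefixed by its title)."""
    text = record.abstract
    if include_title:
        text = record.title + " " + text
    return tokenize(text, **kwargs)


@dataclass
class Vocabulary:
    """Bijective term -> contiguous index map with document frequencies."""

    terms: list[str]
    doc_freq: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("Vocabulary terms are not unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def write_tsv(self, stream: IO[str]) -> None:
        for term in self.terms:
            stream.write(f"{term}\t{self.doc_freq.get(term, 0)}\n")

    @classmethod
    def read_tsv(cls, stream: IO[str]) -> "Vocabulary":
        terms, df = [], {}
        for line in stream:
            if not line.strip():
                continue
            term, count = line.rstrip("\n").split("\t")
            terms.append(term)
            df[term] = int(count)
        return cls(terms=terms, doc_freq=df)


@dataclass
class DocumentTermMatrix:
    """Sparse doc x term counts with row order matching the corpus order.

    Documents whose tokens all fell outside the vocabulary are retained as
    empty rows and flagged in ``empty_docs``.
    """

    doc_ids: list[str]
    counts: sp.csr_matrix
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.doc_ids)} docs x {len(self.vocabulary)} terms"
            )

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())

    @property
    def doc_lengths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    @property
    def empty_docs(self) -> list[str]:
        lengths = self.doc_lengths
        return [d for d, n in zip(self.doc_ids, lengths) if n == 0]


def build_vocabulary(
    corpus: Corpus,
    min_df: int = 5,
    max_df_fraction: float = 0.5,
    stopwords: frozenset[str] = ENGLISH_STOPWORDS,
    min_length: int = 2,
    include_title: bool = False,
) -> Vocabulary:
    """Build a lexicographically indexed vocabulary with df pruning.

    Terms appearing in fewer than ``min_df`` documents or in more than
    ``max_df_fraction`` of all documents are excluded.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not (0 < max_df_fraction <= 1):
        raise ValueError("max_df_fraction must be in (0, 1]")
    df: dict[str, int] = {}
    for rec in corpus:
        for term in set(record_tokens(rec, include_title=include_title,
                                      min_length=min_length, stopwords=stopwords)):
            df[term] = df.get(term, 0) + 1
    max_df = max_df_fraction * len(corpus)
    kept = sorted(t for t, n in df.items() if n >= min_df and n <= max_df)
    if not kept:
        raise ValueError(
            "no terms survive the document-frequency thresholds; "
            "lower min_df or raise max_df_fraction"
        )
    return Vocabulary(terms=kept, doc_freq={t: df[t] for t in kept})


def vectorize(
    corpus: Corpus,
    vocabulary: Vocabulary,
    stopwords: frozenset[str] = ENGLISH_STOPWORDS,
    min_length: int = 2,
    include_title: bool = False,
) -> DocumentTermMatrix:
    """Count in-vocabulary token multiplicities per document."""
    rows, cols, vals = [], [], []
    for d, rec in enumerate(corpus):
        counts: dict[int, int] = {}
        for term in record_tokens(rec, include_title=include_title,
                                  min_length=min_length, stopwords=stopwords):
            j = vocabulary.index.get(term)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            rows.append(d)
            cols.append(j)
            vals.append(counts[j])
    mat = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(corpus), len(vocabulary)),
        dtype=np.int64,
    )
    return DocumentTermMatrix(doc_ids=corpus.pmids, counts=mat, vocabulary=vocabulary)
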