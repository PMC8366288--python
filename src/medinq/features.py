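"""Sentence featurization: n-gram TF-IDF and pluggable sentence embeddings.

TF-IDF follows the common smooth-idf convention: word n-grams (default
n = 1..5) after stop-word removal, vocabulary capped to the top
``max_features`` n-grams by document frequency (ties broken
lexicographically), ``idf(t) = ln((1 + D) / (1 + df(t))) + 1``, raw term
counts, and L2-normalized rows. Features are computed at the sentence
level.

Embeddings are behind a provider contract so an external sentence encoder
(for example a 512-dimensional universal sentence encoder) can be plugged
in; the built-in :class:`HashedEmbedding` is a deterministic hashed
bag-of-words projection that needs no model download. Stop words are *not*
removed for embeddings.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Vocabulary",
    "fit_tfidf",
    "transform_tfidf",
    "TfidfFeaturizer",
    "EmbeddingProvider",
    "HashedEmbedding",
    "embed",
    "feature_tokens",
]

_WORD = re.compile(r"[A-Za-z][A-Za-z'-]*")


def feature_tokens(text: str, stop_words: frozenset[str] = frozenset()) -> list[str]:
    """Lower-cased word tokens with stop words removed."""
    return [w for w in (m.group(0).lower() for m in _WORD.finditer(text))
            if w not in stop_words]


def _ngrams(tokens: list[str], ngram_range: tuple[int, int]) -> list[str]:
    lo, hi = ngram_range
    out: list[str] = []
    for n in range(lo, hi + 1):
        out.extend(" ".join(tokens[i:i + n])
                   for i in range(len(tokens) - n + 1))
    return out


@dataclass
class Vocabulary:
    """Fitted n-gram vocabulary with idf weights."""

    index: dict[str, int]
    idf: np.ndarray
    ngram_range: tuple[int, int]
    max_features: int
    stop_words: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.index)


def fit_tfidf(
    sentences: list[str],
    ngram_range: tuple[int, int] = (1, 5),
    max_features: int = 20000,
    stop_words: frozenset[str] = frozenset(),
) -> Vocabulary:
    """Fit the n-gram vocabulary and idf weights on a corpus.

    The vocabulary keeps the ``max_features`` n-grams with the highest
    document frequency, breaking ties lexicographically (ascending), so
    refits on the same corpus are bit-identical.
    """
    df: dict[str, int] = {}
    n_docs = 0
    for text in sentences:
        toks = feature_tokens(text, stop_words)
        n_docs += 1
        for g in set(_ngrams(toks, ngram_range)):
            df[g] = df.get(g, 0) + 1
    if not df:
        raise ValueError("no features: corpus is empty after stop-word removal")
    kept = sorted(df, key=lambda g: (-df[g], g))[:max_features]
    kept.sort()
    index = {g: i for i, g in enumerate(kept)}
    idf = np.array(
        [np.log((1.0 + n_docs) / (1.0 + df[g])) + 1.0 for g in kept]
    )
    return Vocabulary(index, idf, ngram_range, max_features, stop_words)


def transform_tfidf(sentences: list[str], vocabulary: Vocabulary) -> sp.csr_matrix:
    """Sparse TF-IDF matrix: raw counts x idf, rows L2-normalized.

    Out-of-vocabulary n-grams are ignored; a sentence with no in-vocabulary
    n-gram yields an all-zero row.
    """
    rows, cols, vals = [], [], []
    for i, text in enumerate(sentences):
        toks = feature_tokens(text, vocabulary.stop_words)
        counts: dict[int, int] = {}
        for g in _ngrams(toks, vocabulary.ngram_range):
            j = vocabulary.index.get(g)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            continue
        idx = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        tf = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
        w = tf * vocabulary.idf[idx]
        norm = np.sqrt((w * w).sum())
        if norm > 0:
            w = w / norm
        rows.extend([i] * len(idx))
        cols.extend(idx.tolist())
        vals.extend(w.tolist())
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(sentences), len(vocabulary))
    )


@dataclass
class TfidfFeaturizer:
    """Convenience fit/transform wrapper around the two functions above."""

    ngram_range: tuple[int, int] = (1, 5)
    max_features: int = 20000
    stop_words: frozenset[str] = frozenset()
    vocabulary: Vocabulary | None = field(default=None, repr=False)

    def fit(self, sentences: list[str]) -> "TfidfFeaturizer":
        self.vocabulary = fit_tfidf(
            sentences, self.ngram_range, self.max_features, self.stop_words
        )
        return self

    def transform(self, sentences: list[str]) -> sp.csr_matrix:
        if self.vocabulary is None:
            raise RuntimeError("featurizer is not fitted")
        return transform_tfidf(sentences, self.vocabulary)

    def fit_transform(self, sentences: list[str]) -> sp.csr_matrix:
        return self.fit(sentences).transform(sentences)


class EmbeddingProvider:
    """Contract for sentence encoders: ``embed(texts) -> (n, dim) array``."""

    name: str = "abstract"
    dimension: int = 0
    deterministic: bool = True

    def embed(self, sentences: list[str]) -> np.ndarray:
        raise NotImplementedError


class HashedEmbedding(EmbeddingProvider):
    """Deterministic hashed bag-of-words projection.

    Each token hashes (salted blake2b) to a coordinate and a sign; a
    sentence is the L2-normalized signed count vector. Identical inputs
    produce bit-identical vectors on every platform, which makes this the
    default test-time encoder.
    """

    def __init__(self, dimension: int = 64, seed: int = 0):
        self.name = f"hashed-bow-{dimension}"
        self.dimension = int(dimension)
        self.seed = int(seed)
        self.deterministic = True

    def _coord(self, token: str) -> tuple[int, float]:
        h = hashlib.blake2b(
            f"{self.seed}:{token}".encode(), digest_size=8
        ).digest()
        v = int.from_bytes(h, "big")
        return v % self.dimension, 1.0 if (v >> 63) & 1 else -1.0

    def embed(self, sentences: list[str]) -> np.ndarray:
        out = np.zeros((len(sentences), self.dimension))
        for i, text in enumerate(sentences):
            for tok in feature_tokens(text):  # no stop-word removal
                j, sign = self._coord(tok)
                out[i, j] += sign
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out


def embed(sentences: list[str], provider: EmbeddingProvider) -> np.ndarray:
    """Dense embedding matrix, one row per sentence."""
    if provider is None:
        raise ValueError(
            "no embedding provider available; use the built-in "
            "HashedEmbedding for a deterministic, download-free encoder"
        )
    mat = provider.embed(sentences)
    if mat.shape != (len(sentences), provider.dimension):
        raise ValueError("provider returned a matrix of the wrong shape")
    return mat
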