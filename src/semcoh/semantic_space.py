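"""Latent semantic analysis: build a word-vector space from a corpus.

The space is the engine for all passage semantics downstream: a weighted
term-document matrix is decomposed by truncated SVD, and each word is
represented by its row of the left singular vectors (by default scaled by
the singular values).  Passages are represented by summing word vectors;
similarity between passages is the cosine of their vectors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = [
    "SemanticSpace",
    "PassageVector",
    "DimensionError",
    "UndefinedSimilarityError",
    "tokenize",
    "build_space",
    "term_document_matrix",
    "log_entropy_weight",
    "passage_vector",
    "cosine",
]


class DimensionError(ValueError):
    """Requested latent dimension exceeds what the corpus can support."""


class UndefinedSimilarityError(ValueError):
    """Cosine requested for an empty-flagged or zero-norm vector."""


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Clitics split off as separate tokens ("don't" -> "do", "n't").
_CONTRACTION_SUFFIXES = ("n't", "'ll", "'re", "'ve", "'m", "'s", "'d")
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase a text and split it into word tokens.

    Punctuation is stripped, numerals are kept as tokens, and contraction
    clitics are split on the apostrophe according to a fixed suffix table.
    """
    tokens: list[str] = []
    for match in _TOKEN_RE.finditer(text.lower()):
        word = match.group().strip("'")
        if not word:
            continue
        for suffix in _CONTRACTION_SUFFIXES:
            if word.endswith(suffix) and len(word) > len(suffix):
                tokens.append(word[: -len(suffix)])
                tokens.append(suffix)
                break
        else:
            tokens.append(word)
    return tokens


# ---------------------------------------------------------------------------
# Space construction
# ---------------------------------------------------------------------------


@dataclass
class SemanticSpace:
    """Vocabulary plus a |V| x d word-vector matrix.

    ``vectors[i]`` is the latent representation of ``vocabulary[i]``.
    ``singular_values`` and ``doc_loadings`` (right singular vectors,
    d x n_docs) are retained for diagnostics and reconstruction checks.
    """

    vocabulary: list[str]
    vectors: np.ndarray
    weighting: str
    d: int
    singular_values: np.ndarray | None = None
    doc_loadings: np.ndarray | None = None
    scaled_by_singular_values: bool = True
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocabulary)}
        if len(self._index) != len(self.vocabulary):
            raise ValueError("vocabulary entries must be unique")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("word vectors must be finite")

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the space as plain text (vocab list + dense matrix)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "vocabulary.txt").write_text(
            "\n".join(self.vocabulary) + "\n", encoding="utf-8"
        )
        np.savetxt(directory / "vectors.txt", self.vectors, fmt="%.17e")
        meta = {
            "d": self.d,
            "weighting": self.weighting,
            "scaled_by_singular_values": self.scaled_by_singular_values,
        }
        if self.singular_values is not None:
            meta["singular_values"] = [float(s) for s in self.singular_values]
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SemanticSpace":
        directory = Path(directory)
        vocab = (directory / "vocabulary.txt").read_text(encoding="utf-8").split()
        vectors = np.loadtxt(directory / "vectors.txt", ndmin=2)
        meta = json.loads((directory / "meta.json").read_text())
        sv = meta.get("singular_values")
        return cls(
            vocabulary=vocab,
            vectors=vectors,
            weighting=meta["weighting"],
            d=meta["d"],
            singular_values=None if sv is None else np.asarray(sv, dtype=float),
            scaled_by_singular_values=meta["scaled_by_singular_values"],
        )


def term_document_matrix(
    corpus: Sequence[Sequence[str]], vocabulary: Sequence[str]
) -> sp.csr_matrix:
    """Raw count matrix, terms in rows, documents in columns."""
    index = {w: i for i, w in enumerate(vocabulary)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, doc in enumerate(corpus):
        counts: dict[int, int] = {}
        for tok in doc:
            i = index.get(tok)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        rows.extend(counts.keys())
        cols.extend([j] * len(counts))
        vals.extend(counts.values())
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocabulary), len(corpus)), dtype=float
    )


def log_entropy_weight(counts: sp.csr_matrix) -> sp.csr_matrix:
    """Classic LSA log-entropy weighting.

    Local weight log(1 + tf); global weight 1 - H_t / log(n_docs), where H_t
    is the entropy of the term's distribution over documents.  Terms that
    occur uniformly carry weight ~0, terms concentrated in few documents
    carry weight ~1.
    """
    n_docs = counts.shape[1]
    gf = np.asarray(counts.sum(axis=1)).ravel()  # global term frequency
    gf[gf == 0] = 1.0
    entropy = np.zeros(counts.shape[0])
    coo = counts.tocoo()
    p = coo.data / gf[coo.row]
    contrib = -p * np.log(p)
    np.add.at(entropy, coo.row, contrib)
    if n_docs > 1:
        global_w = 1.0 - entropy / np.log(n_docs)
    else:
        global_w = np.ones_like(entropy)
    global_w = np.clip(global_w, 0.0, 1.0)
    out = coo.copy()
    out.data = np.log1p(coo.data) * global_w[coo.row]
    return out.tocsr()


def build_space(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    weighting: str = "log-entropy",
    scale_by_singular_values: bool = True,
) -> SemanticSpace:
    """Build a latent semantic space from a tokenized corpus.

    Parameters
    ----------
    corpus : sequence of token lists, one per document (lowercase tokens).
    d : latent dimension; must not exceed the number of documents or the
        vocabulary size.
    weighting : "log-entropy" (default) or "raw".
    scale_by_singular_values : if True word vectors are rows of U @ diag(s)
        (the convention used throughout this package); if False, rows of U.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    vocabulary = sorted({tok for doc in corpus for tok in doc})
    if not vocabulary:
        raise ValueError("corpus contains no tokens")
    if d < 1:
        raise DimensionError("d must be a positive integer")
    if d > len(corpus):
        raise DimensionError(
            f"d={d} exceeds the number of documents ({len(corpus)})"
        )
    if d > len(vocabulary):
        raise DimensionError(
            f"d={d} exceeds the vocabulary size ({len(vocabulary)})"
        )

    counts = term_document_matrix(corpus, vocabulary)
    if weighting == "log-entropy":
        weighted = log_entropy_weight(counts)
    elif weighting == "raw":
        weighted = counts
    else:
        raise ValueError(f"unknown weighting scheme: {weighting!r}")

    min_dim = min(weighted.shape)
    if d < min_dim:
        # deterministic start vector -> reproducible SVD up to sign
        v0 = np.ones(min_dim) / np.sqrt(min_dim)
        u, s, vt = svds(weighted, k=d, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u, s, vt = np.linalg.svd(weighted.toarray(), full_matrices=False)
        u, s, vt = u[:, :d], s[:d], vt[:d]

    # resolve the per-dimension sign indeterminacy deterministically
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]

    vectors = u * s if scale_by_singular_values else u
    return SemanticSpace(
        vocabulary=vocabulary,
        vectors=vectors,
        weighting=weighting,
        d=d,
        singular_values=s,
        doc_loadings=vt,
        scaled_by_singular_values=scale_by_singular_values,
    )


# ---------------------------------------------------------------------------
# Passage vectors and similarity
# ---------------------------------------------------------------------------


@dataclass
class PassageVector:
    """Sum of word vectors over a token sequence.

    ``n_contributing_tokens`` counts tokens that had a vocabulary entry;
    out-of-vocabulary tokens contribute nothing but are not an error.  A
    passage with no in-vocabulary tokens is flagged empty and must be
    excluded from cosine comparisons.
    """

    values: np.ndarray
    n_contributing_tokens: int

    @property
    def is_empty(self) -> bool:
        return self.n_contributing_tokens == 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("passage vector entries must be finite")
        if self.n_contributing_tokens < 0:
            raise ValueError("n_contributing_tokens must be >= 0")


def passage_vector(space: SemanticSpace, tokens: Iterable[str]) -> PassageVector:
    """Linear combination (unweighted sum) of word vectors for a passage."""
    total = np.zeros(space.vectors.shape[1])
    n = 0
    for tok in tokens:
        i = space._index.get(tok)
        if i is not None:
            total += space.vectors[i]
            n += 1
    return PassageVector(values=total, n_contributing_tokens=n)


def _as_array(v: PassageVector | np.ndarray) -> np.ndarray:
    if isinstance(v, PassageVector):
        if v.is_empty:
            raise UndefinedSimilarityError(
                "cosine undefined for an empty passage vector"
            )
        return v.values
    return np.asarray(v, dtype=float)


def cosine(a: PassageVector | np.ndarray, b: PassageVector | np.ndarray) -> float:
    """Cosine similarity between two passage vectors, in [-1, 1]."""
    va, vb = _as_array(a), _as_array(b)
    if va.shape != vb.shape:
        raise ValueError("vectors have mismatched dimensions")
    na = float(np.linalg.norm(va))
    nb = float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine undefined for a zero-norm vector")
    value = float(np.dot(va, vb) / (na * nb))
    # guard against floating-point excursions outside [-1, 1]
    return max(-1.0, min(1.0, value))
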