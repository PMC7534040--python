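"""Lexical-semantic speech markers and PCA factor reduction.

Seven markers are computed per response: mean frequency, semantic
diversity, concreteness, age of acquisition and phonemic length of the
nouns produced (looked up in a psycholinguistic norms table), the
type:token ratio, and the percentage of closed-class (function) words.
Together with global and local coherence these nine measures are reduced
to four latent factors by principal components analysis with varimax
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerProfile",
    "FactorModel",
    "DegenerateInputError",
    "load_norms",
    "load_function_words",
    "compute_markers",
    "varimax",
    "fit_pca",
]

NORMS_COLUMNS = [
    "word",
    "pos",
    "frequency",
    "concreteness",
    "aoa",
    "semantic_diversity",
    "phonemic_length",
]

MARKER_NAMES = [
    "noun_frequency",
    "noun_semantic_diversity",
    "noun_concreteness",
    "type_token_ratio",
    "noun_aoa",
    "noun_phonemic_length",
    "pct_closed_class",
]


class DegenerateInputError(ValueError):
    """PCA input contains a constant (zero-variance) column."""


def load_norms(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a norms table (word, pos, frequency, concreteness, aoa,
    semantic_diversity, phonemic_length); frequency is on a log scale."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in NORMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"norms table missing columns: {missing}")
    df = df.copy()
    df["word"] = df["word"].str.lower()
    df["pos"] = df["pos"].str.lower()
    return df


def load_function_words(path: str | Path | None = None) -> frozenset[str]:
    """Closed-class word lexicon; defaults to the packaged English list."""
    if path is None:
        text = (
            resources.files("semcoh.data")
            .joinpath("function_words_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.split() if w.strip())


@dataclass
class MarkerProfile:
    """The seven lexical-semantic markers for one response (or pool).

    Noun markers are means over noun tokens found in the norms table
    (token-weighted: repeated nouns count each time); they are None when no
    noun matched.  ``n_nouns_matched`` / ``n_nouns_unmatched`` record lookup
    coverage.
    """

    noun_frequency: float | None
    noun_semantic_diversity: float | None
    noun_concreteness: float | None
    type_token_ratio: float
    noun_aoa: float | None
    noun_phonemic_length: float | None
    pct_closed_class: float
    n_tokens: int
    n_nouns_matched: int
    n_nouns_unmatched: int

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in MARKER_NAMES}


def compute_markers(
    tagged_tokens: Sequence[tuple[str, str]],
    norms: pd.DataFrame,
    function_words: Iterable[str],
) -> MarkerProfile:
    """Compute the seven markers from POS-tagged clean tokens.

    ``tagged_tokens`` are (word, pos) pairs; any POS label starting with
    "n" is treated as a noun.  Norm lookup is case-insensitive on the exact
    surface form (no lemmatization).  Type:token ratio and % closed class
    are computed over all clean tokens.
    """
    if len(tagged_tokens) == 0:
        raise ValueError("cannot compute markers for an empty token list")
    fw = {w.lower() for w in function_words}
    words = [w.lower() for w, _ in tagged_tokens]

    ttr = len(set(words)) / len(words)
    pct_closed = 100.0 * sum(w in fw for w in words) / len(words)

    noun_norms = norms[norms["pos"].str.startswith("n")]
    lookup = {
        w: row
        for w, row in zip(noun_norms["word"], noun_norms.itertuples(index=False))
    }
    matched_rows = []
    n_unmatched = 0
    for word, pos in tagged_tokens:
        if not pos.lower().startswith("n"):
            continue
        row = lookup.get(word.lower())
        if row is None:
            n_unmatched += 1
        else:
            matched_rows.append(row)

    def _mean(attr: str) -> float | None:
        if not matched_rows:
            return None
        return float(np.mean([getattr(r, attr) for r in matched_rows]))

    return MarkerProfile(
        noun_frequency=_mean("frequency"),
        noun_semantic_diversity=_mean("semantic_diversity"),
        noun_concreteness=_mean("concreteness"),
        type_token_ratio=ttr,
        noun_aoa=_mean("aoa"),
        noun_phonemic_length=_mean("phonemic_length"),
        pct_closed_class=pct_closed,
        n_tokens=len(tagged_tokens),
        n_nouns_matched=len(matched_rows),
        n_nouns_unmatched=n_unmatched,
    )


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------


@dataclass
class FactorModel:
    """Varimax-rotated principal components of standardized measures."""

    loadings: pd.DataFrame            # measures x factors
    explained_variance: np.ndarray    # % of total variance per factor
    scores: pd.DataFrame              # observations x factors
    column_means: np.ndarray
    column_sds: np.ndarray


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation (maximizes the variance of squared
    loadings within factors).  Returns the rotation matrix R such that the
    rotated loadings are ``loadings @ R``."""
    p, k = loadings.shape
    rotation = np.eye(k)
    if k < 2:
        return rotation
    var = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T
            @ (rotated**3 - rotated @ np.diag(np.sum(rotated**2, axis=0)) / p)
        )
        rotation = u @ vt
        new_var = float(np.sum(s))
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return rotation


def fit_pca(
    measures: pd.DataFrame | np.ndarray,
    k: int = 4,
    rotate: bool = True,
) -> FactorModel:
    """Extract k rotated components from a complete measures matrix.

    Columns are z-scored over the estimation sample, components come from
    the eigendecomposition of the correlation matrix (loadings are
    eigenvectors scaled by the square roots of eigenvalues), varimax
    rotation is applied, each factor's sign is fixed so its largest-|loading|
    measure loads positively, and factors are ordered by explained variance.
    Factor scores are least-squares regression estimates on the standardized
    measures, so they have mean zero over the estimation sample.
    """
    if isinstance(measures, pd.DataFrame):
        columns = list(measures.columns)
        index = measures.index
        X = measures.to_numpy(dtype=float)
    else:
        X = np.asarray(measures, dtype=float)
        columns = [f"m{i+1}" for i in range(X.shape[1])]
        index = pd.RangeIndex(X.shape[0])
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("measures matrix contains missing values")
    if n < k:
        raise ValueError(f"need at least k={k} complete rows, got {n}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise DegenerateInputError(
                f"column {columns[j]!r} is constant; PCA input is degenerate"
            )
    Z = (X - means) / sds

    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order] * np.sqrt(eigvals)

    if rotate:
        loadings = loadings @ varimax(loadings)

    # deterministic sign: the measure with the largest |loading| on each
    # factor loads positively
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]

    ssq = np.sum(loadings**2, axis=0)
    order = np.argsort(ssq)[::-1]
    loadings = loadings[:, order]
    explained = 100.0 * ssq[order] / p

    factor_names = [f"factor{i+1}" for i in range(loadings.shape[1])]
    # regression scores: Z ~ scores @ loadings.T  =>  S = Z L (L'L)^-1
    scores = Z @ loadings @ np.linalg.inv(loadings.T @ loadings)

    return FactorModel(
        loadings=pd.DataFrame(loadings, index=columns, columns=factor_names),
        explained_variance=explained,
        scores=pd.DataFrame(scores, index=index, columns=factor_names),
        column_means=means,
        column_sds=sds,
    )
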