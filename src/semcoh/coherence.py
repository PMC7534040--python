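"""Global and local coherence of speech via a moving-window LSA method.

Each response is divided into overlapping windows of ``w`` tokens (default
20), stepping one token at a time.  Global coherence (GC) is the mean cosine
between each window's vector and a prompt-specific composite vector built
from healthy controls' responses — a measure of how closely the speaker
stays on the probed topic.  Local coherence (LC) is the mean cosine between
each window and the window covering the ``w`` tokens immediately preceding
it — a measure of topic continuity from moment to moment.

The "previous window" for LC is the *disjoint* predecessor, not the step-1
neighbour (which would share w-1 of w tokens and be trivially similar);
the overlapping reading is available behind ``lc_style="overlapping"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .semantic_space import (
    PassageVector,
    SemanticSpace,
    UndefinedSimilarityError,
    cosine,
    passage_vector,
)

__all__ = [
    "WindowSeries",
    "CompositeVector",
    "CoherenceResult",
    "make_windows",
    "build_composite",
    "global_coherence",
    "local_coherence",
    "score_response",
    "aggregate_participant",
]

DEFAULT_WINDOW = 20


@dataclass
class WindowSeries:
    """Passage vectors for every w-token window of a response, step 1."""

    window_size: int
    vectors: list[PassageVector]
    starts: list[int]

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class CompositeVector:
    """Mean of unit-normalized control-response vectors for one prompt."""

    prompt_id: str
    values: np.ndarray
    n_contributors: int


@dataclass
class CoherenceResult:
    """Per-response coherence summary (means over windows)."""

    participant_id: str
    prompt_id: str
    gc: float | None
    lc: float | None
    n_windows_gc: int
    n_comparisons_lc: int
    response_length: int


def make_windows(
    tokens: Sequence[str], space: SemanticSpace, w: int = DEFAULT_WINDOW
) -> WindowSeries:
    """Vectors for all contiguous w-token windows, advancing one token.

    Implemented with a cumulative sum over token vectors so the cost is
    linear in response length; windows with no in-vocabulary token are
    empty-flagged, not errors.
    """
    n = len(tokens)
    if n < w:
        raise ValueError(f"response has {n} tokens; needs at least w={w}")
    d = space.vectors.shape[1]
    token_vecs = np.zeros((n, d))
    in_vocab = np.zeros(n)
    for i, tok in enumerate(tokens):
        j = space._index.get(tok)
        if j is not None:
            token_vecs[i] = space.vectors[j]
            in_vocab[i] = 1.0
    csum = np.vstack([np.zeros(d), np.cumsum(token_vecs, axis=0)])
    ccount = np.concatenate([[0.0], np.cumsum(in_vocab)])
    vectors = []
    starts = list(range(n - w + 1))
    for p in starts:
        vals = csum[p + w] - csum[p]
        count = int(round(ccount[p + w] - ccount[p]))
        vectors.append(PassageVector(values=vals, n_contributing_tokens=count))
    return WindowSeries(window_size=w, vectors=vectors, starts=starts)


def build_composite(
    control_responses: Iterable[Sequence[str]],
    space: SemanticSpace,
    prompt_id: str = "",
) -> CompositeVector:
    """Average the unit-normalized vectors of control responses to a prompt.

    Normalizing before averaging keeps long responses from dominating the
    composite; the result represents the prototypical semantic content
    healthy speakers produce for the prompt.
    """
    unit_vectors = []
    for tokens in control_responses:
        pv = passage_vector(space, tokens)
        if pv.is_empty:
            continue
        norm = np.linalg.norm(pv.values)
        if norm == 0:
            continue
        unit_vectors.append(pv.values / norm)
    if not unit_vectors:
        raise ValueError(
            f"no usable control responses to build composite for prompt "
            f"{prompt_id!r}"
        )
    return CompositeVector(
        prompt_id=prompt_id,
        values=np.mean(unit_vectors, axis=0),
        n_contributors=len(unit_vectors),
    )


def global_coherence(
    ws: WindowSeries, comp: CompositeVector
) -> tuple[float | None, list[float | None]]:
    """Mean cosine between each window and the prompt composite.

    Windows with no vector content yield missing per-window values; if every
    window is empty the GC itself is undefined (None), never coerced to 0.
    """
    per_window: list[float | None] = []
    for pv in ws.vectors:
        try:
            per_window.append(cosine(pv, comp.values))
        except UndefinedSimilarityError:
            per_window.append(None)
    defined = [v for v in per_window if v is not None]
    gc = float(np.mean(defined)) if defined else None
    return gc, per_window


def local_coherence(
    ws: WindowSeries, style: str = "disjoint"
) -> tuple[float | None, list[float | None]]:
    """Mean cosine between each window and its preceding window.

    With ``style="disjoint"`` (default) the window starting at position p is
    compared with the window covering the w tokens immediately before p, so
    the two windows share no tokens.  ``style="overlapping"`` compares with
    the step-1 predecessor instead.
    """
    w = ws.window_size
    lag = w if style == "disjoint" else 1
    if style not in ("disjoint", "overlapping"):
        raise ValueError(f"unknown LC style: {style!r}")
    per_comparison: list[float | None] = []
    for idx in range(lag, len(ws.vectors)):
        try:
            per_comparison.append(cosine(ws.vectors[idx], ws.vectors[idx - lag]))
        except UndefinedSimilarityError:
            per_comparison.append(None)
    defined = [v for v in per_comparison if v is not None]
    lc = float(np.mean(defined)) if defined else None
    return lc, per_comparison


def score_response(
    tokens: Sequence[str],
    space: SemanticSpace,
    comp: CompositeVector,
    participant_id: str = "",
    prompt_id: str = "",
    w: int = DEFAULT_WINDOW,
    lc_style: str = "disjoint",
) -> CoherenceResult:
    """GC and LC for one response, honouring the length-eligibility rules."""
    n = len(tokens)
    if n < w:
        return CoherenceResult(
            participant_id, prompt_id, None, None, 0, 0, n
        )
    ws = make_windows(tokens, space, w)
    gc, gc_trace = global_coherence(ws, comp)
    n_gc = sum(v is not None for v in gc_trace)
    if n >= 2 * w or lc_style == "overlapping":
        lc, lc_trace = local_coherence(ws, style=lc_style)
        n_lc = sum(v is not None for v in lc_trace)
    else:
        lc, n_lc = None, 0
    return CoherenceResult(
        participant_id=participant_id,
        prompt_id=prompt_id,
        gc=gc,
        lc=lc,
        n_windows_gc=n_gc,
        n_comparisons_lc=n_lc,
        response_length=n,
    )


def aggregate_participant(results: Iterable[CoherenceResult]) -> pd.DataFrame:
    """Participant-level means over eligible responses.

    Each participant's GC (LC) is the unweighted mean of their defined
    response-level values; participants with no defined value for a measure
    get a missing entry.  Group summaries downstream take unweighted means
    over participants and sample (ddof=1) standard deviations.
    """
    rows = [
        {
            "participant_id": r.participant_id,
            "prompt_id": r.prompt_id,
            "gc": r.gc,
            "lc": r.lc,
            "response_length": r.response_length,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["participant_id", "gc", "lc", "n_responses", "mean_length"]
        ).set_index("participant_id")
    out = df.groupby("participant_id").agg(
        gc=("gc", "mean"),
        lc=("lc", "mean"),
        n_responses=("prompt_id", "size"),
        mean_length=("response_length", "mean"),
    )
    return out
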