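"""Semantic-primitive extraction: the SF-SAI score.

A *semantic primitive* is a high-salience word of a theme (field)
corpus: frequent in the field posts and semantically coherent with the
other candidate words.  Candidates are the field-corpus tokens that
survive a part-of-speech filter and a stop-word list and that exist in
the background embedding vocabulary.  Each candidate gets two scores:

* **SF (semantic frequency)** — its relative frequency among candidate
  tokens in the field corpus, ``count(w) / Σ count``.
* **SAI (semantic active index)** — its mean cosine similarity, in the
  background embedding space, to every other candidate; a coherence
  measure: words central to the theme's vocabulary score high.

Both scores are min–max normalized to ``[0, 1]`` over the candidate set
and combined multiplicatively; the top-``k`` tokens by combined score
(ties broken lexicographically) are the extracted primitives.  The two
scores, the normalization and the combiner are pluggable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import PostPool
from .embedding import EmbeddingModel


@dataclass(frozen=True)
class SemanticPrimitive:
    token: str
    sf: float  # raw relative frequency in the field corpus
    sai: float  # raw mean cosine similarity to co-candidates
    score: float  # combined normalized score in [0, 1]
    vector: np.ndarray

    def __repr__(self) -> str:  # vectors are noisy in reprs
        return (
            f"SemanticPrimitive({self.token!r}, sf={self.sf:.4f}, "
            f"sai={self.sai:.4f}, score={self.score:.4f})"
        )


@dataclass
class CandidateSet:
    tokens: list[str]  # sorted, unique
    source_theme: Optional[str] = None

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def build_candidates(
    field_pool: PostPool,
    model: EmbeddingModel,
    allowed_pos: Optional[set[str]] = None,
    stopwords: Iterable[str] = (),
    source_theme: Optional[str] = None,
) -> CandidateSet:
    """Field-corpus tokens passing POS, stop-word, and vocabulary filters.

    A token is kept when at least one of its occurrences carries an
    allowed POS tag (all tags allowed when ``allowed_pos`` is ``None``),
    it is not a stop word, and it is in the embedding vocabulary.
    """
    stop = set(stopwords)
    kept: set[str] = set()
    for p in field_pool:
        tags = p.pos_tags if p.pos_tags is not None else [None] * len(p.tokens)
        for tok, tag in zip(p.tokens, tags):
            if tok in stop or tok not in model:
                continue
            if allowed_pos is not None and tag not in allowed_pos:
                continue
            kept.add(tok)
    if not kept:
        raise ValueError(
            "empty candidate set: loosen the POS filter / stop-word list, or "
            "check that field-corpus tokens are in the embedding vocabulary"
        )
    return CandidateSet(sorted(kept), source_theme)


def _candidate_counts(field_pool: PostPool, candidates: CandidateSet) -> Counter:
    cand = set(candidates.tokens)
    counts: Counter = Counter()
    for p in field_pool:
        counts.update(t for t in p.tokens if t in cand)
    return counts


def semantic_frequency(
    token: str, field_pool: PostPool, candidates: CandidateSet
) -> float:
    """Relative frequency of ``token`` among candidate tokens; in (0, 1]."""
    counts = _candidate_counts(field_pool, candidates)
    if counts[token] == 0:
        raise ValueError(f"token {token!r} has zero count in the field corpus")
    return counts[token] / sum(counts.values())


def semantic_active_index(
    token: str, candidates: CandidateSet, model: EmbeddingModel
) -> float:
    """Mean cosine similarity between ``token`` and every other candidate."""
    if len(candidates) < 2:
        raise ValueError("semantic_active_index needs at least two candidates")
    others = [t for t in candidates if t != token]
    return float(np.mean([_cosine(model.vector(token), model.vector(t)) for t in others]))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def extract_primitives(
    field_pool: PostPool,
    model: EmbeddingModel,
    k: int = 30,
    combiner: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
    allowed_pos: Optional[set[str]] = None,
    stopwords: Iterable[str] = (),
    source_theme: Optional[str] = None,
) -> list[SemanticPrimitive]:
    """Top-``k`` semantic primitives of a field corpus.

    SF and SAI are each min–max normalized over the candidate set and
    combined (default: product).  Ranking is by combined score
    descending, ties broken lexicographically by token; ``k`` is capped
    at the candidate count.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    candidates = build_candidates(
        field_pool, model, allowed_pos=allowed_pos, stopwords=stopwords,
        source_theme=source_theme,
    )
    tokens = candidates.tokens
    counts = _candidate_counts(field_pool, candidates)
    total = sum(counts.values())
    sf_raw = np.array([counts[t] / total for t in tokens], dtype=np.float64)

    # SAI for all candidates at once: row-normalized cosine matrix
    M = np.stack([model.vector(t) for t in tokens]).astype(np.float64)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    U = M / norms
    S = U @ U.T
    n = len(tokens)
    if n < 2:
        sai_raw = np.zeros(n)
    else:
        sai_raw = (S.sum(axis=1) - np.diag(S)) / (n - 1)

    combine = combiner or (lambda a, b: a * b)
    score = np.asarray(combine(_minmax(sf_raw), _minmax(sai_raw)), dtype=np.float64)

    order = sorted(range(n), key=lambda i: (-score[i], tokens[i]))
    top = order[: min(k, n)]
    return [
        SemanticPrimitive(
            token=tokens[i],
            sf=float(sf_raw[i]),
            sai=float(sai_raw[i]),
            score=float(score[i]),
            vector=model.vector(tokens[i]).copy(),
        )
        for i in top
    ]


def primitives_to_frame(
    primitives: Sequence[SemanticPrimitive], theme: Optional[str] = None
) -> pd.DataFrame:
    """Primitive table: token, sf, sai, score, rank, theme."""
    return pd.DataFrame(
        {
            "token": [p.token for p in primitives],
            "sf": [p.sf for p in primitives],
            "sai": [p.sai for p in primitives],
            "score": [p.score for p in primitives],
            "rank": np.arange(1, len(primitives) + 1),
            "theme": theme,
        }
    )
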