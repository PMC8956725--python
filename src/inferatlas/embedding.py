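"""Skip-gram word embeddings for the background-knowledge corpus.

The semantic model is a skip-gram embedding with negative sampling
(SGNS): each vocabulary token gets one dense vector, trained so that
tokens appearing within a context window of each other score high under
a sigmoid dot product while randomly drawn noise tokens score low.
Defaults follow the pipeline's reference settings — context window 10,
vector dimension 400 — with the remaining optimizer knobs (negative
samples, learning rate, epochs) exposed as configuration.

Training is single-threaded and fully seeded, so a given corpus and seed
always yield bit-identical vectors.  The distance contract downstream
modules rely on is cosine distance, ``1 − cos(u, v)``, in ``[0, 2]``.

The trainer is written directly on NumPy: skip-gram pairs are collected
with per-center dynamic windows (a uniform draw in ``1..window``, the
standard word2vec trick that weights nearby contexts more), shuffled,
and consumed in mini-batches.  Within a batch, gradients for repeated
rows are accumulated before the update, which makes the math a
mini-batch variant of the classic per-pair SGD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import PostPool

__all__ = ["EmbeddingModel", "train_skipgram", "embedding_distance"]


@dataclass
class EmbeddingModel:
    """Vocabulary → fixed-dimension vectors with a cosine distance contract."""

    vocabulary: dict[str, int]  # token -> row index
    vectors: np.ndarray  # (V, dim) float32
    dim: int
    window: int
    min_count: int
    seed: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.dim):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"({len(self.vocabulary)}, {self.dim})"
            )

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def __len__(self) -> int:
        return len(self.vocabulary)

    @property
    def tokens(self) -> list[str]:
        inv = sorted(self.vocabulary.items(), key=lambda kv: kv[1])
        return [t for t, _ in inv]

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocabulary[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in embedding vocabulary") from None

    def similarity(self, w1: str, w2: str) -> float:
        """Cosine similarity between two vocabulary tokens."""
        u, v = self.vector(w1), self.vector(w2)
        nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(np.dot(u, v) / (nu * nv))

    def distance(self, w1: str, w2: str) -> float:
        """Cosine distance ``1 − cos``; 0 for identical tokens, at most 2."""
        if w1 == w2:
            self.vector(w1)  # still validate vocabulary membership
            return 0.0
        return 1.0 - self.similarity(w1, w2)

    # -- persistence (word2vec text format) --------------------------------

    def save_word2vec(self, path: str | Path) -> None:
        """Write the established word2vec text format: a ``V dim`` header,
        then one ``token v1 ... vdim`` line per vocabulary token."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for tok in self.tokens:
                vec = self.vectors[self.vocabulary[tok]]
                fh.write(tok + " " + " ".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def load_word2vec(
        cls, path: str | Path, window: int = 0, min_count: int = 0, seed: int = 0
    ) -> "EmbeddingModel":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab: dict[str, int] = {}
            vecs = np.empty((n, dim), dtype=np.float32)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vecs[i] = np.asarray(parts[1:], dtype=np.float32)
        if len(vocab) != n:
            raise ValueError(f"header promised {n} tokens, file had {len(vocab)}")
        return cls(vocab, vecs, dim, window, min_count, seed)


def embedding_distance(model: EmbeddingModel, w1: str, w2: str) -> float:
    """Cosine distance between two vocabulary tokens (errors on OOV)."""
    return model.distance(w1, w2)


# ---------------------------------------------------------------------------
# Training


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _collect_pairs(
    sentences: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for sent in sentences:
        n = len(sent)
        if n < 2:
            continue
        spans = rng.integers(1, window + 1, size=n)
        for i in range(n):
            b = int(spans[i])
            lo, hi = max(0, i - b), min(n, i + b + 1)
            ctx = np.concatenate([sent[lo:i], sent[i + 1 : hi]])
            centers.append(np.full(len(ctx), sent[i]))
            contexts.append(ctx)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return (
        np.concatenate(centers).astype(np.int64),
        np.concatenate(contexts).astype(np.int64),
    )


def train_skipgram(
    pool: PostPool | Iterable[Sequence[str]],
    dim: int = 400,
    window: int = 10,
    min_count: int = 5,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    batch_size: int = 2048,
    seed: int = 0,
) -> EmbeddingModel:
    """Train an SGNS embedding on the tokenized pool.

    The vocabulary keeps tokens with corpus frequency ``>= min_count``
    (an empty effective vocabulary is an error).  Noise tokens are drawn
    from the unigram distribution raised to the 3/4 power.  All
    randomness (init, dynamic windows, shuffles, negatives) flows from
    ``seed``.
    """
    if isinstance(pool, PostPool):
        token_lists: list[Sequence[str]] = [p.tokens for p in pool]
    else:
        token_lists = [list(t) for t in pool]

    counts = Counter(t for toks in token_lists for t in toks)
    # deterministic order: frequency-descending, then lexicographic
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ValueError(
            f"empty effective vocabulary: no token reaches min_count={min_count}"
        )
    vocab = {t: i for i, t in enumerate(kept)}
    V = len(vocab)

    sentences = [
        np.asarray([vocab[t] for t in toks if t in vocab], dtype=np.int64)
        for toks in token_lists
    ]
    sentences = [s for s in sentences if len(s) >= 2]
    if not sentences:
        raise ValueError("no post has two or more in-vocabulary tokens")

    rng = np.random.default_rng(seed)
    W = ((rng.random((V, dim), dtype=np.float64) - 0.5) / dim).astype(np.float32)
    C = np.zeros((V, dim), dtype=np.float32)

    freq = np.array([counts[t] for t in kept], dtype=np.float64)
    noise = freq**0.75
    noise /= noise.sum()

    centers0, contexts0 = _collect_pairs(sentences, window, rng)
    n_pairs = len(centers0)
    if n_pairs == 0:
        raise ValueError("corpus produced no skip-gram training pairs")
    total_batches = epochs * max(1, -(-n_pairs // batch_size))
    batch_no = 0

    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        centers, contexts = centers0[order], contexts0[order]
        for start in range(0, n_pairs, batch_size):
            lr = alpha + (min_alpha - alpha) * (batch_no / max(1, total_batches - 1))
            batch_no += 1
            c_idx = centers[start : start + batch_size]
            o_idx = contexts[start : start + batch_size]
            B = len(c_idx)
            neg_idx = rng.choice(V, size=(B, negative), p=noise)

            Wc = W[c_idx]  # (B, d)
            Co = C[o_idx]  # (B, d)
            Cn = C[neg_idx]  # (B, k, d)

            # positive pairs: push sigmoid(w·c) toward 1
            g_pos = (1.0 - _sigmoid(np.einsum("bd,bd->b", Wc, Co))) * lr  # (B,)
            # negative pairs: push sigmoid(w·n) toward 0
            g_neg = -_sigmoid(np.einsum("bd,bkd->bk", Wc, Cn)) * lr  # (B, k)

            grad_W = g_pos[:, None] * Co + np.einsum("bk,bkd->bd", g_neg, Cn)
            grad_Co = g_pos[:, None] * Wc
            grad_Cn = g_neg[:, :, None] * Wc[:, None, :]

            np.add.at(W, c_idx, grad_W.astype(np.float32))
            np.add.at(C, o_idx, grad_Co.astype(np.float32))
            np.add.at(
                C, neg_idx.ravel(), grad_Cn.reshape(-1, dim).astype(np.float32)
            )

    return EmbeddingModel(
        vocabulary=vocab,
        vectors=W,
        dim=dim,
        window=window,
        min_count=min_count,
        seed=seed,
        counts={t: int(counts[t]) for t in kept},
    )
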