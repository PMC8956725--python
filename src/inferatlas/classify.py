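"""Binary target / off-target relevance classification.

Crawled keyword hits contain noise — advertisements, aphorisms, running
commentary — that mentions the search terms without expressing the
feeling under study.  A maximum-margin (SVM) classifier separates
*target* posts from *off-target* ones.  Posts are vectorized either as
the arithmetic mean of their in-vocabulary token embeddings (default;
the embedding is trained on the background corpus first) or as
bag-of-words counts over a fixed vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .corpus import PostPool
from .embedding import EmbeddingModel

LABELS = ("target", "off_target")


@dataclass
class FeatureMatrix:
    post_ids: list[str]
    vectors: np.ndarray  # (n_posts, dim)
    method: str  # "embedding_mean" | "bag_of_words"
    vocabulary: Optional[list[str]] = None  # bag_of_words column order
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.post_ids):
            raise ValueError("row count does not match post_ids")


@dataclass
class ClassifierReport:
    accuracy: float
    n_eval: int
    confusion: np.ndarray  # rows true, cols predicted, order LABELS
    labels: tuple[str, str] = LABELS

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "accuracy": self.accuracy,
                    "n_eval": self.n_eval,
                    "labels": list(self.labels),
                    "confusion": self.confusion.tolist(),
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def vectorize_posts(
    pool: PostPool,
    model: Optional[EmbeddingModel] = None,
    method: str = "embedding_mean",
    vocabulary: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Fixed-length vector per post.

    ``embedding_mean``: arithmetic mean of in-vocabulary token vectors
    (zero vector, plus a warning, when a post has none).
    ``bag_of_words``: token counts over a fixed vocabulary (derived from
    the pool when not given).
    """
    for p in pool:
        if not p.tokens:
            raise ValueError(f"post {p.id!r} is untokenized; vectorization needs tokens")
    ids = pool.ids
    warnings: list[str] = []
    if method == "embedding_mean":
        if model is None:
            raise ValueError("embedding_mean vectorization requires an EmbeddingModel")
        X = np.zeros((len(ids), model.dim), dtype=np.float64)
        for i, p in enumerate(pool):
            vecs = [model.vector(t) for t in p.tokens if t in model]
            if vecs:
                X[i] = np.mean(vecs, axis=0)
            else:
                warnings.append(f"post {p.id!r}: no in-vocabulary tokens, zero vector")
        return FeatureMatrix(ids, X, method, warnings=warnings)
    if method == "bag_of_words":
        if vocabulary is None:
            vocabulary = sorted({t for p in pool for t in p.tokens})
        vocab_idx = {t: i for i, t in enumerate(vocabulary)}
        X = np.zeros((len(ids), len(vocabulary)), dtype=np.float64)
        for i, p in enumerate(pool):
            hit = False
            for t in p.tokens:
                j = vocab_idx.get(t)
                if j is not None:
                    X[i, j] += 1.0
                    hit = True
            if not hit:
                warnings.append(f"post {p.id!r}: no in-vocabulary tokens, zero vector")
        return FeatureMatrix(ids, X, method, vocabulary=list(vocabulary), warnings=warnings)
    raise ValueError(f"unknown vectorization method {method!r}")


def train_classifier(
    features: FeatureMatrix,
    labels: Sequence[str],
    seed: int = 0,
    kernel: str = "linear",
    C: float = 1.0,
) -> SVC:
    """Train the binary maximum-margin classifier (deterministic per seed)."""
    y = np.asarray(labels)
    if len(y) != len(features.post_ids):
        raise ValueError("labels and features are not aligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need two classes to train, got only {list(classes)}")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    clf = SVC(kernel=kernel, C=C, random_state=seed)
    clf.fit(features.vectors, y)
    return clf


def evaluate(
    clf: SVC, features: FeatureMatrix, labels: Sequence[str]
) -> ClassifierReport:
    """Accuracy and 2×2 confusion table on an evaluation set."""
    y = np.asarray(labels)
    if len(y) != len(features.post_ids):
        raise ValueError("labels and features are not aligned")
    if features.vectors.shape[1] != clf.n_features_in_:
        raise ValueError(
            f"feature dimension {features.vectors.shape[1]} does not match the "
            f"classifier's {clf.n_features_in_}"
        )
    pred = clf.predict(features.vectors)
    conf = confusion_matrix(y, pred, labels=list(LABELS))
    acc = float(np.trace(conf) / len(y))
    return ClassifierReport(accuracy=acc, n_eval=len(y), confusion=conf)


def save_classifier(clf: SVC, path: str | Path, meta: Optional[dict] = None) -> None:
    """Persist the model (joblib binary) with a JSON sidecar of metadata."""
    path = Path(path)
    joblib.dump(clf, path)
    sidecar = {"dim": int(clf.n_features_in_), "kernel": clf.kernel, "C": clf.C}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )


def load_classifier(path: str | Path) -> SVC:
    return joblib.load(path)
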