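"""The 2D semantic atlas: t-SNE map, relative distances, and closeness.

The extracted primitives live in the high-dimensional embedding space;
for interpretation they are projected to 2D with t-SNE and the
projection is min–max normalized to the unit square.  Distances between
primitives on this map are *relative* distances: only their ordering and
their relation to the map-wide distance statistics are meaningful, not
their absolute scale.  Per map we report the minimum, lower quartile,
median, mean, and maximum of the ``n(n−1)/2`` pairwise distances
(quartiles by linear interpolation, the type-7 convention), plus a
kernel-density surface over the points.

Two primitives are *semantically close* when their relative distance is
strictly below **both** the mean and the lower quartile of all pairwise
distances on the same map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

from .primitives import SemanticPrimitive

__all__ = [
    "DistanceStats",
    "ClosenessVerdict",
    "SemanticMap",
    "reduce_2d",
    "relative_distances",
    "distance_stats",
    "is_close",
    "group_mean_distance",
    "build_map",
    "close_pairs",
    "render_atlas",
]


@dataclass(frozen=True)
class DistanceStats:
    """Summary of the strict upper triangle of a distance matrix."""

    minimum: float
    lower_quartile: float
    median: float
    mean: float
    maximum: float
    upper_quartile: float  # emitted for completeness; the closeness rule uses Q1

    def __post_init__(self) -> None:
        if not (
            self.minimum <= self.lower_quartile <= self.median <= self.maximum
            and self.minimum <= self.mean <= self.maximum
        ):
            raise ValueError(f"inconsistent distance statistics: {self}")


@dataclass(frozen=True)
class ClosenessVerdict:
    pair: tuple[str, str]
    distance: float
    close: bool


@dataclass
class SemanticMap:
    primitives: list[SemanticPrimitive]
    coords: np.ndarray  # (n, 2), unit square
    distances: np.ndarray  # (n, n) symmetric, zero diagonal
    stats: DistanceStats
    density: Optional[np.ndarray]  # (grid, grid) KDE surface, or None
    seed: int

    @property
    def tokens(self) -> list[str]:
        return [p.token for p in self.primitives]

    def distance_between(self, t1: str, t2: str) -> float:
        toks = self.tokens
        try:
            return float(self.distances[toks.index(t1), toks.index(t2)])
        except ValueError as exc:
            raise KeyError(f"token not on map: {exc}") from None


def _normalize_unit_square(raw: np.ndarray) -> np.ndarray:
    """Per-axis min–max normalization to [0, 1] (degenerate axis → 0.5)."""
    out = np.empty_like(raw, dtype=np.float64)
    for j in range(raw.shape[1]):
        lo, hi = raw[:, j].min(), raw[:, j].max()
        out[:, j] = 0.5 if hi - lo < 1e-12 else (raw[:, j] - lo) / (hi - lo)
    return out


def reduce_2d(
    vectors: np.ndarray | Sequence[SemanticPrimitive],
    perplexity: float = 5.0,
    seed: int = 42,
) -> np.ndarray:
    """t-SNE to 2D, then min–max normalized to the unit square.

    Deterministic per seed (PCA initialization, exact gradient).
    """
    if isinstance(vectors, (list, tuple)) and vectors and isinstance(
        vectors[0], SemanticPrimitive
    ):
        X = np.stack([p.vector for p in vectors])
    else:
        X = np.asarray(vectors, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for a 2D map, got {n}")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < point count ({n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact",
        learning_rate="auto",
    )
    return _normalize_unit_square(tsne.fit_transform(X))


def relative_distances(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between unit-square map points."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points for pairwise distances")
    return squareform(pdist(coords))


def distance_stats(matrix: np.ndarray) -> DistanceStats:
    """Statistics over the strict upper triangle of the distance matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for distance statistics")
    tri = matrix[np.triu_indices(n, k=1)]
    q1, med, q3 = np.percentile(tri, [25, 50, 75])  # linear interpolation (type 7)
    return DistanceStats(
        minimum=float(tri.min()),
        lower_quartile=float(q1),
        median=float(med),
        mean=float(tri.mean()),
        maximum=float(tri.max()),
        upper_quartile=float(q3),
    )


def is_close(
    distance: float,
    stats: DistanceStats,
    pair: tuple[str, str] = ("", ""),
) -> ClosenessVerdict:
    """Closeness rule: strictly below both the mean and the lower quartile."""
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    close = distance < stats.mean and distance < stats.lower_quartile
    return ClosenessVerdict(pair=pair, distance=float(distance), close=close)


def group_mean_distance(tokens: Sequence[str], smap: SemanticMap) -> float:
    """Mean pairwise relative distance within a token subset of the map."""
    if len(tokens) < 2:
        raise ValueError("need at least 2 tokens")
    map_tokens = smap.tokens
    try:
        idx = [map_tokens.index(t) for t in tokens]
    except ValueError:
        missing = [t for t in tokens if t not in map_tokens]
        raise KeyError(f"token(s) not on map: {missing}") from None
    sub = smap.distances[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(len(idx), k=1)].mean())


def build_map(
    primitives: Sequence[SemanticPrimitive],
    perplexity: float = 5.0,
    seed: int = 42,
    bandwidth: Optional[float] = None,
    grid_size: int = 100,
) -> SemanticMap:
    """Project primitives, compute distances, stats, and the KDE surface."""
    primitives = list(primitives)
    coords = reduce_2d(primitives, perplexity=perplexity, seed=seed)
    dists = relative_distances(coords)
    stats = distance_stats(dists)
    density = None
    if len(primitives) > 2:
        try:
            kde = gaussian_kde(coords.T, bw_method=bandwidth)
            gx = np.linspace(-0.05, 1.05, grid_size)
            xx, yy = np.meshgrid(gx, gx)
            density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
        except np.linalg.LinAlgError:  # degenerate coordinates
            density = None
    return SemanticMap(primitives, coords, dists, stats, density, seed)


def close_pairs(smap: SemanticMap) -> list[ClosenessVerdict]:
    """Closeness verdicts for every unordered primitive pair on the map."""
    toks = smap.tokens
    out = []
    for i in range(len(toks)):
        for j in range(i + 1, len(toks)):
            out.append(
                is_close(smap.distances[i, j], smap.stats, pair=(toks[i], toks[j]))
            )
    return out


def stats_to_json(stats: DistanceStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(stats), indent=2), encoding="utf-8")


def distances_to_tsv(smap: SemanticMap, path: str | Path) -> None:
    toks = smap.tokens
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("token\t" + "\t".join(toks) + "\n")
        for i, t in enumerate(toks):
            fh.write(t + "\t" + "\t".join(f"{d:.6f}" for d in smap.distances[i]) + "\n")


def render_atlas(
    smap: SemanticMap, path: str | Path, bandwidth: Optional[float] = None
) -> None:
    """Render the atlas: density shading (darker = denser), labeled
    primitives, and the five distance statistics in the upper-left box."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    density = smap.density
    if bandwidth is not None and len(smap.primitives) > 2:
        kde = gaussian_kde(smap.coords.T, bw_method=bandwidth)
        gx = np.linspace(-0.05, 1.05, 100)
        xx, yy = np.meshgrid(gx, gx)
        density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(100, 100)
    if density is not None:
        ax.imshow(
            density,
            origin="lower",
            extent=(-0.05, 1.05, -0.05, 1.05),
            cmap="Greys",
            aspect="auto",
        )
    ax.scatter(smap.coords[:, 0], smap.coords[:, 1], s=12, color="tab:red", zorder=3)
    for p, (x, y) in zip(smap.primitives, smap.coords):
        ax.annotate(p.token, (x, y), fontsize=7, xytext=(2, 2),
                    textcoords="offset points", zorder=4)
    s = smap.stats
    box = (
        f"min: {s.minimum:.4f}\nmax: {s.maximum:.4f}\nQ1: {s.lower_quartile:.4f}\n"
        f"median: {s.median:.4f}\nmean: {s.mean:.4f}"
    )
    ax.text(
        0.02, 0.98, box, transform=ax.transAxes, va="top", ha="left", fontsize=8,
        bbox=dict(boxstyle="round", facecolor="white", alpha=0.8),
    )
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150)
    plt.close(fig)
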