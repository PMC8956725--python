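"""Semantic map geometry: t-SNE projection, distance stats, closeness rule."""

import math

import numpy as np
import pytest

from inferatlas import (
    DistanceStats,
    SemanticPrimitive,
    build_map,
    close_pairs,
    distance_stats,
    group_mean_distance,
    is_close,
    reduce_2d,
    relative_distances,
    render_atlas,
)

TRIANGLE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])


def make_primitives(vectors, tokens=None):
    tokens = tokens or [f"w{i}" for i in range(len(vectors))]
    return [
        SemanticPrimitive(token=t, sf=0.1, sai=0.5, score=0.5,
                          vector=np.asarray(v, dtype=float))
        for t, v in zip(tokens, vectors)
    ]


def stats_like(mean, q1):
    """DistanceStats carrying a given mean and lower quartile."""
    return DistanceStats(minimum=0.0, lower_quartile=q1, median=q1 + 0.01,
                         mean=mean, maximum=1.0, upper_quartile=0.9)


class TestReduce2D:
    def test_shape_and_unit_square(self):
        rng = np.random.default_rng(0)
        coords = reduce_2d(rng.normal(size=(12, 20)), perplexity=3, seed=1)
        assert coords.shape == (12, 2)
        assert coords.min() >= 0.0 and coords.max() <= 1.0

    def test_perplexity_must_be_below_count(self):
        with pytest.raises(ValueError, match="perplexity"):
            reduce_2d(np.eye(4), perplexity=4, seed=0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 15))
        a = reduce_2d(X, perplexity=3, seed=7)
        b = reduce_2d(X, perplexity=3, seed=7)
        assert np.array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(5)
        a = rng.normal(loc=0.0, scale=0.05, size=(10, 40))
        b = rng.normal(loc=3.0, scale=0.05, size=(10, 40))
        coords = reduce_2d(np.vstack([a, b]), perplexity=5, seed=2)
        from sklearn.metrics import silhouette_score

        labels = [0] * 10 + [1] * 10
        assert silhouette_score(coords, labels) > 0.5


class TestDistances:
    def test_hand_geometry_of_right_triangle(self):
        d = relative_distances(TRIANGLE)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(1.0)
        assert d[1, 2] == pytest.approx(math.sqrt(2))

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = relative_distances(rng.random((8, 2)))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_identical_points_distance_zero(self):
        d = relative_distances(np.array([[0.3, 0.3], [0.3, 0.3]]))
        assert d[0, 1] == 0.0

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            relative_distances(np.array([[0.0, 0.0]]))


class TestDistanceStats:
    def test_triangle_mean_and_median(self):
        s = distance_stats(relative_distances(TRIANGLE))
        assert s.mean == pytest.approx((2 + math.sqrt(2)) / 3, abs=1e-9)
        assert s.median == pytest.approx(1.0)
        assert s.minimum == pytest.approx(1.0)
        assert s.maximum == pytest.approx(math.sqrt(2))

    def test_all_equal_distances_collapse_stats(self):
        # equilateral triangle: every pairwise distance equals the side
        side = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        s = distance_stats(relative_distances(side))
        for v in (s.minimum, s.lower_quartile, s.median, s.mean, s.maximum):
            assert v == pytest.approx(1.0)

    def test_quartile_uses_linear_interpolation(self):
        # type-7 rule by hand: for sorted x and h = (n-1)p, the p-quantile is
        # x[floor(h)] + (h - floor(h)) * (x[floor(h)+1] - x[floor(h)]);
        # e.g. for values {1,2,3,4} and p=0.25, h=0.75 gives 1.75
        m = np.zeros((4, 4))
        m[0, 1], m[0, 2], m[0, 3], m[1, 2], m[1, 3], m[2, 3] = 1, 2, 3, 4, 2.5, 3.5
        m = m + m.T
        x = sorted([1, 2, 3, 4, 2.5, 3.5])
        h = (len(x) - 1) * 0.25
        lo = int(h)
        expected_q1 = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
        assert distance_stats(m).lower_quartile == pytest.approx(expected_q1)
        x4 = [1.0, 2.0, 3.0, 4.0]
        h4 = 3 * 0.25
        assert x4[0] + h4 * (x4[1] - x4[0]) == pytest.approx(1.75)

    def test_matches_sorted_brute_force(self):
        rng = np.random.default_rng(2)
        m = relative_distances(rng.random((9, 2)))
        tri = sorted(m[i, j] for i in range(9) for j in range(i + 1, 9))
        s = distance_stats(m)
        assert s.minimum == pytest.approx(tri[0])
        assert s.maximum == pytest.approx(tri[-1])
        assert s.mean == pytest.approx(sum(tri) / len(tri))


class TestCloseness:
    def test_reference_close_pair(self):
        v = is_close(0.0091, stats_like(mean=0.1615, q1=0.1002))
        assert v.close

    def test_boundary_equal_to_quartile_is_not_close(self):
        v = is_close(0.1060, stats_like(mean=0.1775, q1=0.1060))
        assert not v.close

    def test_above_mean_is_not_close(self):
        assert not is_close(0.2, stats_like(mean=0.1615, q1=0.1002)).close

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            is_close(-0.1, stats_like(0.2, 0.1))

    def test_agrees_with_direct_predicate_on_map_pairs(self):
        rng = np.random.default_rng(4)
        prims = make_primitives(rng.normal(size=(12, 30)))
        smap = build_map(prims, perplexity=3, seed=0)
        for v in close_pairs(smap):
            expected = (v.distance < smap.stats.mean
                        and v.distance < smap.stats.lower_quartile)
            assert v.close == expected

    def test_rescaling_coords_preserves_verdicts(self):
        """Uniformly scaling raw coordinates leaves closeness unchanged:
        relative distances rescale together with their statistics."""
        rng = np.random.default_rng(6)
        raw = rng.random((10, 2))
        for scale in (1.0, 3.7, 250.0):
            d = relative_distances(raw * scale)
            s = distance_stats(d)
            verdicts = [is_close(d[i, j], s).close
                        for i in range(10) for j in range(i + 1, 10)]
            if scale == 1.0:
                base = verdicts
            else:
                assert verdicts == base


class TestGroupMeanAndMap:
    def test_group_mean_on_triangle(self):
        prims = make_primitives(np.eye(3, 10), tokens=["a", "b", "c"])
        smap = build_map(prims, perplexity=2, seed=0)
        smap.coords = TRIANGLE.astype(float)
        smap.distances = relative_distances(smap.coords)
        got = group_mean_distance(["a", "b", "c"], smap)
        assert got == pytest.approx((2 + math.sqrt(2)) / 3, abs=1e-9)

    def test_group_mean_of_all_points_equals_stats_mean(self):
        rng = np.random.default_rng(8)
        prims = make_primitives(rng.normal(size=(8, 16)))
        smap = build_map(prims, perplexity=3, seed=1)
        assert group_mean_distance(smap.tokens, smap) == pytest.approx(
            smap.stats.mean
        )

    def test_missing_token_rejected(self):
        prims = make_primitives(np.eye(4, 8))
        smap = build_map(prims, perplexity=2, seed=1)
        with pytest.raises(KeyError):
            group_mean_distance(["w0", "nope"], smap)


class TestRender:
    def test_atlas_file_written_with_stats_box(self, tmp_path):
        rng = np.random.default_rng(9)
        prims = make_primitives(rng.normal(size=(10, 12)))
        smap = build_map(prims, perplexity=3, seed=2)
        out = tmp_path / "atlas.svg"
        render_atlas(smap, out)
        assert out.exists() and out.stat().st_size > 0
        svg = out.read_text(encoding="utf-8")
        s = smap.stats
        for value in (s.minimum, s.maximum, s.lower_quartile, s.median, s.mean):
            assert f"{value:.4f}" in svg
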