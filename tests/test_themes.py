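"""Theme distribution accounting, stratified sampling, and Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inferatlas import (
    Post,
    PostPool,
    cohens_kappa,
    load_codebook,
    stratified_sample,
    theme_distribution,
    verify_codebook,
)
from inferatlas.themes import THEME_CODES

#: Reference coded sample: per-code counts over 1400 posts and the
#: percentages their published table prints for them.
TABLE_COUNTS = {
    "IF-L": 40, "IF-SI": 110, "IF-LA": 247, "IF-FB": 25,
    "IF-PD": 261, "IF-A": 238, "IF-P": 209, "IF-PE": 270,
}
TABLE_PERCENTS = {
    "IF-L": 2.86, "IF-SI": 7.86, "IF-LA": 17.64, "IF-FB": 1.79,
    "IF-PD": 18.64, "IF-A": 17.0, "IF-P": 14.93, "IF-PE": 19.29,
}


class TestCodebook:
    def test_shipped_codebook_has_exactly_eight_codes(self):
        codes = [c.code for c in load_codebook()]
        assert sorted(codes) == sorted(THEME_CODES)
        assert len(codes) == 8


class TestDistribution:
    def test_reference_counts_reproduce_printed_percentages(self):
        labels = [c for c, n in TABLE_COUNTS.items() for _ in range(n)]
        dist = theme_distribution(labels)
        assert dist.total == 1400
        assert sum(dist.counts.values()) == 1400
        assert dist.percentages == TABLE_PERCENTS

    def test_percentages_sum_to_hundred_within_rounding(self):
        labels = [c for c, n in TABLE_COUNTS.items() for _ in range(n)]
        dist = theme_distribution(labels)
        assert abs(sum(dist.percentages.values()) - 100.0) <= 0.05

    def test_half_up_rounding(self):
        # 1/8 = 12.5% exactly: half-up gives 12.50; 270/1400 = 19.2857 -> 19.29
        dist = theme_distribution(["IF-PE"] + ["IF-PD"] * 7)
        assert dist.percentages["IF-PE"] == 12.5
        assert theme_distribution(
            ["IF-PE"] * 270 + ["IF-PD"] * 1130
        ).percentages["IF-PE"] == 19.29

    def test_single_code_hundred_percent(self):
        dist = theme_distribution(["IF-A"] * 7)
        assert dist.percentages["IF-A"] == 100.0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            theme_distribution(["IF-XX"])


class TestKappa:
    def test_identical_vectors_kappa_one(self):
        v = ["IF-A", "IF-P", "IF-A", "IF-L"]
        assert cohens_kappa(v, v).kappa == 1.0

    def test_hand_computed_confusion_table(self):
        # confusion [[20, 5], [10, 15]] over n=50: po=0.70, pe=0.50, kappa=0.40
        r1 = ["a"] * 25 + ["b"] * 25
        r2 = ["a"] * 20 + ["b"] * 5 + ["a"] * 10 + ["b"] * 15
        k = cohens_kappa(r1, r2)
        assert k.po == pytest.approx(0.70)
        assert k.pe == pytest.approx(0.50)
        assert k.kappa == pytest.approx(0.40)

    def test_constant_rater_yields_zero(self):
        r1 = ["a", "b", "a", "b", "b", "a"]
        r2 = ["a"] * 6
        assert cohens_kappa(r1, r2).kappa == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cohens_kappa(["a"], ["a", "b"])

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(0)
        r1 = rng.choice(list("abc"), size=60).tolist()
        r2 = rng.choice(list("abc"), size=60).tolist()
        assert cohens_kappa(r1, r2).kappa == pytest.approx(cohens_kappa(r2, r1).kappa)

    def test_matches_contingency_oracle_on_random_vectors(self):
        """1000 random label-vector pairs against a brute-force
        contingency-table computation (and sklearn as a second opinion)."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(42)
        codes = list("abcd")
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            r1 = rng.choice(codes, size=n).tolist()
            r2 = rng.choice(codes, size=n).tolist()
            table = np.zeros((4, 4))
            for a, b in zip(r1, r2):
                table[codes.index(a), codes.index(b)] += 1
            po = np.trace(table) / n
            pe = float(np.sum(table.sum(1) * table.sum(0)) / n**2)
            if pe >= 1.0 - 1e-12:
                continue
            expected = (po - pe) / (1 - pe)
            got = cohens_kappa(r1, r2)
            assert got.kappa == pytest.approx(expected, abs=1e-12)
            assert got.kappa == pytest.approx(cohen_kappa_score(r1, r2), abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(["x", "y", "z"]), min_size=2, max_size=30))
    def test_kappa_never_exceeds_one(self, labels):
        perm = labels[::-1]
        try:
            k = cohens_kappa(labels, perm).kappa
        except ValueError:
            return  # degenerate marginals with imperfect agreement
        assert k <= 1.0 + 1e-12


def year_pool(counts: dict[int, int]) -> PostPool:
    posts = []
    for year, n in counts.items():
        for i in range(n):
            posts.append(Post(id=f"{year}-{i}", account_id="a", follower_count=0,
                              date=f"{year}-06-15", theme_code="IF-PE"))
    return PostPool(posts)


class TestStratifiedSample:
    def test_seven_years_by_two_hundred(self):
        pool = year_pool({y: 300 for y in range(2011, 2018)})
        out = stratified_sample(pool, per_year=200, seed=1)
        assert len(out) == 1400
        from collections import Counter

        per_year = Counter(p.year for p in out)
        assert all(v == 200 for v in per_year.values())

    def test_zero_per_year_empty(self):
        pool = year_pool({2011: 10})
        assert len(stratified_sample(pool, per_year=0)) == 0

    def test_insufficient_year_error_names_year(self):
        pool = year_pool({2011: 300, 2012: 150})
        with pytest.raises(ValueError, match="2012"):
            stratified_sample(pool, per_year=200)

    def test_deterministic_per_seed(self):
        pool = year_pool({2011: 50, 2012: 50})
        a = stratified_sample(pool, per_year=20, seed=9)
        b = stratified_sample(pool, per_year=20, seed=9)
        assert a.ids == b.ids


class TestVerifyCodebook:
    def test_perfect_raters_all_kappas_one(self):
        ids = [f"p{i}" for i in range(200)]
        rng = np.random.default_rng(1)
        codes = rng.choice(THEME_CODES, size=200)
        a1 = dict(zip(ids, codes))
        kappas = verify_codebook(a1, dict(a1), n_check=140, seed=0)
        assert kappas["overall"].kappa == 1.0
        for c in THEME_CODES:
            assert kappas[c].kappa == 1.0

    def test_full_sample_check_equals_direct_computation(self):
        ids = [f"p{i}" for i in range(100)]
        rng = np.random.default_rng(2)
        a1 = dict(zip(ids, rng.choice(THEME_CODES, size=100)))
        a2 = dict(zip(ids, rng.choice(THEME_CODES, size=100)))
        kappas = verify_codebook(a1, a2, n_check=100, seed=0)
        direct = cohens_kappa([a1[i] for i in sorted(ids)], [a2[i] for i in sorted(ids)])
        assert kappas["overall"].kappa == pytest.approx(direct.kappa)

    def test_n_check_above_sample_rejected(self):
        a = {"p1": "IF-A", "p2": "IF-P"}
        with pytest.raises(ValueError):
            verify_codebook(a, dict(a), n_check=3)
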