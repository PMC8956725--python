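"""Theme codebook, stratified sampling, distribution stats, and Cohen's kappa.

The causes of inferiority feelings are coded with an eight-code
codebook: physical defects (IF-PD), love and affection (IF-LA), family
background (IF-FB), personality (IF-P), personal experiences (IF-PE),
social interaction (IF-SI), learning (IF-L), and abilities (IF-A).
Posts are sampled per publication year (200 per year over seven years by
default), each post receives exactly one code, and coding consistency is
verified on a random subsample with Cohen's kappa,

    kappa = (p_o − p_e) / (1 − p_e),

where ``p_o`` is the observed agreement rate of the two raters and
``p_e`` the agreement expected by chance from their marginal code
frequencies.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus import PostPool

#: The eight theme codes in codebook order.
THEME_CODES = ("IF-PD", "IF-LA", "IF-FB", "IF-P", "IF-PE", "IF-SI", "IF-L", "IF-A")


@dataclass(frozen=True)
class ThemeCode:
    code: str
    description: str
    example: str = ""


@dataclass
class ThemeDistribution:
    """Per-code counts and percentages of a coded sample."""

    counts: dict[str, int]
    percentages: dict[str, float]  # percent of total, half-up rounded to 2 decimals
    total: int


@dataclass
class KappaResult:
    po: float
    pe: float
    kappa: float
    n: int


def load_codebook(path: Optional[str | Path] = None) -> list[ThemeCode]:
    """The shipped eight-code codebook (or a user-supplied CSV)."""
    if path is None:
        ref = resources.files("inferatlas") / "data" / "theme_codebook.csv"
        with resources.as_file(ref) as p:
            return load_codebook(p)
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        return [
            ThemeCode(rec["code"], rec["description"], rec.get("example", ""))
            for rec in csv.DictReader(fh)
        ]


def stratified_sample(
    pool: PostPool,
    per_year: int = 200,
    years: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> PostPool:
    """Sample ``per_year`` posts uniformly without replacement from each year.

    Errors name any year with fewer than ``per_year`` dated posts.
    """
    if per_year < 0:
        raise ValueError("per_year must be non-negative")
    by_year: dict[int, list[str]] = {}
    for p in pool:
        if p.year is not None:
            by_year.setdefault(p.year, []).append(p.id)
    if years is None:
        years = sorted(by_year)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for y in years:
        ids = by_year.get(y, [])
        if len(ids) < per_year:
            raise ValueError(
                f"year {y} has only {len(ids)} posts, need {per_year}"
            )
        picked = rng.choice(len(ids), size=per_year, replace=False)
        chosen.extend(ids[i] for i in sorted(picked))
    return pool.subset(chosen, note=f"stratified sample {per_year}/year over {list(years)}")


def _round_half_up(x: Decimal, places: str = "0.01") -> float:
    return float(x.quantize(Decimal(places), rounding=ROUND_HALF_UP))


def theme_distribution(
    assignments: Mapping[str, str] | Sequence[str],
    codes: Sequence[str] = THEME_CODES,
) -> ThemeDistribution:
    """Counts and percentages per theme code over a coded sample.

    ``assignments`` maps post id → code (or is a plain code sequence).
    Percentages are ``count / total × 100`` rounded half-up to two
    decimals, matching how coding tables are conventionally printed.
    """
    labels = list(assignments.values()) if isinstance(assignments, Mapping) else list(assignments)
    if not labels:
        raise ValueError("no assignments given")
    unknown = sorted(set(labels) - set(codes))
    if unknown:
        raise ValueError(f"unknown theme code(s): {', '.join(unknown)}")
    counts = Counter(labels)
    total = len(labels)
    pct = {
        c: _round_half_up(Decimal(counts.get(c, 0)) * 100 / Decimal(total))
        for c in codes
    }
    return ThemeDistribution({c: counts.get(c, 0) for c in codes}, pct, total)


def cohens_kappa(r1: Sequence[str], r2: Sequence[str]) -> KappaResult:
    """Cohen's kappa between two raters' label vectors.

    ``p_o`` is the fraction of positions where the raters agree; ``p_e``
    sums, over codes, the product of the two raters' marginal
    proportions.  Degenerate case: when ``p_e == 1`` both raters are
    constant on the same code — perfect agreement, kappa 1; a constant
    rater against a varying one yields kappa 0 through the formula.
    """
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2):
        raise ValueError(f"length mismatch: {len(r1)} vs {len(r2)}")
    n = len(r1)
    if n == 0:
        raise ValueError("empty label vectors")
    po = sum(a == b for a, b in zip(r1, r2)) / n
    m1, m2 = Counter(r1), Counter(r2)
    pe = sum((m1[c] / n) * (m2[c] / n) for c in set(m1) | set(m2))
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return KappaResult(po=1.0, pe=1.0, kappa=1.0, n=n)
        raise ValueError("degenerate marginals: pe == 1 with imperfect agreement")
    return KappaResult(po=po, pe=pe, kappa=(po - pe) / (1.0 - pe), n=n)


def verify_codebook(
    assignments_r1: Mapping[str, str],
    assignments_r2: Mapping[str, str],
    n_check: int = 140,
    seed: int = 0,
    codes: Sequence[str] = THEME_CODES,
) -> dict[str, KappaResult]:
    """Consistency check on a random subsample of doubly-coded posts.

    Draws ``n_check`` post ids (seeded, without replacement) from the
    ids both raters coded, and returns the overall kappa under key
    ``"overall"`` plus a one-vs-rest kappa per code.
    """
    ids = sorted(set(assignments_r1) & set(assignments_r2))
    if n_check > len(ids):
        raise ValueError(f"n_check={n_check} exceeds the {len(ids)} doubly-coded posts")
    rng = np.random.default_rng(seed)
    picked = [ids[i] for i in rng.choice(len(ids), size=n_check, replace=False)]
    v1 = [assignments_r1[i] for i in picked]
    v2 = [assignments_r2[i] for i in picked]
    out: dict[str, KappaResult] = {"overall": cohens_kappa(v1, v2)}
    for c in codes:
        b1 = [x == c for x in v1]
        b2 = [x == c for x in v2]
        try:
            out[c] = cohens_kappa([str(x) for x in b1], [str(x) for x in b2])
        except ValueError:
            # code absent for one rater with imperfect agreement: kappa undefined
            out[c] = KappaResult(po=float("nan"), pe=1.0, kappa=float("nan"), n=n_check)
    return out
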