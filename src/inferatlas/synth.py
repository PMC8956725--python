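"""Synthetic microblog corpora with planted structure.

Real inferiority-feeling corpora cannot be redistributed, so every
downstream stage is exercised on generated corpora whose ground truth is
known by construction.  The generator plants exactly the structure the
pipeline is supposed to recover:

* **Two post types of interest** — type 1 posts contain the head
  keyword for *inferiority*; type 2 posts instead hit every core
  attribute group A1–A4 plus at least one affect group (A5 ∪ A6), i.e.
  they satisfy the ontology conjunction by construction while never
  containing the head keyword.
* **Off-target noise** — advertisement-like and aphorism-like posts
  built from two disjoint noise vocabularies; they contain neither the
  head keyword nor any attribute token.
* **Marketing accounts** — a fixed fraction of accounts get follower
  counts above 5000, so the marketing pre-filter has a known yield.
* **Theme clusters** — each relevant post draws a theme; its content
  tokens come from that theme's core vocabulary (ten tokens per theme by
  default) mixed with a shared filler vocabulary, so same-theme tokens
  co-occur within posts and the skip-gram geometry is predictable.  The
  core tokens are the planted "semantic primitives" the SF-SAI stage
  should recover.
* **Rater noise** — two simulated coders report the true theme with
  probability ``1 − error_rate``, else a uniformly random other code.

All randomness flows from a single config seed; a fixed config yields a
byte-identical corpus.  Default theme weights follow the empirical
distribution of causes reported for coded microblog samples (personal
experiences most common at ~19%, family background rarest at ~1.8%).
No attempt is made to model real microblog style, post lengths, or user
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import Post, PostPool
from .ontology import (
    ATTRIBUTE_TABLE,
    AFFECT_GROUPS,
    CORE_GROUPS,
    HEAD_KEYWORD,
    HEAD_KEYWORD_ASCII,
    AttributeGroup,
    default_groups,
)
from .themes import THEME_CODES

#: Default theme mixture: the empirical shares of the eight causes.
DEFAULT_THEME_WEIGHTS: dict[str, float] = {
    "IF-L": 0.0286,
    "IF-SI": 0.0786,
    "IF-LA": 0.1764,
    "IF-FB": 0.0179,
    "IF-PD": 0.1864,
    "IF-A": 0.17,
    "IF-P": 0.1493,
    "IF-PE": 0.1928,  # weights must sum to 1; residual absorbed here
}

CORE_TOKENS_PER_THEME = 10

# POS tags per token class (synthetic tags; content tokens are nouns so a
# noun-only candidate filter keeps content and drops function words)
_GROUP_POS = {"A1": "v", "A2": "r", "A3": "v", "A4": "r", "A5": "a", "A6": "a"}


def generate_keyword_tables(seed: int = 0, ascii_tokens: bool = False) -> list[AttributeGroup]:
    """The six attribute groups A1–A6 (head word + synonyms).

    ``ascii_tokens`` swaps the Chinese tokens for transliterated ASCII
    equivalents of identical cardinality, for test readability.  The
    output is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators.
    """
    return default_groups(ascii_tokens=ascii_tokens)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    n_posts: int = 2000
    n_accounts: int = 300
    marketing_fraction: float = 0.2
    p_keyword_post: float = 0.35  # type 1: contains the head keyword
    p_attribute_post: float = 0.25  # type 2: satisfies the ontology conjunction
    p_offtarget: float = 0.40  # ads / aphorisms
    theme_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THEME_WEIGHTS)
    )
    vocab_size: int = 240  # shared filler tokens
    n_noise_tokens: int = 40  # per off-target noise class
    filler_rate: float = 0.4  # share of content slots drawn from fillers
    filler_home_bias: float = 0.7  # share of filler draws from the theme's home fillers
    tokens_per_post: tuple[int, int] = (12, 30)
    rater_error_rate: float = 0.1
    years: tuple[int, int] = (2011, 2017)  # inclusive
    ascii_tokens: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_keyword_post + self.p_attribute_post + self.p_offtarget
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"post-type proportions sum to {total}, expected 1")
        wsum = sum(self.theme_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"theme weights sum to {wsum}, expected 1")
        unknown = set(self.theme_weights) - set(THEME_CODES)
        if unknown:
            raise ValueError(f"unknown theme code(s) in weights: {sorted(unknown)}")
        lo, hi = self.tokens_per_post
        if lo > hi or lo < 1:
            raise ValueError(f"bad tokens_per_post range {self.tokens_per_post}")
        if self.p_attribute_post > 0 and lo < 5:
            raise ValueError(
                "tokens_per_post minimum must be >= 5 when attribute posts are "
                "generated (a type-2 post needs five attribute tokens)"
            )

    @property
    def head_keyword(self) -> str:
        return HEAD_KEYWORD_ASCII if self.ascii_tokens else HEAD_KEYWORD


@dataclass
class GroundTruth:
    """Planted per-post labels and per-theme primitive sets."""

    frame: pd.DataFrame  # columns: post_id, post_type, relevance, eq1_match, theme
    theme_primitives: dict[str, tuple[str, ...]]  # theme -> planted core tokens
    token_pos: dict[str, str]  # token -> synthetic POS tag

    @property
    def target_ids(self) -> set[str]:
        f = self.frame
        return set(f.loc[f.relevance == "target", "post_id"])

    @property
    def keyword_ids(self) -> set[str]:
        f = self.frame
        return set(f.loc[f.post_type == "keyword", "post_id"])

    @property
    def eq1_ids(self) -> set[str]:
        f = self.frame
        return set(f.loc[f.eq1_match, "post_id"])

    @property
    def themed(self) -> pd.DataFrame:
        return self.frame[self.frame.theme.notna()].reset_index(drop=True)


def _theme_vocab(code: str) -> list[str]:
    stem = code.lower().replace("if-", "")
    return [f"{stem}_core{i:02d}" for i in range(CORE_TOKENS_PER_THEME)]


def generate_corpus(config: SyntheticConfig) -> tuple[PostPool, GroundTruth]:
    """Generate a corpus and its ground truth (deterministic per seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    groups = {g.name: sorted(g.members) for g in default_groups(cfg.ascii_tokens)}
    head = cfg.head_keyword

    fillers = [f"filler{i:03d}" for i in range(cfg.vocab_size)]
    ad_vocab = [f"ad{i:03d}" for i in range(cfg.n_noise_tokens)]
    apho_vocab = [f"apho{i:03d}" for i in range(cfg.n_noise_tokens)]
    themes = sorted(cfg.theme_weights)
    theme_vocabs = {c: _theme_vocab(c) for c in themes}
    # each filler leans toward one "home" theme: real filler words carry a
    # topical skew, which keeps fillers from collapsing into one embedding hub
    filler_home = rng.integers(0, len(themes), size=len(fillers))
    home_fillers = {
        t: [fillers[j] for j in np.flatnonzero(filler_home == i)] or fillers
        for i, t in enumerate(themes)
    }

    token_pos: dict[str, str] = {head: "a"}
    for name, members in groups.items():
        for m in members:
            token_pos[m] = _GROUP_POS[name]
    for t in fillers + ad_vocab + apho_vocab:
        token_pos[t] = "n"
    for vocab in theme_vocabs.values():
        for t in vocab:
            token_pos[t] = "n"

    # accounts: exactly round(marketing_fraction * n_accounts) marketing
    n_mkt = int(round(cfg.marketing_fraction * cfg.n_accounts))
    followers = np.concatenate(
        [
            rng.integers(5001, 50001, size=n_mkt),
            rng.integers(10, 5001, size=cfg.n_accounts - n_mkt),
        ]
    )
    acc_order = rng.permutation(cfg.n_accounts)
    followers = followers[acc_order]
    account_ids = [f"acc{i:05d}" for i in range(cfg.n_accounts)]

    # exact planted type counts
    n_kw = int(round(cfg.p_keyword_post * cfg.n_posts))
    n_attr = int(round(cfg.p_attribute_post * cfg.n_posts))
    n_off = cfg.n_posts - n_kw - n_attr
    if n_off < 0:
        raise ValueError("post-type proportions produce a negative off-target count")
    types = np.array(["keyword"] * n_kw + ["attribute"] * n_attr + ["offtarget"] * n_off)
    rng.shuffle(types)

    theme_p = np.array([cfg.theme_weights[c] for c in themes])
    lo, hi = cfg.tokens_per_post
    y0, y1 = cfg.years

    posts: list[Post] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_posts):
        ptype = str(types[i])
        acc = int(rng.integers(0, cfg.n_accounts))
        length = int(rng.integers(lo, hi + 1))
        year = int(rng.integers(y0, y1 + 1))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        date = f"{year:04d}-{month:02d}-{day:02d}"

        theme: Optional[str] = None
        if ptype == "offtarget":
            noise_vocab = ad_vocab if rng.random() < 0.5 else apho_vocab
            tokens = [
                noise_vocab[int(rng.integers(0, len(noise_vocab)))]
                for _ in range(length)
            ]
        else:
            theme = themes[int(rng.choice(len(themes), p=theme_p))]
            vocab = theme_vocabs[theme]
            home = home_fillers[theme]

            def draw_content() -> str:
                if rng.random() < cfg.filler_rate:
                    if rng.random() < cfg.filler_home_bias:
                        return home[int(rng.integers(0, len(home)))]
                    return fillers[int(rng.integers(0, len(fillers)))]
                return vocab[int(rng.integers(0, len(vocab)))]

            content = [draw_content() for _ in range(length)]
            if ptype == "keyword":
                content[int(rng.integers(0, length))] = head
            else:  # attribute post: one token per core group + one affect token
                picks = [
                    groups[g][int(rng.integers(0, len(groups[g])))] for g in CORE_GROUPS
                ]
                affect = AFFECT_GROUPS[int(rng.integers(0, len(AFFECT_GROUPS)))]
                picks.append(groups[affect][int(rng.integers(0, len(groups[affect])))])
                slots = rng.choice(length, size=len(picks), replace=False)
                for s, tok in zip(slots, picks):
                    content[int(s)] = tok
            tokens = content

        relevance = "off_target" if ptype == "offtarget" else "target"
        posts.append(
            Post(
                id=f"post{i:06d}",
                account_id=account_ids[acc],
                follower_count=int(followers[acc]),
                text=" ".join(tokens),
                date=date,
                tokens=tokens,
                pos_tags=[token_pos[t] for t in tokens],
                relevance_label=relevance,
                theme_code=theme,
            )
        )
        truth_rows.append(
            {
                "post_id": f"post{i:06d}",
                "post_type": ptype,
                "relevance": relevance,
                "eq1_match": ptype == "attribute",
                "theme": theme,
            }
        )

    pool = PostPool(posts, provenance=f"synthetic corpus (seed={cfg.seed}, n={cfg.n_posts})")
    truth = GroundTruth(
        frame=pd.DataFrame(truth_rows),
        theme_primitives={c: tuple(v) for c, v in theme_vocabs.items()},
        token_pos=token_pos,
    )
    return pool, truth


def simulate_raters(
    truth: GroundTruth,
    error_rate: float,
    seed: int = 0,
    codes: Sequence[str] = THEME_CODES,
) -> pd.DataFrame:
    """Two simulated coders over the themed posts.

    Each rater independently reports the true theme with probability
    ``1 − error_rate``, otherwise a uniformly random *other* code.
    Returns a frame with columns ``post_id, truth, rater1, rater2``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    themed = truth.themed
    rng = np.random.default_rng(seed)
    codes = list(codes)

    def one_rater() -> list[str]:
        out = []
        for t in themed.theme:
            if rng.random() < error_rate:
                others = [c for c in codes if c != t]
                out.append(others[int(rng.integers(0, len(others)))])
            else:
                out.append(t)
        return out

    return pd.DataFrame(
        {
            "post_id": themed.post_id,
            "truth": themed.theme,
            "rater1": one_rater(),
            "rater2": one_rater(),
        }
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as CSV (post_id, post_type, relevance, eq1_match, theme)."""
    truth.frame.to_csv(path, index=False)
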