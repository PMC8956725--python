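"""Ontology-attribute keyword filtering of microblog posts.

Inferiority-related posts fall in two classes: posts that literally
contain the head keyword ("自卑", *inferiority*), and posts that express
the concept without naming it.  The second class is selected with a
boolean filter over six ontological attribute groups A1–A6 derived from
dictionary definitions of the concept — A1 *think*, A2 *oneself*,
A3 *inferior to*, A4 *other people*, A5 *feel low*, A6 *sadness*, each a
head word plus its synonyms.  A post is selected when it hits all four
core groups and at least one affect group:

    A1 ∩ A2 ∩ A3 ∩ A4 ∩ (A5 ∪ A6)

Matching is exact token match on the segmented token list by default
(substring matching on raw text is available behind a flag).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import Post, PostPool

GROUP_NAMES = ("A1", "A2", "A3", "A4", "A5", "A6")
CORE_GROUPS = ("A1", "A2", "A3", "A4")
AFFECT_GROUPS = ("A5", "A6")

#: Head keyword of the concept, in Chinese and ASCII-transliterated form.
HEAD_KEYWORD = "自卑"
HEAD_KEYWORD_ASCII = "zibei"

#: The six attribute groups: (chinese token, ascii transliteration, gloss).
#: First entry of each group is the head word, the rest are synonyms.
ATTRIBUTE_TABLE: dict[str, list[tuple[str, str, str]]] = {
    "A1": [("认为", "renwei", "think"), ("以为", "yiwei", "feel")],
    "A2": [("自己", "ziji", "oneself"), ("本人", "benren", "myself"), ("我", "wo", "I")],
    "A3": [("不如", "buru", "inferior to"), ("比不过", "bibuguo", "not equal to")],
    "A4": [
        ("别人", "bieren", "other people"),
        ("他", "tahe", "he"),
        ("她", "tashe", "she"),
        ("他/她们", "tamen", "them"),
    ],
    "A5": [
        ("低落", "diluo", "feel low"),
        ("沮丧", "jusang", "depressed"),
        ("颓唐", "tuitang", "dejected"),
        ("萎靡", "weimi", "downhearted"),
        ("消沉", "xiaochen", "despondent"),
    ],
    "A6": [
        ("悲伤", "beishang", "sadness"),
        ("心酸", "xinsuan", "feel sad"),
        ("悲戚", "beiqi", "grief"),
        ("伤感", "shanggan", "unhappiness"),
        ("悲哀", "beiai", "sadness"),
        ("哀痛", "aitong", "mourning"),
    ],
}


@dataclass(frozen=True)
class AttributeGroup:
    """A named keyword set: the head word of one attribute plus synonyms."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of one selection strategy on one post."""

    post_id: str
    selected: bool
    matched_groups: frozenset[str]
    strategy: str  # "keyword" | "ontology"


def default_groups(ascii_tokens: bool = False) -> list[AttributeGroup]:
    """The six packaged attribute groups (Chinese or ASCII token mode)."""
    idx = 1 if ascii_tokens else 0
    return [
        AttributeGroup(name, frozenset(row[idx] for row in rows))
        for name, rows in ATTRIBUTE_TABLE.items()
    ]


def load_keyword_table(path: Optional[str | Path] = None) -> list[AttributeGroup]:
    """Load attribute groups from a CSV with columns group, token, gloss.

    Without a path, the packaged default table is used.
    """
    if path is None:
        ref = resources.files("inferatlas") / "data" / "attribute_keywords.csv"
        with resources.as_file(ref) as p:
            return load_keyword_table(p)
    members: dict[str, set[str]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            members.setdefault(rec["group"], set()).add(rec["token"])
    return [AttributeGroup(name, frozenset(toks)) for name, toks in sorted(members.items())]


def _group_map(groups: Iterable[AttributeGroup]) -> dict[str, AttributeGroup]:
    gmap = {g.name: g for g in groups}
    missing = [n for n in GROUP_NAMES if n not in gmap]
    if missing:
        raise ValueError(f"missing attribute group(s): {', '.join(missing)}")
    return gmap


def matches_group(
    tokens: Sequence[str], group: AttributeGroup, text: Optional[str] = None
) -> bool:
    """True iff any token equals any group member (exact string match).

    When ``text`` is given instead of tokens, substring matching on the
    raw text is used.
    """
    if text is not None:
        return any(m in text for m in group.members)
    return any(t in group.members for t in tokens)


def eq1_filter(
    post: Post, groups: Iterable[AttributeGroup], on_text: bool = False
) -> FilterVerdict:
    """Apply the attribute-group conjunction A1∩A2∩A3∩A4∩(A5∪A6) to one post."""
    gmap = _group_map(groups)
    text = post.text if on_text else None
    tokens = post.tokens if not on_text else ()
    matched = frozenset(
        name for name, g in gmap.items() if matches_group(tokens, g, text=text)
    )
    selected = all(n in matched for n in CORE_GROUPS) and any(
        n in matched for n in AFFECT_GROUPS
    )
    return FilterVerdict(post.id, selected, matched, strategy="ontology")


def eq1_select(
    pool: PostPool, groups: Iterable[AttributeGroup], on_text: bool = False
) -> PostPool:
    """Posts selected by the attribute-group boolean filter."""
    groups = list(groups)
    keep = [p.id for p in pool if eq1_filter(p, groups, on_text=on_text).selected]
    return pool.subset(keep, note="ontology attribute filter")


def keyword_select(pool: PostPool, head_keyword: str = HEAD_KEYWORD) -> PostPool:
    """Posts containing the head keyword.

    Token-level exact match when the post is tokenized, substring match
    on the raw text otherwise — mirroring a keyword search.
    """
    if not head_keyword:
        raise ValueError("head_keyword must be non-empty")

    def hit(p: Post) -> bool:
        return head_keyword in p.tokens if p.tokens else head_keyword in p.text

    return pool.subset([p.id for p in pool if hit(p)], note=f"keyword search {head_keyword!r}")


def union_select(
    pool: PostPool,
    groups: Iterable[AttributeGroup],
    head_keyword: str = HEAD_KEYWORD,
    on_text: bool = False,
) -> PostPool:
    """Union of the two crawl strategies, deduplicated by post id."""
    groups = list(groups)
    by_keyword = set(keyword_select(pool, head_keyword).ids)
    by_ontology = set(eq1_select(pool, groups, on_text=on_text).ids)
    return pool.subset(
        by_keyword | by_ontology,
        note=f"union selection ({len(by_keyword)} keyword, {len(by_ontology)} ontology)",
    )
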