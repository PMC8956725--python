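"""Core data types for microblog posts and the post pool.

A :class:`Post` is one microblog record: an opaque id, the posting
account, the account's follower count at crawl time, the post date, the
raw text, and the segmented token sequence (with optional aligned
part-of-speech tags).  A :class:`PostPool` is a collection of posts with
unique ids plus a free-text provenance trail recording the filters that
produced it.

The only analysis step owned here is the marketing-account pre-filter:
accounts with more than 5000 followers are treated as marketing accounts
and their posts are dropped before any semantic processing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

RELEVANCE_LABELS = ("target", "off_target")

#: Fields serialized to JSONL / CSV, in column order.
POST_FIELDS = (
    "id",
    "account_id",
    "follower_count",
    "date",
    "text",
    "tokens",
    "pos_tags",
    "relevance_label",
    "theme_code",
)


@dataclass
class Post:
    """One microblog post.

    ``tokens`` may be empty until segmentation; when ``pos_tags`` is
    present it must align one-to-one with ``tokens``.  ``date`` is an
    ISO-8601 string (``YYYY-MM-DD``) or ``None``.
    """

    id: str
    account_id: str
    follower_count: int
    text: str = ""
    date: Optional[str] = None
    tokens: list[str] = field(default_factory=list)
    pos_tags: Optional[list[str]] = None
    relevance_label: Optional[str] = None
    theme_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.follower_count < 0:
            raise ValueError(
                f"post {self.id!r}: follower_count must be >= 0, got {self.follower_count}"
            )
        if self.pos_tags is not None and len(self.pos_tags) != len(self.tokens):
            raise ValueError(
                f"post {self.id!r}: {len(self.pos_tags)} pos_tags for {len(self.tokens)} tokens"
            )
        if self.relevance_label is not None and self.relevance_label not in RELEVANCE_LABELS:
            raise ValueError(
                f"post {self.id!r}: relevance_label must be one of {RELEVANCE_LABELS}"
            )

    @property
    def year(self) -> Optional[int]:
        return int(self.date[:4]) if self.date else None


@dataclass
class PostPool:
    """A collection of posts with unique ids and a provenance trail."""

    posts: list[Post] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.posts:
            if p.id in seen:
                raise ValueError(f"duplicate post id {p.id!r} in pool")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.posts]

    def by_id(self, post_id: str) -> Post:
        for p in self.posts:
            if p.id == post_id:
                return p
        raise KeyError(post_id)

    def subset(self, keep: Iterable[str], note: str = "") -> "PostPool":
        """New pool with the posts whose ids are in ``keep`` (order kept)."""
        keep = set(keep)
        prov = self.provenance + (f" | {note}" if note else "")
        return PostPool([p for p in self.posts if p.id in keep], prov.strip(" |"))


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def _post_from_record(rec: dict, where: str) -> Post:
    for key in ("id", "account_id", "follower_count", "text"):
        if key not in rec or rec[key] in (None, ""):
            if key == "text" and rec.get(key) == "":
                continue  # empty text is legal
            raise ValueError(f"{where}: missing required field {key!r}")
    tokens = rec.get("tokens") or []
    if isinstance(tokens, str):
        tokens = tokens.split()
    pos_tags = rec.get("pos_tags") or None
    if isinstance(pos_tags, str):
        pos_tags = pos_tags.split() or None
    return Post(
        id=str(rec["id"]),
        account_id=str(rec["account_id"]),
        follower_count=int(rec["follower_count"]),
        text=rec.get("text") or "",
        date=rec.get("date") or None,
        tokens=list(tokens),
        pos_tags=list(pos_tags) if pos_tags else None,
        relevance_label=rec.get("relevance_label") or None,
        theme_code=rec.get("theme_code") or None,
    )


def read_posts(path: str | Path, format: Optional[str] = None) -> PostPool:
    """Read a post pool from JSONL (one post per line) or CSV.

    Malformed records raise :class:`ValueError` naming the offending
    line; duplicate ids raise as well (via :class:`PostPool`).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    posts: list[Post] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
                posts.append(_post_from_record(rec, f"line {lineno}"))
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                posts.append(_post_from_record(rec, f"line {lineno}"))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")
    return PostPool(posts, provenance=f"read from {path.name} ({fmt})")


def write_posts(pool: PostPool, path: str | Path, format: Optional[str] = None) -> None:
    """Write a pool to JSONL or CSV (UTF-8; lossless round trip).

    Tokens are stored as a JSON list in JSONL and as a whitespace-joined
    string in CSV (CSV has no native list type).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for p in pool:
                rec = {
                    "id": p.id,
                    "account_id": p.account_id,
                    "follower_count": p.follower_count,
                    "date": p.date,
                    "text": p.text,
                    "tokens": p.tokens,
                    "pos_tags": p.pos_tags,
                    "relevance_label": p.relevance_label,
                    "theme_code": p.theme_code,
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=POST_FIELDS)
            writer.writeheader()
            for p in pool:
                writer.writerow(
                    {
                        "id": p.id,
                        "account_id": p.account_id,
                        "follower_count": p.follower_count,
                        "date": p.date or "",
                        "text": p.text,
                        "tokens": " ".join(p.tokens),
                        "pos_tags": " ".join(p.pos_tags) if p.pos_tags else "",
                        "relevance_label": p.relevance_label or "",
                        "theme_code": p.theme_code or "",
                    }
                )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")


# ---------------------------------------------------------------------------
# Filters


def filter_marketing_accounts(pool: PostPool, threshold: int = 5000) -> PostPool:
    """Drop posts by marketing accounts (strictly more than ``threshold`` followers).

    Accounts with *more than* 5000 followers are generally marketing
    accounts whose posts are mostly advertisements; posts from accounts
    with exactly ``threshold`` followers are kept (strict inequality).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be a positive integer, got {threshold}")
    kept = [p for p in pool if p.follower_count <= threshold]
    removed = len(pool) - len(kept)
    pct = (100.0 * removed / len(pool)) if len(pool) else 0.0
    note = f"marketing filter (> {threshold} followers): removed {removed} ({pct:.1f}%)"
    prov = (pool.provenance + " | " + note).strip(" |")
    return PostPool(kept, prov)


def filter_date_range(pool: PostPool, start: str, end: str) -> PostPool:
    """Keep posts dated in ``[start, end)`` (ISO-8601 strings; undated dropped)."""
    kept = [p for p in pool if p.date is not None and start <= p.date < end]
    prov = (pool.provenance + f" | date window [{start}, {end})").strip(" |")
    return PostPool(kept, prov)
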