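"""Corpus ingestion: read coded posts, keyword-filter, deduplicate.

Posts arrive as line-delimited JSON (or CSV with the same columns):
``id``, ``created_utc`` (epoch seconds), ``user_type``, ``post_type``,
``text``.  User and post types come from a closed coding vocabulary;
missing labels default to ``unknown``.  Usernames and links are never
ingested — records carry no identifying information beyond the opaque id.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Closed label vocabularies for manual coding (hc = healthcare professional).
USER_TYPES: tuple[str, ...] = ("patient", "caregiver", "hc", "unknown")
POST_TYPES: tuple[str, ...] = ("advice", "experience", "both", "unknown")


class CorpusFormatError(ValueError):
    """Malformed corpus record; the message names the line."""


@dataclass(frozen=True)
class CodedPost:
    """One forum post with its manual codes.

    ``created`` is epoch seconds (UTC); ``user_type`` and ``post_type`` are
    restricted to the closed coding vocabularies.
    """

    id: str
    created: int
    user_type: str
    post_type: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")
        if self.user_type not in USER_TYPES:
            raise ValueError(
                f"user_type {self.user_type!r} not in {USER_TYPES}"
            )
        if self.post_type not in POST_TYPES:
            raise ValueError(
                f"post_type {self.post_type!r} not in {POST_TYPES}"
            )


@dataclass(frozen=True)
class KeywordPattern:
    """A wildcard keyword such as ``clinical*trial``.

    ``*`` matches zero or more *non-alphanumeric* characters, so the
    pattern matches "clinical trial", "clinical-trial" and "clinicaltrial"
    but not "clinically trialed" (letters must never be swallowed).
    Matching is case-insensitive substring search.
    """

    raw: str

    def __post_init__(self) -> None:
        if not any(tok for tok in self.raw.split("*") if re.search(r"[0-9a-zA-Z]", tok)):
            raise ValueError(
                f"keyword pattern {self.raw!r} has no literal alphanumeric token"
            )

    def regex(self) -> re.Pattern[str]:
        tokens = [t for t in self.raw.split("*") if t]
        body = r"[^0-9a-zA-Z]*".join(re.escape(t) for t in tokens)
        return re.compile(body, re.IGNORECASE)

    def matches(self, text: str) -> bool:
        return self.regex().search(text) is not None


#: The default clinical-trial keyword set.
DEFAULT_KEYWORDS: tuple[KeywordPattern, ...] = tuple(
    KeywordPattern(p)
    for p in (
        "clinical*trial",
        "new*drug",
        "new*treatment",
        "experimental*trial",
        "experimental*drug",
        "experimental*treatment",
    )
)


def _post_from_record(record: dict, where: str) -> CodedPost:
    if "id" not in record or not str(record["id"]).strip():
        raise CorpusFormatError(f"{where}: missing or empty 'id'")
    if "text" not in record:
        raise CorpusFormatError(f"{where}: missing 'text'")
    try:
        created = int(record.get("created_utc", 0))
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"{where}: created_utc not an integer") from exc
    user_type = str(record.get("user_type") or "unknown").strip().lower() or "unknown"
    post_type = str(record.get("post_type") or "unknown").strip().lower() or "unknown"
    try:
        return CodedPost(
            id=str(record["id"]),
            created=created,
            user_type=user_type,
            post_type=post_type,
            text=str(record["text"]),
        )
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: {exc}") from exc


def read_posts(path: str | Path) -> list[CodedPost]:
    """Read a corpus of coded posts from JSONL or CSV.

    Format is chosen by extension (``.csv`` → CSV with header; anything
    else → one JSON object per line).  Missing ``user_type``/``post_type``
    default to ``unknown``; labels outside the coding vocabularies raise
    :class:`CorpusFormatError` naming the offending line.
    """
    path = Path(path)
    posts: list[CodedPost] = []
    if path.suffix.lower() == ".csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                posts.append(_post_from_record(row, f"{path}:{lineno}"))
    else:
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                if not raw.strip():
                    continue
                try:
                    record = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if not isinstance(record, dict):
                    raise CorpusFormatError(f"{path}:{lineno}: record is not an object")
                posts.append(_post_from_record(record, f"{path}:{lineno}"))
    return posts


def write_posts(posts: Iterable[CodedPost], path: str | Path) -> None:
    """Write posts as JSONL (round-trips bit-identically on text content)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "created_utc": p.created,
                        "user_type": p.user_type,
                        "post_type": p.post_type,
                        "text": p.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def filter_by_keywords(
    posts: Sequence[CodedPost],
    patterns: Sequence[KeywordPattern] | None = None,
) -> list[CodedPost]:
    """Keep posts whose text matches at least one wildcard keyword.

    ``patterns`` defaults to the six clinical-trial keywords.  Original
    order is preserved; an explicitly empty pattern list is a
    configuration error.
    """
    if patterns is None:
        patterns = DEFAULT_KEYWORDS
    if not patterns:
        raise ValueError("keyword pattern list must be non-empty")
    compiled = [p.regex() for p in patterns]
    kept = [p for p in posts if any(rx.search(p.text) for rx in compiled)]
    logger.info("keyword filter: %d of %d posts kept", len(kept), len(posts))
    return kept


def deduplicate(posts: Sequence[CodedPost]) -> list[CodedPost]:
    """Drop repeated post ids, keeping the first occurrence of each."""
    seen: set[str] = set()
    kept: list[CodedPost] = []
    for p in posts:
        if p.id in seen:
            continue
        seen.add(p.id)
        kept.append(p)
    if len(kept) != len(posts):
        logger.info("deduplicate: removed %d duplicate posts", len(posts) - len(kept))
    return kept


def epoch_to_datetime(created: int) -> str:
    """Convert epoch seconds to an ISO-8601 UTC string (e.g. 1970-01-01T00:00:00Z)."""
    if created < 0:
        raise ValueError(f"epoch seconds must be non-negative, got {created}")
    dt = datetime.fromtimestamp(int(created), tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")
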