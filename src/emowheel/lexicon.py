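"""Word–emotion association lexicons in the NRC EmoLex style.

A lexicon maps lowercase words to a binary association vector over ten
categories: Plutchik's eight basic emotions (anger, anticipation, disgust,
fear, joy, sadness, surprise, trust) plus the two sentiment polarities
(negative, positive).  A word may be associated with several categories at
once — "death", for instance, carries negative sentiment together with
anger, anticipation, disgust, fear, sadness and surprise.

Matching is exact lowercase string equality: no stemming or lemmatization,
so "failure" does not match "fail".  Out-of-vocabulary words score the
all-zero vector; they are never an error.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: The ten categories in canonical tabular order (emotions first, then
#: sentiments).  All count vectors and matrices in this package use this
#: column order.
CATEGORIES: tuple[str, ...] = (
    "anger",
    "anticipation",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
    "trust",
    "negative",
    "positive",
)

#: The eight basic emotions (dyads are defined over these only).
EMOTIONS: tuple[str, ...] = CATEGORIES[:8]

#: The two sentiment polarities.
SENTIMENTS: tuple[str, ...] = CATEGORIES[8:]

_CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon files; the message names the line."""


def _normalize_word(word: str) -> str:
    """Unicode-aware lowercase, surrounding whitespace stripped."""
    return word.strip().lower()


@dataclass
class EmotionLexicon:
    """A word → 10-flag association table.

    Parameters
    ----------
    entries
        Mapping from word to its association vector.  Words are normalized
        (lowercased, stripped) on construction; vectors are validated to be
        length 10 with entries in {0, 1}.
    source_name
        Free-text provenance label carried through to run manifests.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    source_name: str = "unnamed"

    def __post_init__(self) -> None:
        normalized: dict[str, np.ndarray] = {}
        for word, vec in self.entries.items():
            arr = np.asarray(vec, dtype=np.int64)
            if arr.shape != (len(CATEGORIES),):
                raise ValueError(
                    f"association vector for {word!r} has shape {arr.shape}, "
                    f"expected ({len(CATEGORIES)},)"
                )
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"association flags for {word!r} not all in {{0,1}}")
            key = _normalize_word(word)
            if not key:
                raise ValueError("empty word in lexicon entries")
            normalized[key] = arr
        self.entries = normalized

    # -- queries ---------------------------------------------------------

    def lookup(self, word: str) -> np.ndarray:
        """Return the association vector for ``word`` (case-insensitive).

        Out-of-vocabulary words return the all-zero vector.
        """
        vec = self.entries.get(_normalize_word(word))
        if vec is None:
            return np.zeros(len(CATEGORIES), dtype=np.int64)
        return vec.copy()

    def categories_of(self, word: str) -> frozenset[str]:
        """Names of the categories flagged for ``word``."""
        vec = self.lookup(word)
        return frozenset(c for c, f in zip(CATEGORIES, vec) if f)

    def words_flagging(self, category: str) -> list[str]:
        """Sorted words whose vector flags ``category``."""
        idx = _CATEGORY_INDEX[category]
        return sorted(w for w, v in self.entries.items() if v[idx])

    def __contains__(self, word: str) -> bool:
        return _normalize_word(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> list[str]:
        return sorted(self.entries)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_flags(
        cls, flagged: Mapping[str, Iterable[str]], source_name: str = "unnamed"
    ) -> "EmotionLexicon":
        """Build a lexicon from word → flagged-category-names mappings."""
        entries: dict[str, np.ndarray] = {}
        for word, cats in flagged.items():
            vec = np.zeros(len(CATEGORIES), dtype=np.int64)
            for c in cats:
                if c not in _CATEGORY_INDEX:
                    raise ValueError(f"unknown category {c!r} for word {word!r}")
                vec[_CATEGORY_INDEX[c]] = 1
            entries[word] = vec
        return cls(entries=entries, source_name=source_name)

    # -- I/O --------------------------------------------------------------

    def write_long(self, path: str | Path) -> None:
        """Write the lexicon in NRC long format (word TAB category TAB flag).

        All ten lines are written per word so a reload round-trips exactly.
        """
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            for word in sorted(self.entries):
                vec = self.entries[word]
                for cat, flag in zip(CATEGORIES, vec):
                    fh.write(f"{word}\t{cat}\t{int(flag)}\n")


def load_lexicon(
    path: str | Path, dialect: str = "long", source_name: str | None = None
) -> EmotionLexicon:
    """Load a word–emotion lexicon from a TSV file.

    Parameters
    ----------
    path
        File to read (UTF-8).
    dialect
        ``"long"`` for NRC EmoLex triples (``word<TAB>category<TAB>flag``,
        one association per line; absent lines mean 0), or ``"wide"`` for a
        header row naming the ten categories followed by one row per word.

    Raises
    ------
    LexiconFormatError
        On a malformed line (the message names the 1-based line number), an
        unknown category name, or a flag outside {0, 1}.
    """
    path = Path(path)
    if dialect == "long":
        return _load_long(path, source_name or path.name)
    if dialect == "wide":
        return _load_wide(path, source_name or path.name)
    raise ValueError(f"unknown lexicon dialect {dialect!r} (expected 'long' or 'wide')")


def _load_long(path: Path, source_name: str) -> EmotionLexicon:
    entries: dict[str, np.ndarray] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            word, category, flag_s = parts
            word = _normalize_word(word)
            category = category.strip().lower()
            if not word:
                raise LexiconFormatError(f"{path}:{lineno}: empty word")
            if category not in _CATEGORY_INDEX:
                raise LexiconFormatError(
                    f"{path}:{lineno}: unknown category {category!r}"
                )
            if flag_s.strip() not in ("0", "1"):
                raise LexiconFormatError(
                    f"{path}:{lineno}: flag must be 0 or 1, got {flag_s!r}"
                )
            flag = int(flag_s)
            vec = entries.setdefault(word, np.zeros(len(CATEGORIES), dtype=np.int64))
            idx = _CATEGORY_INDEX[category]
            if vec[idx] != 0 and vec[idx] != flag:
                logger.warning(
                    "%s:%d: duplicate entry for (%s, %s); last flag wins",
                    path,
                    lineno,
                    word,
                    category,
                )
            vec[idx] = flag
    return EmotionLexicon(entries=entries, source_name=source_name)


def _load_wide(path: Path, source_name: str) -> EmotionLexicon:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return EmotionLexicon(entries={}, source_name=source_name)
        cats = [c.strip().lower() for c in header[1:]]
        unknown = [c for c in cats if c not in _CATEGORY_INDEX]
        if unknown:
            raise LexiconFormatError(f"{path}:1: unknown category names {unknown}")
        if sorted(cats) != sorted(CATEGORIES):
            raise LexiconFormatError(
                f"{path}:1: header must name all 10 categories exactly once"
            )
        entries: dict[str, np.ndarray] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) != len(header):
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            word = _normalize_word(row[0])
            vec = np.zeros(len(CATEGORIES), dtype=np.int64)
            for cat, flag_s in zip(cats, row[1:]):
                if flag_s.strip() not in ("0", "1"):
                    raise LexiconFormatError(
                        f"{path}:{lineno}: flag must be 0 or 1, got {flag_s!r}"
                    )
                vec[_CATEGORY_INDEX[cat]] = int(flag_s)
            if word in entries:
                logger.warning("%s:%d: duplicate word %r; last row wins", path, lineno, word)
            entries[word] = vec
    return EmotionLexicon(entries=entries, source_name=source_name)


#: Ten example words with their full NRC association vectors, used as the
#: built-in fixture lexicon (cancer-forum vocabulary: hospital, curable,
#: time, hope, pain, death, risk, promise, failure, cancer).
_FIXTURE_FLAGS: dict[str, tuple[str, ...]] = {
    "hospital": ("fear", "sadness", "trust"),
    "curable": ("positive", "trust"),
    "time": ("anticipation",),
    "hope": ("positive", "anticipation", "joy", "surprise", "trust"),
    "pain": ("negative", "fear", "sadness"),
    "death": ("negative", "anger", "anticipation", "disgust", "fear", "sadness", "surprise"),
    "risk": ("negative", "anticipation", "fear"),
    "promise": ("positive", "joy", "trust"),
    "failure": ("negative", "disgust", "fear", "sadness"),
    "cancer": ("negative", "anger", "disgust", "fear", "sadness"),
}


def fixture_lexicon() -> EmotionLexicon:
    """The built-in 10-word example lexicon.

    A small, fully specified subset of the NRC EmoLex covering typical
    cancer-forum vocabulary, embedded so the pipeline is runnable and
    testable without downloading the full lexicon.
    """
    return EmotionLexicon.from_flags(_FIXTURE_FLAGS, source_name="builtin-fixture")


def lookup(lexicon: EmotionLexicon, word: str) -> np.ndarray:
    """Functional alias for :meth:`EmotionLexicon.lookup`."""
    return lexicon.lookup(word)
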