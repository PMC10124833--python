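"""Sentence segmentation, tokenization and per-sentence emotion counting.

Each post is split into sentences; each sentence is tokenized into
lowercase bag-of-words tokens; each token is looked up in the lexicon and
contributes one count to every category its association vector flags.
The result is a sentence × category count matrix plus corpus aggregates
(total frequency N and per-sentence mean M for each category).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .ingest import CodedPost
from .lexicon import CATEGORIES, EmotionLexicon

#: Tokens before a period that do not end a sentence.
ABBREVIATIONS: frozenset[str] = frozenset(
    {"dr", "mr", "mrs", "ms", "vs", "e.g", "i.e", "etc"}
)

# Terminal punctuation run, optional closing quotes/brackets, then
# whitespace or end of text.
_TERMINATOR = re.compile(r"[.!?]+[\"'”’)\]]*(?=\s|$)")

# Unicode alphanumeric runs, underscore excluded; apostrophes and hyphens
# split words ("don't" -> don, t; "state-of-the-art" -> 4 tokens).
_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)

_LAST_WORD = re.compile(r"(\S+)$")


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of one post, with its token list."""

    post_id: str
    index: int
    text: str
    tokens: tuple[str, ...]


def tokenize(sentence: str) -> list[str]:
    """Lowercase bag-of-words tokens: split on any non-alphanumeric character."""
    return _TOKEN.findall(sentence.lower())


def split_sentences(text: str, post_id: str = "") -> list[SentenceRecord]:
    """Deterministic rule-based sentence segmentation.

    Splits on runs of terminal punctuation (``. ! ?``, optionally followed
    by closing quotes) at a whitespace boundary, unless the preceding word
    is a guarded abbreviation (dr, mr, mrs, ms, vs, e.g, i.e, etc).
    Empty segments are dropped.
    """
    sentences: list[SentenceRecord] = []
    start = 0
    index = 0

    def emit(segment: str) -> None:
        nonlocal index
        segment = segment.strip()
        if not segment:
            return
        sentences.append(
            SentenceRecord(
                post_id=post_id,
                index=index,
                text=segment,
                tokens=tuple(tokenize(segment)),
            )
        )
        index += 1

    for m in _TERMINATOR.finditer(text):
        preceding = _LAST_WORD.search(text[: m.start()])
        if preceding is not None:
            word = preceding.group(1).lower().lstrip("\"'“‘([")
            if word in ABBREVIATIONS:
                continue
        emit(text[start : m.end()])
        start = m.end()
    emit(text[start:])
    return sentences


def score_sentence(tokens: Sequence[str], lexicon: EmotionLexicon) -> np.ndarray:
    """Count, per category, the tokens whose lexicon vector flags it.

    Token-based: a word occurring twice counts twice.  A multi-category
    word contributes to every category it flags; out-of-vocabulary tokens
    contribute nothing.
    """
    counts = np.zeros(len(CATEGORIES), dtype=np.int64)
    for tok in tokens:
        counts += lexicon.lookup(tok)
    return counts


@dataclass
class SentenceEmotionMatrix:
    """Per-sentence count table over the ten categories.

    ``frame`` has columns ``post_id``, ``sentence_index``, ``sentence``,
    ``n_tokens`` and the ten category columns in canonical order, one row
    per sentence (ordered by post, then sentence index).
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["post_id", "sentence_index", "sentence", "n_tokens", *CATEGORIES]
        )
    )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[SentenceRecord, np.ndarray]],
    ) -> "SentenceEmotionMatrix":
        rows = []
        for rec, counts in records:
            row = {
                "post_id": rec.post_id,
                "sentence_index": rec.index,
                "sentence": rec.text,
                "n_tokens": len(rec.tokens),
            }
            row.update({c: int(v) for c, v in zip(CATEGORIES, counts)})
            rows.append(row)
        if not rows:
            return cls()
        return cls(frame=pd.DataFrame(rows))

    @property
    def n_sentences(self) -> int:
        return len(self.frame)

    @property
    def n_words(self) -> int:
        return int(self.frame["n_tokens"].sum()) if len(self.frame) else 0

    def counts(self) -> np.ndarray:
        """The raw sentence × category count array (n_sentences, 10)."""
        if not len(self.frame):
            return np.zeros((0, len(CATEGORIES)), dtype=np.int64)
        return self.frame[list(CATEGORIES)].to_numpy(dtype=np.int64)

    def column_totals(self) -> dict[str, int]:
        totals = self.counts().sum(axis=0)
        return {c: int(t) for c, t in zip(CATEGORIES, totals)}

    def to_csv(self, path) -> None:
        """Write ``sentence_scores.csv`` (no n_tokens column in the report)."""
        cols = ["post_id", "sentence_index", "sentence", *CATEGORIES]
        self.frame[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class CorpusEmotionSummary:
    """Corpus aggregates: total frequency N and mean per sentence M."""

    N: dict[str, int]
    M: dict[str, float]
    n_sentences: int
    n_words: int

    def to_json_dict(self) -> dict:
        return {
            "N": dict(self.N),
            "M": {c: round_half_up(m, 2) for c, m in self.M.items()},
            "n_sentences": self.n_sentences,
            "n_words": self.n_words,
        }


def score_corpus(
    posts: Sequence[CodedPost], lexicon: EmotionLexicon
) -> SentenceEmotionMatrix:
    """Score every sentence of every post; one matrix row per sentence."""
    records: list[tuple[SentenceRecord, np.ndarray]] = []
    for post in posts:
        for rec in split_sentences(post.text, post_id=post.id):
            records.append((rec, score_sentence(rec.tokens, lexicon)))
    return SentenceEmotionMatrix.from_records(records)


def aggregate(matrix: SentenceEmotionMatrix) -> CorpusEmotionSummary:
    """Column totals N and per-sentence means M = N / n_sentences.

    Raises ``ValueError`` on an empty matrix (M is undefined).
    """
    if matrix.n_sentences == 0:
        raise ValueError("cannot aggregate an empty sentence matrix: M undefined")
    totals = matrix.column_totals()
    n = matrix.n_sentences
    return CorpusEmotionSummary(
        N=totals,
        M={c: totals[c] / n for c in CATEGORIES},
        n_sentences=n,
        n_words=matrix.n_words,
    )
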