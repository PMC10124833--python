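"""Synthetic corpora with planted emotion structure and exact ground truth.

The generator emulates the shape of a keyword-filtered cancer-forum corpus:
a few hundred posts of a handful to a couple dozen sentences, timestamps
spaning mid-2011 to late 2021, user/post-type codes drawn from realistic
marginal frequencies, and sentences that mix lexicon words (sampled by a
per-category emotion mixture) with out-of-vocabulary filler words.

Ground truth is defined from the *planted words' full lexicon vectors*,
not from the sampling intent: a multi-emotion word like "death" counts
toward every category it flags, so the truth matrix is exactly what an
exact-match scorer must reproduce.  Fillers are screened against the
lexicon, guaranteeing zero contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ingest import POST_TYPES, USER_TYPES, CodedPost, write_posts
from .lexicon import CATEGORIES, EmotionLexicon
from .scoring import ABBREVIATIONS, SentenceEmotionMatrix, SentenceRecord, tokenize

#: Corpus time span emulated by the generator: July 2011 – November 2021.
EPOCH_RANGE: tuple[int, int] = (1309478400, 1638316800)

#: Default per-category sampling weights, proportional to the relative
#: prevalence observed in cancer clinical-trial forum discussions
#: (positive and fear-heavy, surprise rare).
DEFAULT_EMOTION_MIXTURE: dict[str, float] = {
    "positive": 2557.0,
    "negative": 2154.0,
    "fear": 1702.0,
    "sadness": 1494.0,
    "trust": 1470.0,
    "anticipation": 1376.0,
    "anger": 1095.0,
    "joy": 946.0,
    "disgust": 925.0,
    "surprise": 615.0,
}

DEFAULT_USER_TYPE_PROBS: dict[str, float] = {
    "patient": 0.383,
    "caregiver": 0.332,
    "hc": 0.021,
    "unknown": 0.264,
}

DEFAULT_POST_TYPE_PROBS: dict[str, float] = {
    "advice": 0.227,
    "experience": 0.419,
    "both": 0.251,
    "unknown": 0.103,
}

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    Defaults emulate the target study conditions: 337 posts, roughly
    3–20 sentences per post and 8–25 words per sentence (≈ 60k tokens in
    total), 70% out-of-vocabulary filler, emotion mixture and user/post
    type marginals as observed in the field.
    """

    n_posts: int = 337
    sentences_per_post: tuple[int, int] = (3, 20)
    words_per_sentence: tuple[int, int] = (8, 25)
    emotion_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_MIXTURE)
    )
    oov_fraction: float = 0.7
    user_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_USER_TYPE_PROBS)
    )
    post_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POST_TYPE_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts < 0:
            raise ConfigurationError("n_posts must be non-negative")
        for name, (lo, hi) in (
            ("sentences_per_post", self.sentences_per_post),
            ("words_per_sentence", self.words_per_sentence),
        ):
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or below 1")
        if not 0.0 <= self.oov_fraction < 1.0:
            raise ConfigurationError("oov_fraction must lie in [0, 1)")
        if any(w < 0 for w in self.emotion_mixture.values()):
            raise ConfigurationError("emotion mixture weights must be non-negative")
        unknown = set(self.emotion_mixture) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown mixture categories: {sorted(unknown)}")
        if sum(self.emotion_mixture.values()) <= 0:
            raise ConfigurationError("emotion mixture must have positive total weight")
        for name, probs, vocab in (
            ("user_type_probs", self.user_type_probs, USER_TYPES),
            ("post_type_probs", self.post_type_probs, POST_TYPES),
        ):
            if set(probs) - set(vocab):
                raise ConfigurationError(f"{name} has labels outside {vocab}")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} must sum to 1")


@dataclass
class SyntheticCorpusBundle:
    """Generated posts plus the exact planted truth matrix."""

    posts: list[CodedPost]
    truth_matrix: SentenceEmotionMatrix

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        posts_path = out_dir / "posts.jsonl"
        truth_path = out_dir / "truth.csv"
        write_posts(self.posts, posts_path)
        self.truth_matrix.frame.to_csv(truth_path, index=False)
        return {"posts": posts_path, "truth": truth_path}


def _categorical(rng: np.random.Generator, items: list, weights: list[float]):
    cum = np.cumsum(weights, dtype=float)
    cum /= cum[-1]
    return items[int(np.searchsorted(cum, rng.random(), side="right"))]


def _eligible_words(lexicon: EmotionLexicon) -> dict[str, list[str]]:
    """Per category, lexicon words safe to plant.

    A word is safe when it survives tokenization unchanged (single
    alphanumeric token) and is not an abbreviation-guard token, so that
    scoring the generated text recovers the planted counts exactly.
    """
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for word in lexicon.words:
        if word in ABBREVIATIONS or tokenize(word) != [word]:
            continue
        vec = lexicon.lookup(word)
        for c, flag in zip(CATEGORIES, vec):
            if flag:
                by_cat[c].append(word)
    return by_cat


def _make_filler(rng: np.random.Generator, lexicon: EmotionLexicon) -> str:
    while True:
        n_syll = int(rng.integers(2, 5))
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syll)
        )
        if word not in lexicon and word not in ABBREVIATIONS:
            return word


def _render_sentence(words: Sequence[str]) -> str:
    text = " ".join(words)
    return (text[0].upper() + text[1:] + ".") if text else ""


def generate_corpus(
    config: GeneratorConfig, lexicon: EmotionLexicon
) -> SyntheticCorpusBundle:
    """Generate a corpus with planted, exactly known emotion counts.

    Each word slot is independently an out-of-vocabulary filler (with
    probability ``oov_fraction``) or a lexicon word drawn by first sampling
    a category from the emotion mixture, then a word uniformly among the
    words flagging it.  The truth row for a sentence is the sum of the
    planted lexicon words' full association vectors.

    Raises :class:`ConfigurationError` if a category with positive mixture
    weight has no plantable lexicon word.
    """
    if len(lexicon) == 0:
        raise ConfigurationError("lexicon must be non-empty")
    by_cat = _eligible_words(lexicon)
    active = [(c, w) for c, w in config.emotion_mixture.items() if w > 0]
    unreachable = [c for c, _ in active if not by_cat[c]]
    if unreachable:
        raise ConfigurationError(
            f"no plantable lexicon word for requested categories: {unreachable}"
        )
    cats = [c for c, _ in active]
    weights = [w for _, w in active]

    rng = np.random.default_rng(config.seed)
    posts: list[CodedPost] = []
    records: list[tuple[SentenceRecord, np.ndarray]] = []
    user_items = sorted(config.user_type_probs)
    post_items = sorted(config.post_type_probs)

    for i in range(config.n_posts):
        post_id = f"syn{i:05d}"
        n_sent = int(rng.integers(config.sentences_per_post[0], config.sentences_per_post[1] + 1))
        sentences: list[str] = []
        for j in range(n_sent):
            n_words = int(
                rng.integers(config.words_per_sentence[0], config.words_per_sentence[1] + 1)
            )
            words: list[str] = []
            vec = np.zeros(len(CATEGORIES), dtype=np.int64)
            for _ in range(n_words):
                if rng.random() < config.oov_fraction:
                    words.append(_make_filler(rng, lexicon))
                else:
                    cat = _categorical(rng, cats, weights)
                    pool = by_cat[cat]
                    word = pool[int(rng.integers(len(pool)))]
                    words.append(word)
                    vec += lexicon.lookup(word)
            sentence = _render_sentence(words)
            sentences.append(sentence)
            records.append(
                (
                    SentenceRecord(
                        post_id=post_id, index=j, text=sentence, tokens=tuple(words)
                    ),
                    vec,
                )
            )
        posts.append(
            CodedPost(
                id=post_id,
                created=int(rng.integers(EPOCH_RANGE[0], EPOCH_RANGE[1])),
                user_type=_categorical(
                    rng, user_items, [config.user_type_probs[k] for k in user_items]
                ),
                post_type=_categorical(
                    rng, post_items, [config.post_type_probs[k] for k in post_items]
                ),
                text=" ".join(sentences),
            )
        )
    return SyntheticCorpusBundle(
        posts=posts, truth_matrix=SentenceEmotionMatrix.from_records(records)
    )


class DeficitError(ValueError):
    """A planted-scenario request cannot be met; lists the deficit."""

    def __init__(self, deficits: Mapping[str, int]):
        self.deficits = dict(deficits)
        super().__init__(
            "cannot realize requested counts with the available vocabulary; "
            f"deficits: {self.deficits}"
        )


def plant_dyad_scenario(
    spec: Sequence[Mapping[str, int]], lexicon: EmotionLexicon
) -> SyntheticCorpusBundle:
    """Build a corpus whose sentences realize requested category counts.

    ``spec`` is one mapping (category → desired count) per sentence.  Words
    are chosen greedily, preferring words whose vector fits entirely inside
    the remaining demand; when no word fits exactly, a word covering part
    of the demand is planted and the recorded truth reflects the *actual*
    planted vectors (which may then exceed the request in some category).

    Raises :class:`DeficitError` when no lexicon word flags any remaining
    requested category.
    """
    vocab = [w for w in lexicon.words if tokenize(w) == [w] and w not in ABBREVIATIONS]
    vecs = {w: lexicon.lookup(w) for w in vocab}
    filler_rng = np.random.default_rng(0)

    records: list[tuple[SentenceRecord, np.ndarray]] = []
    sentences: list[str] = []
    for j, wanted in enumerate(spec):
        unknown = set(wanted) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in scenario: {sorted(unknown)}")
        remaining = np.zeros(len(CATEGORIES), dtype=np.int64)
        for c, k in wanted.items():
            if k < 0:
                raise ConfigurationError("requested counts must be non-negative")
            remaining[CATEGORIES.index(c)] = k
        words: list[str] = []
        vec = np.zeros(len(CATEGORIES), dtype=np.int64)
        while remaining.sum() > 0:
            fits = [
                w for w in vocab if vecs[w].sum() > 0 and bool(np.all(vecs[w] <= remaining))
            ]
            if fits:
                word = sorted(fits, key=lambda w: (-int(vecs[w].sum()), w))[0]
            else:
                partial = [
                    w for w in vocab if int(np.minimum(vecs[w], remaining).sum()) > 0
                ]
                if not partial:
                    deficits = {
                        c: int(r) for c, r in zip(CATEGORIES, remaining) if r > 0
                    }
                    raise DeficitError(deficits)
                word = sorted(
                    partial,
                    key=lambda w: (
                        -int(np.minimum(vecs[w], remaining).sum()),
                        int(np.clip(vecs[w] - remaining, 0, None).sum()),
                        w,
                    ),
                )[0]
            words.append(word)
            vec += vecs[word]
            remaining = np.clip(remaining - vecs[word], 0, None)
        if not words:
            words.append(_make_filler(filler_rng, lexicon))
        sentence = _render_sentence(words)
        sentences.append(sentence)
        records.append(
            (
                SentenceRecord(post_id="scenario", index=j, text=sentence, tokens=tuple(words)),
                vec,
            )
        )

    posts = (
        [
            CodedPost(
                id="scenario",
                created=EPOCH_RANGE[0],
                user_type="patient",
                post_type="experience",
                text=" ".join(sentences),
            )
        ]
        if sentences
        else []
    )
    return SyntheticCorpusBundle(
        posts=posts, truth_matrix=SentenceEmotionMatrix.from_records(records)
    )
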