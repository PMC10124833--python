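"""Plutchik dyads: the 28-pair registry and the co-occurrence statistic.

Each unordered pair of the eight basic emotions names a complex emotion
(a *dyad*).  Pairs of emotions adjacent on Plutchik's wheel form primary
dyads, pairs two steps apart secondary, three steps apart tertiary, and
diametrically opposed pairs the four opposites — 8 + 8 + 8 + 4 = C(8,2) = 28
dyads in total.  The sentiment polarities are not part of the wheel and are
excluded from dyad computation.

The co-occurrence statistic: within a sentence, a dyad's score is the
minimum of its two constituent emotion counts (sadness 2 and joy 3 in one
sentence give bittersweetness 2).  Corpus frequency is the sum of this
per-sentence score over all sentences.  For display, each dyad class (and
the basic-emotion wheel itself) is normalized by its class maximum so the
most frequent member scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .lexicon import CATEGORIES, EMOTIONS
from .scoring import CorpusEmotionSummary, SentenceEmotionMatrix

DYAD_CLASSES: tuple[str, ...] = ("primary", "secondary", "tertiary", "opposite")

#: Accepted alternative spellings → canonical dyad names.
NAME_ALIASES: dict[str, str] = {
    "cynism": "cynicism",
    "morbideness": "morbidness",
    "bitter sweetness": "bittersweetness",
}


@dataclass(frozen=True)
class DyadDefinition:
    """A named complex emotion formed by two basic emotions."""

    name: str
    dyad_class: str
    emotion_1: str
    emotion_2: str

    def __post_init__(self) -> None:
        if self.dyad_class not in DYAD_CLASSES:
            raise ValueError(f"unknown dyad class {self.dyad_class!r}")
        for e in (self.emotion_1, self.emotion_2):
            if e not in EMOTIONS:
                raise ValueError(f"{e!r} is not a basic emotion")
        if self.emotion_1 == self.emotion_2:
            raise ValueError("a dyad combines two distinct emotions")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.emotion_1, self.emotion_2))


def _d(name: str, dyad_class: str, e1: str, e2: str) -> DyadDefinition:
    return DyadDefinition(name=name, dyad_class=dyad_class, emotion_1=e1, emotion_2=e2)


#: The full registry in canonical report order (class blocks, most frequent
#: wheel convention ordering within each block).
DYAD_REGISTRY: tuple[DyadDefinition, ...] = (
    # primary dyads: adjacent emotions on the wheel
    _d("remorse", "primary", "disgust", "sadness"),
    _d("contempt", "primary", "anger", "disgust"),
    _d("optimism", "primary", "anticipation", "joy"),
    _d("submission", "primary", "trust", "fear"),
    _d("aggressiveness", "primary", "anger", "anticipation"),
    _d("love", "primary", "joy", "trust"),
    _d("alarm", "primary", "fear", "surprise"),
    _d("disappointment", "primary", "sadness", "surprise"),
    # secondary dyads: two wheel positions apart
    _d("envy", "secondary", "anger", "sadness"),
    _d("despair", "secondary", "sadness", "fear"),
    _d("hope", "secondary", "anticipation", "trust"),
    _d("curiosity", "secondary", "trust", "surprise"),
    _d("guilt", "secondary", "joy", "fear"),
    _d("cynicism", "secondary", "disgust", "anticipation"),
    _d("pride", "secondary", "anger", "joy"),
    _d("unbelief", "secondary", "surprise", "disgust"),
    # tertiary dyads: three wheel positions apart
    _d("outrage", "tertiary", "anger", "surprise"),
    _d("shame", "tertiary", "disgust", "fear"),
    _d("anxiety", "tertiary", "anticipation", "fear"),
    _d("sentimentality", "tertiary", "sadness", "trust"),
    _d("pessimism", "tertiary", "anticipation", "sadness"),
    _d("delight", "tertiary", "joy", "surprise"),
    _d("dominance", "tertiary", "anger", "trust"),
    _d("morbidness", "tertiary", "disgust", "joy"),
    # opposite dyads: diametric pairs
    _d("frozenness", "opposite", "fear", "anger"),
    _d("confusion", "opposite", "anticipation", "surprise"),
    _d("ambivalence", "opposite", "trust", "disgust"),
    _d("bittersweetness", "opposite", "joy", "sadness"),
)


def dyad_registry() -> list[DyadDefinition]:
    """The fixed 28-entry dyad registry, in report order."""
    return list(DYAD_REGISTRY)


def get_dyad(name: str) -> DyadDefinition:
    """Look a dyad up by canonical name or accepted alias."""
    key = NAME_ALIASES.get(name.strip().lower(), name.strip().lower())
    for d in DYAD_REGISTRY:
        if d.name == key:
            return d
    raise KeyError(f"unknown dyad name {name!r}")


def _counts_for(counts, category: str) -> int:
    if isinstance(counts, Mapping):
        return int(counts.get(category, 0))
    seq = np.asarray(counts)
    return int(seq[CATEGORIES.index(category)])


def sentence_dyad_score(counts, dyad: DyadDefinition) -> int:
    """Per-sentence co-occurrence: min of the dyad's two emotion counts.

    ``counts`` is either a mapping category → count or a length-10 vector
    in canonical category order.
    """
    return min(_counts_for(counts, dyad.emotion_1), _counts_for(counts, dyad.emotion_2))


def corpus_dyad_scores(matrix: SentenceEmotionMatrix) -> pd.DataFrame:
    """Sum the per-sentence min-rule score over all sentences, per dyad.

    Returns the dyad table (``dyad_class``, ``name``, ``emotion_1``,
    ``emotion_2``, ``frequency``) in registry order, ratios not yet filled.
    """
    counts = matrix.counts()
    col = {e: CATEGORIES.index(e) for e in EMOTIONS}
    rows = []
    for d in DYAD_REGISTRY:
        if len(counts):
            freq = int(
                np.minimum(counts[:, col[d.emotion_1]], counts[:, col[d.emotion_2]]).sum()
            )
        else:
            freq = 0
        rows.append(
            {
                "dyad_class": d.dyad_class,
                "name": d.name,
                "emotion_1": d.emotion_1,
                "emotion_2": d.emotion_2,
                "frequency": freq,
            }
        )
    return pd.DataFrame(rows)


def normalize_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``ratio`` column: frequency / max frequency within the class.

    Within each dyad class the most frequent dyad gets ratio exactly 1; a
    class whose maximum is 0 gets all-zero ratios.  Ratios are exact
    doubles; report writers round to 2 decimals.
    """
    out = table.reset_index(drop=True).copy()
    ratios = np.zeros(len(out), dtype=float)
    for cls, block in out.groupby("dyad_class", sort=False):
        m = block["frequency"].max()
        if m > 0:
            ratios[block.index] = block["frequency"] / m
    out["ratio"] = ratios
    return out


def basic_emotion_ratios(summary: CorpusEmotionSummary) -> dict[str, float]:
    """Normalize the eight basic-emotion totals by their maximum.

    Sentiments are excluded: the wheel is drawn over basic emotions only.
    A corpus with no emotion hits at all gets all-zero ratios.
    """
    totals = {e: summary.N[e] for e in EMOTIONS}
    m = max(totals.values())
    if m == 0:
        return {e: 0.0 for e in EMOTIONS}
    return {e: totals[e] / m for e in EMOTIONS}


def dyad_table_for_report(table: pd.DataFrame) -> pd.DataFrame:
    """Copy of the dyad table with 2-decimal half-up rounded ratios."""
    out = table.copy()
    out["ratio"] = [round_half_up(r, 2) for r in out["ratio"]]
    return out
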