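"""Shared fixtures: lexicons, tiny corpora, and the printed dyad table."""

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emowheel import CodedPost, EmotionLexicon, fixture_lexicon

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon() -> EmotionLexicon:
    """The built-in 10-word example lexicon."""
    return fixture_lexicon()


@pytest.fixture(scope="session")
def mono_lexicon() -> EmotionLexicon:
    """A lexicon with exactly one single-category word per category."""
    return EmotionLexicon.from_flags(
        {
            "rage": ["anger"],
            "await": ["anticipation"],
            "yuck": ["disgust"],
            "dread": ["fear"],
            "glee": ["joy"],
            "gloom": ["sadness"],
            "gasp": ["surprise"],
            "rely": ["trust"],
            "bad": ["negative"],
            "good": ["positive"],
        },
        source_name="mono",
    )


def make_post(pid: str, text: str, user_type: str = "patient",
              post_type: str = "experience", created: int = 1400000000) -> CodedPost:
    return CodedPost(id=pid, created=created, user_type=user_type,
                     post_type=post_type, text=text)


@pytest.fixture()
def small_corpus() -> list[CodedPost]:
    return [
        make_post("p1", "There is hope. The pain was real."),
        make_post("p2", "Death and cancer. A promise of time.", user_type="caregiver"),
    ]


#: The published co-occurrence frequencies for all 28 dyads, frozen as the
#: input for ratio-normalization checks.
PUBLISHED_DYAD_FREQUENCIES: dict[str, tuple[str, int]] = {
    "remorse": ("primary", 813),
    "contempt": ("primary", 778),
    "optimism": ("primary", 719),
    "submission": ("primary", 626),
    "aggressiveness": ("primary", 370),
    "love": ("primary", 279),
    "alarm": ("primary", 276),
    "disappointment": ("primary", 254),
    "envy": ("secondary", 1322),
    "despair": ("secondary", 1225),
    "hope": ("secondary", 802),
    "curiosity": ("secondary", 408),
    "guilt": ("secondary", 356),
    "cynicism": ("secondary", 325),
    "pride": ("secondary", 275),
    "unbelief": ("secondary", 207),
    "outrage": ("tertiary", 1375),
    "shame": ("tertiary", 796),
    "anxiety": ("tertiary", 568),
    "sentimentality": ("tertiary", 553),
    "pessimism": ("tertiary", 485),
    "delight": ("tertiary", 462),
    "dominance": ("tertiary", 417),
    "morbidness": ("tertiary", 244),
    "frozenness": ("opposite", 944),
    "confusion": ("opposite", 482),
    "ambivalence": ("opposite", 369),
    "bittersweetness": ("opposite", 344),
}


@pytest.fixture(scope="session")
def published_dyad_table() -> pd.DataFrame:
    rows = [
        {"dyad_class": cls, "name": name, "frequency": freq}
        for name, (cls, freq) in PUBLISHED_DYAD_FREQUENCIES.items()
    ]
    return pd.DataFrame(rows)
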