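"""Radial Plutchik-wheel rendering.

Five wheels are drawn per run: the basic-emotion wheel (8 petals in the
canonical Plutchik arrangement, joy at the top, proceeding clockwise) and
one wheel per dyad class (8 petals for primary/secondary/tertiary, 4 for
opposites).  Petal length is the ratio-normalized score in [0, 1]; the
class maximum therefore always reaches the unit ring.  Raw frequencies are
never drawn — they live in the CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._util import round_half_up
from .dyads import DYAD_CLASSES, DYAD_REGISTRY

#: Canonical angular order of the basic wheel, clockwise from the top.
BASIC_WHEEL_ORDER: tuple[str, ...] = (
    "joy",
    "trust",
    "fear",
    "surprise",
    "sadness",
    "disgust",
    "anger",
    "anticipation",
)

WHEEL_KINDS: tuple[str, ...] = ("basic", *DYAD_CLASSES)

_PETAL_COLORS = {
    "basic": "#f2a900",
    "primary": "#7b4ea3",
    "secondary": "#2a7fb8",
    "tertiary": "#3a9d5d",
    "opposite": "#c23b4b",
}


@dataclass(frozen=True)
class WheelSpec:
    """One wheel: its kind and the ordered petal scores in [0, 1]."""

    kind: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in WHEEL_KINDS:
            raise ValueError(f"unknown wheel kind {self.kind!r}")
        expected = petal_order(self.kind)
        if tuple(self.scores) != expected:
            raise ValueError(
                f"{self.kind} wheel must score petals {expected} in order, "
                f"got {tuple(self.scores)}"
            )
        for name, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score for {name!r} outside [0, 1]: {s}")


def petal_order(kind: str) -> tuple[str, ...]:
    """Fixed angular petal order for a wheel kind."""
    if kind == "basic":
        return BASIC_WHEEL_ORDER
    return tuple(d.name for d in DYAD_REGISTRY if d.dyad_class == kind)


def make_wheel_specs(
    basic_ratios: dict[str, float], dyad_table: pd.DataFrame
) -> dict[str, WheelSpec]:
    """Assemble the five wheel specs from ratio tables."""
    specs = {
        "basic": WheelSpec(
            kind="basic", scores={e: basic_ratios[e] for e in BASIC_WHEEL_ORDER}
        )
    }
    by_name = dict(zip(dyad_table["name"], dyad_table["ratio"]))
    for cls in DYAD_CLASSES:
        specs[cls] = WheelSpec(
            kind=cls, scores={n: float(by_name[n]) for n in petal_order(cls)}
        )
    return specs


def render_wheel(spec: WheelSpec, path: str | Path, title: str | None = None) -> Path:
    """Render one wheel as a radial petal chart (SVG or PNG by extension)."""
    path = Path(path)
    names = list(spec.scores)
    values = np.array([spec.scores[n] for n in names], dtype=float)
    n = len(names)
    # clockwise from the top
    theta = np.pi / 2 - np.arange(n) * 2 * np.pi / n
    width = 0.82 * 2 * np.pi / n

    fig = plt.figure(figsize=(5.2, 5.2))
    ax = fig.add_subplot(111, projection="polar")
    ax.bar(
        theta,
        values,
        width=width,
        bottom=0.0,
        color=_PETAL_COLORS[spec.kind],
        alpha=0.75,
        edgecolor="black",
        linewidth=0.6,
    )
    ring = np.linspace(0, 2 * np.pi, 200)
    ax.plot(ring, np.ones_like(ring), color="0.55", linewidth=0.8, linestyle=":")
    for ang, name, val in zip(theta, names, values):
        ax.text(ang, 1.32, name, ha="center", va="center", fontsize=8)
        ax.text(ang, 1.16, f"{round_half_up(val, 2):.2f}", ha="center", va="center", fontsize=7)
    ax.set_ylim(0, 1.45)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.spines["polar"].set_visible(False)
    ax.set_title(title or f"{spec.kind} wheel", fontsize=11, pad=14)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
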