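"""Inter-rater reliability and coding-scheme bookkeeping.

Two independent coders label every post's user type (patient, caregiver,
healthcare professional, unknown) and post type (advice, experience, both,
unknown).  Agreement is summarized with unweighted Cohen's kappa over all
categories — "unknown" is a label, not missing data — and interpreted with
the conventional bands from "no agreement" (≤ 0) up to "almost perfect
agreement" (0.81–1.00).  Disagreements are a human adjudication step; this
module reports, it does not auto-resolve.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .ingest import POST_TYPES, USER_TYPES, CodedPost


@dataclass
class CodingSheet:
    """One coder's labels: post id → label, from a closed vocabulary."""

    coder: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        vocab = set(USER_TYPES) | set(POST_TYPES)
        bad = {v for v in self.labels.values() if v not in vocab}
        if bad:
            raise ValueError(f"labels outside the coding vocabulary: {sorted(bad)}")


def read_coding_sheet(path: str | Path, coder: str | None = None) -> CodingSheet:
    """Read a coder's CSV sheet with columns ``post_id,label``."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("post_id") or "").strip()
            label = (row.get("label") or "").strip().lower()
            if not pid or not label:
                raise ValueError(f"{path}:{lineno}: missing post_id or label")
            if pid in labels:
                raise ValueError(f"{path}:{lineno}: post {pid!r} labeled twice")
            labels[pid] = label
    return CodingSheet(coder=coder or path.stem, labels=labels)


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its ingredients and interpretation band."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    band: str
    n_items: int

    def to_json_dict(self) -> dict:
        return {
            "kappa": round_half_up(self.kappa, 2),
            "observed_agreement": round_half_up(self.observed_agreement, 4),
            "expected_agreement": round_half_up(self.expected_agreement, 4),
            "band": self.band,
            "n_items": self.n_items,
        }


def kappa_band(kappa: float) -> str:
    """Interpretation band for a kappa value.

    ≤ 0 no agreement; 0.01–0.20 slight; 0.21–0.40 fair; 0.41–0.60
    moderate; 0.61–0.80 substantial; 0.81–1.00 almost perfect.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa <= 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight agreement"
    if kappa <= 0.40:
        return "fair agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "almost perfect agreement"


def cohen_kappa(a: CodingSheet, b: CodingSheet) -> AgreementResult:
    """Unweighted two-rater Cohen's kappa over the shared post ids.

    kappa = (po − pe) / (1 − pe), with po the observed proportion of
    agreement and pe the agreement expected by chance from the two raters'
    marginal label distributions.

    Raises ``ValueError`` if the sheets share fewer than 2 ids or if
    pe = 1 (kappa undefined).
    """
    shared = sorted(set(a.labels) & set(b.labels))
    if not shared:
        raise ValueError("coding sheets have disjoint id sets")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared items for kappa")
    n = len(shared)
    la = [a.labels[i] for i in shared]
    lb = [b.labels[i] for i in shared]
    po = sum(x == y for x, y in zip(la, lb)) / n
    ca, cb = Counter(la), Counter(lb)
    pe = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if pe == 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    kappa = (po - pe) / (1 - pe)
    return AgreementResult(
        kappa=kappa,
        observed_agreement=po,
        expected_agreement=pe,
        band=kappa_band(kappa),
        n_items=n,
    )


def frequency_table(posts: Sequence[CodedPost], field: str) -> pd.DataFrame:
    """Counts and percentages per code for ``user_type`` or ``post_type``.

    User-type percentages use the corpus size as denominator; post-type
    percentages use the sum of assigned labels.  Percentages are rounded
    half-up to one decimal.
    """
    if field == "user_type":
        codes = USER_TYPES
        values = [p.user_type for p in posts]
        denom = len(posts)
    elif field == "post_type":
        codes = POST_TYPES
        values = [p.post_type for p in posts]
        denom = len(values)
    else:
        raise ValueError(f"field must be 'user_type' or 'post_type', got {field!r}")
    counts = Counter(values)
    rows = []
    for code in codes:
        c = counts.get(code, 0)
        pct = round_half_up(100.0 * c / denom, 1) if denom else 0.0
        rows.append({"code": code, "count": c, "percentage": pct})
    return pd.DataFrame(rows)


def inclusion_filter(posts: Sequence[CodedPost]) -> list[CodedPost]:
    """Keep only posts authored by patients or caregivers.

    Posts from healthcare professionals or with unknown user type are
    excluded from the emotion analysis.
    """
    return [p for p in posts if p.user_type in ("patient", "caregiver")]
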