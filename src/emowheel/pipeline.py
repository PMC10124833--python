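"""End-to-end orchestration: ingest → filter → score → dyads → wheels.

``run_pipeline`` executes the full analysis on one corpus and writes every
tabular and graphical artifact plus a run manifest.  Every figure's
underlying numbers are also emitted as CSV; nothing is figure-only.  Stage
logging records counts in and out so exclusion bookkeeping is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import round_half_up
from .dyads import basic_emotion_ratios, corpus_dyad_scores, dyad_table_for_report, normalize_ratios
from .ingest import (
    DEFAULT_KEYWORDS,
    CodedPost,
    KeywordPattern,
    deduplicate,
    filter_by_keywords,
    read_posts,
)
from .lexicon import fixture_lexicon, load_lexicon
from .reliability import cohen_kappa, frequency_table, read_coding_sheet
from .scoring import aggregate, score_corpus
from .viz import make_wheel_specs, render_wheel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it and partial outputs are removed."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    posts_path: str
    out_dir: str
    lexicon: str = "builtin"  # "builtin" or a file path
    lexicon_dialect: str = "long"
    keywords: str | None = "builtin"  # "builtin", None (skip), or a file path
    apply_inclusion: bool = True
    coding_sheets: dict[str, tuple[str, str]] = field(default_factory=dict)
    strata: bool = True
    figure_format: str = "svg"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "coding_sheets" in raw:
            raw["coding_sheets"] = {
                k: tuple(v) for k, v in raw["coding_sheets"].items()
            }
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_keywords(spec: str | None) -> list[KeywordPattern] | None:
    if spec is None or spec == "none":
        return None
    if spec == "builtin":
        return list(DEFAULT_KEYWORDS)
    patterns = []
    with open(spec, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                patterns.append(KeywordPattern(line))
    return patterns


def _summarize(posts: list[CodedPost], lexicon) -> tuple[dict, pd.DataFrame]:
    matrix = score_corpus(posts, lexicon)
    if matrix.n_sentences == 0:
        return {"n_sentences": 0, "n_words": 0, "N": {}, "M": {}}, matrix.frame
    return aggregate(matrix).to_json_dict(), matrix.frame


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; return the artifact paths.

    Stages: ingest → keyword filter (optional) → deduplicate → inclusion
    filter (optional) → sentence scoring → aggregation → dyad scoring →
    ratio normalization → five wheels.  Any stage error raises
    :class:`PipelineError` naming the stage, and partial outputs written by
    this run are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_log: list[dict] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    current_stage = "setup"
    try:
        # --- lexicon -----------------------------------------------------
        current_stage = "lexicon"
        if config.lexicon == "builtin":
            lexicon = fixture_lexicon()
        else:
            lexicon = load_lexicon(config.lexicon, dialect=config.lexicon_dialect)

        # --- ingest ------------------------------------------------------
        current_stage = "ingest"
        posts = read_posts(config.posts_path)
        if not posts:
            raise ValueError(f"no posts read from {config.posts_path}")
        stage_log.append({"stage": "ingest", "n_in": None, "n_out": len(posts)})

        # --- keyword filter ----------------------------------------------
        patterns = _load_keywords(config.keywords)
        if patterns is not None:
            current_stage = "keyword_filter"
            n_in = len(posts)
            posts = filter_by_keywords(posts, patterns)
            stage_log.append({"stage": "keyword_filter", "n_in": n_in, "n_out": len(posts)})

        # --- deduplicate -------------------------------------------------
        current_stage = "deduplicate"
        n_in = len(posts)
        posts = deduplicate(posts)
        stage_log.append({"stage": "deduplicate", "n_in": n_in, "n_out": len(posts)})

        # --- coding summary (frequencies on the full deduplicated corpus)
        current_stage = "coding_summary"
        coding: dict = {
            "user_type": frequency_table(posts, "user_type").to_dict(orient="records"),
            "post_type": frequency_table(posts, "post_type").to_dict(orient="records"),
        }
        for fld, (path_a, path_b) in config.coding_sheets.items():
            result = cohen_kappa(read_coding_sheet(path_a), read_coding_sheet(path_b))
            coding[f"kappa_{fld}"] = result.to_json_dict()
        coding_path = track(out_dir / "coding_summary.json")
        coding_path.write_text(json.dumps(coding, indent=2, sort_keys=True) + "\n")

        # --- inclusion filter --------------------------------------------
        if config.apply_inclusion:
            current_stage = "inclusion_filter"
            from .reliability import inclusion_filter

            n_in = len(posts)
            posts = inclusion_filter(posts)
            stage_log.append(
                {"stage": "inclusion_filter", "n_in": n_in, "n_out": len(posts)}
            )

        # --- scoring + aggregation ---------------------------------------
        current_stage = "score_corpus"
        matrix = score_corpus(posts, lexicon)
        scores_path = track(out_dir / "sentence_scores.csv")
        matrix.to_csv(scores_path)
        stage_log.append(
            {"stage": "score_corpus", "n_in": len(posts), "n_out": matrix.n_sentences}
        )

        current_stage = "aggregate"
        summary = aggregate(matrix)
        summary_doc: dict = {"overall": summary.to_json_dict()}
        if config.strata:
            for fld, codes in (
                ("user_type", ("patient", "caregiver")),
                ("post_type", ("advice", "experience", "both")),
            ):
                for code in codes:
                    subset = [p for p in posts if getattr(p, fld) == code]
                    if subset:
                        sub_doc, _ = _summarize(subset, lexicon)
                        summary_doc.setdefault(fld, {})[code] = sub_doc
        summary_path = track(out_dir / "summary.json")
        summary_path.write_text(json.dumps(summary_doc, indent=2, sort_keys=True) + "\n")

        # --- dyads -------------------------------------------------------
        current_stage = "dyad_scores"
        dyad_table = normalize_ratios(corpus_dyad_scores(matrix))
        dyads_path = track(out_dir / "dyads.csv")
        dyad_table_for_report(dyad_table).to_csv(dyads_path, index=False)

        # --- wheels ------------------------------------------------------
        current_stage = "wheels"
        ratios = basic_emotion_ratios(summary)
        specs = make_wheel_specs(ratios, dyad_table)
        wheel_rows = [
            {"kind": kind, "name": name, "score": score}
            for kind, spec in specs.items()
            for name, score in spec.scores.items()
        ]
        wheel_scores_path = track(out_dir / "wheel_scores.csv")
        pd.DataFrame(wheel_rows).to_csv(wheel_scores_path, index=False)
        artifacts: dict[str, Path] = {
            "coding_summary": coding_path,
            "sentence_scores": scores_path,
            "summary": summary_path,
            "dyads": dyads_path,
            "wheel_scores": wheel_scores_path,
        }
        for kind, spec in specs.items():
            img = track(out_dir / f"wheel_{kind}.{config.figure_format}")
            render_wheel(spec, img)
            artifacts[f"wheel_{kind}"] = img

        # --- manifest ----------------------------------------------------
        current_stage = "manifest"
        cfg = dataclasses.asdict(config)
        cfg["coding_sheets"] = {k: list(v) for k, v in cfg["coding_sheets"].items()}
        manifest = {
            "config": cfg,
            "seed": config.seed,
            "versions": {"emowheel": __version__, "pandas": pd.__version__},
            "lexicon": {"source": lexicon.source_name, "n_words": len(lexicon)},
            "input_digests": {
                "posts": _sha256(Path(config.posts_path)),
            },
            "stages": stage_log,
        }
        manifest_path = track(out_dir / "manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = manifest_path
        return artifacts
    except PipelineError:
        raise
    except Exception as exc:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:  # pragma: no cover - best-effort cleanup
                pass
        raise PipelineError(current_stage, exc) from exc
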