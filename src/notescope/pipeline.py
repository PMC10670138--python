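"""End-to-end orchestration: the four analysis arms on one note corpus.

A single :func:`run_pipeline` call reads the inputs named in a
:class:`RunConfig`, runs emotion profiling, hybrid sentiment, the
morphological profile and difficulty-area detection, and returns one nested
report dictionary (serialisable to JSON deterministically).  Optional inputs
(tagger table, sentiment model, expert flags) only switch off their
dependent sections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .affect import EmotionIntensityScorer, read_affective_lexicon, read_embeddings
from .corpus import TextPreprocessor, read_notes, read_stopwords
from .pos import DictionaryTagger, PosProfiler, characteristic_terms
from .sentiment import HybridSentimentClassifier, read_polarity_lexicon, sentiment_summary
from .topics import LsaContextClassifier

logger = logging.getLogger("notescope")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    notes: str
    lexicon: str
    embeddings: str
    polarity: str
    areas: str
    tagger: str | None = None
    stopwords: str | None = None
    notes_format: str = "jsonl"
    n_neighbors: int = 5
    alpha: float = 1.0  # dictionary-only by default: no trained model shipped
    lsa_k: int | None = None
    threshold: float = 20.0
    top_k_terms: int = 20
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 100.0:
            raise ValueError("threshold must lie in (0, 100)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8"))
        return cls(**data)


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all four analysis arms; returns the consolidated report."""
    notes = read_notes(config.notes, config.notes_format)
    stopwords = read_stopwords(config.stopwords) if config.stopwords else frozenset()
    processed = TextPreprocessor(stopwords=stopwords).fit().transform(notes)
    nonempty = [p for p in processed if p.length_N > 0]
    if len(nonempty) < len(processed):
        dropped = [p.id for p in processed if p.length_N == 0]
        logger.warning("dropping empty notes: %s", dropped)
    processed = nonempty
    by_id = {n.id: n for n in notes}

    report: dict[str, Any] = {"n_notes": len(processed)}

    # --- emotions ---------------------------------------------------------
    lexicon = read_affective_lexicon(config.lexicon)
    embeddings = read_embeddings(config.embeddings)
    scorer = EmotionIntensityScorer(lexicon, embeddings, config.n_neighbors)
    profiles = scorer.fit(processed).profile_frame(processed)
    grouping = {p.id: by_id[p.id].stage for p in processed}
    stage_means = profiles.groupby(profiles.index.map(grouping)).mean()
    stage_sizes = profiles.groupby(profiles.index.map(grouping)).size()
    report["emotions"] = {
        "per_note": profiles.round(10).to_dict(orient="index"),
        "per_stage": {
            stage: {
                **{e: float(stage_means.loc[stage, e]) for e in profiles.columns},
                "n": int(stage_sizes.loc[stage]),
            }
            for stage in stage_means.index
        },
        "skipped_words": scorer.skipped_words_,
    }

    # --- sentiment --------------------------------------------------------
    polarity = read_polarity_lexicon(config.polarity)
    clf = HybridSentimentClassifier(polarity, alpha=config.alpha).fit(processed)
    results = clf.score_notes(processed)
    report["sentiment"] = {
        "per_note": {
            r.note_id: {"dict_score": r.dict_score, "label": r.hybrid_label}
            for r in results
        },
        "summary": sentiment_summary(results),
    }

    # --- morphological profile -------------------------------------------
    if config.tagger:
        profiler = PosProfiler(
            DictionaryTagger.from_tsv(config.tagger), polarity_lexicon=polarity
        )
        report["pos"] = {
            "profile": profiler.corpus_profile(notes).as_dict(),
            "characteristic_terms": characteristic_terms(
                processed, stopwords, config.top_k_terms
            ),
        }
    else:
        logger.info("no tagger table supplied; skipping the morphological profile")

    # --- difficulty areas -------------------------------------------------
    areas = json.loads(Path(config.areas).read_text("utf-8"))
    topics = LsaContextClassifier(
        areas, k=config.lsa_k, threshold=config.threshold
    ).fit(processed)
    frame = topics.affiliation_frame()
    report["topics"] = {
        "per_note": {
            f"{row.note_id}/{row.area}": {
                "W_P": float(row.W_P),
                "W_N": float(row.W_N),
                "rel_diff": None if pd.isna(row.rel_diff) else float(row.rel_diff),
                "context": row.context,
            }
            for row in frame.itertuples(index=False)
        }
    }
    flags = {
        n.id: n.expert_flags
        for n in notes
        if n.expert_flags and n.id in {p.id for p in processed}
    }
    if len(flags) == len(processed):
        report["topics"]["agreement"] = topics.score(flags).per_area
    else:
        logger.info("expert flags absent or incomplete; skipping agreement")

    report = _round_floats(report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), "utf-8"
        )
        (outdir / "report.md").write_text(render_markdown(report), "utf-8")
    return report


def render_markdown(report: dict) -> str:
    """Short human-readable summary of a pipeline report."""
    lines = ["# notescope report", "", f"Notes analysed: {report['n_notes']}", ""]
    if "sentiment" in report:
        counts = report["sentiment"]["summary"]
        lines += [
            "## Sentiment toward the body",
            "",
            ", ".join(f"{label}: {counts[label]}" for label in sorted(counts)),
            "",
        ]
    if "emotions" in report:
        lines += ["## Mean emotion intensity per stage group", ""]
        for stage, row in sorted(report["emotions"]["per_stage"].items()):
            vals = ", ".join(
                f"{k}={row[k]:.3f}" for k in sorted(row) if k != "n"
            )
            lines.append(f"- stage {stage} (n={row['n']}): {vals}")
        lines.append("")
    if "pos" in report:
        profile = report["pos"]["profile"]
        lines += [
            "## Morphological profile",
            "",
            f"- adjectives: {profile['adj_total']} "
            f"({profile['adj_negative']} negative, {profile['adj_positive']} positive)",
            f"- verbs: {profile['verb_total']} "
            f"({profile['verb_tobe_total']} copula, {profile['verb_other_total']} other)",
            f"- possessive 'my': {profile['my_count']}",
            "",
        ]
    if "topics" in report and "agreement" in report["topics"]:
        lines += ["## Agreement with expert flags", ""]
        for area, row in sorted(report["topics"]["agreement"].items()):
            lines.append(
                f"- {area}: {row['pct_consistent']:.0f}% consistent, "
                f"{row['pct_error']:.0f}% error, "
                f"{row['pct_mixed_detected_as_single']:.0f}% mixed→single, "
                f"{row['pct_single_detected_as_mixed']:.0f}% single→mixed"
            )
        lines.append("")
    return "\n".join(lines)
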