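"""End-to-end orchestration of the framing-trend (H1) and topic-valence
(H2) analyses, with per-stage audit logging and provenance metadata.

``run_h1``: corpus -> tokenize -> collocates (MI-filtered) -> valence
merge -> synonym means -> narrative score series -> per-framing trend fits
and the slope-difference test.

``run_h2``: collocates -> per framing x century collocate bags -> seeded
LDA -> topic valence labels -> positivity proportions -> two-way mixed
ANOVA (framing between, century within, one unit per topic slot paired
across centuries within a framing (x genre) stratum).

Every CSV written starts with a '#'-prefixed metadata line recording the
seed and a hash of the configuration, so outputs are re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import collocation, corpus, topics as topics_mod, trends, valence
from .anova import AnovaResult, two_way_mixed_anova
from .collocation import TargetLexicon, WindowConfig
from .errors import ConfigurationError, DataError
from .topics import TopicModelSpec
from .valence import ValenceLexicon

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    corpus_path: str
    valence_lexicon_path: str | None = None
    target_lexicon_path: str | None = None
    exclusion_path: str | None = None
    output_dir: str = "stereotrend_out"
    dialect: str = "jsonl"
    decade_range: tuple[int, int] = corpus.DEFAULT_YEAR_RANGE
    window: WindowConfig = field(default_factory=WindowConfig)
    topic_spec: TopicModelSpec = field(default_factory=TopicModelSpec)
    by_genre: bool = False
    weighted_means: bool = True
    missing_rating: str = "error"
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        window = WindowConfig(**raw.pop("window", {})) if not isinstance(raw.get("window"), WindowConfig) else raw.pop("window")
        tspec = raw.pop("topic_spec", {})
        if not isinstance(tspec, TopicModelSpec):
            tspec = TopicModelSpec(**tspec)
        if "decade_range" in raw:
            raw["decade_range"] = tuple(raw["decade_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(window=window, topic_spec=tspec, **raw)

    def metadata(self) -> str:
        payload = dataclasses.asdict(self)
        # only analysis-relevant fields enter the hash, so reruns into a
        # different directory remain recognizably identical
        for presentation_only in ("output_dir", "log_level", "make_plots"):
            payload.pop(presentation_only, None)
        payload["window"] = dataclasses.asdict(self.window)
        payload["window"]["excluded_articles"] = sorted(self.window.excluded_articles)
        payload["topic_spec"] = dataclasses.asdict(self.topic_spec)
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]
        return f"seed={self.seed} config_hash={digest}"


def _write_csv(frame: pd.DataFrame, path: Path, metadata: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {metadata}\n")
        frame.to_csv(fh, index=False)


def _load_inputs(config: PipelineConfig):
    docs = list(corpus.read_corpus(config.corpus_path, config.dialect, config.decade_range))
    logger.info("documents read: %d", len(docs))
    if not docs:
        raise DataError(f"no valid documents in {config.corpus_path}")
    tokenized = corpus.tokenize_corpus(docs, config.decade_range)
    targets = (
        TargetLexicon.from_tsv(config.target_lexicon_path)
        if config.target_lexicon_path
        else TargetLexicon.default()
    )
    exclusion = (
        collocation.read_exclusion_list(config.exclusion_path)
        if config.exclusion_path
        else None
    )
    return tokenized, targets, exclusion


def extract_stage(config: PipelineConfig):
    """Shared collocate-extraction stage; returns (records, table, targets)."""
    tokenized, targets, exclusion = _load_inputs(config)
    stats = corpus.corpus_frequencies(tokenized, by_genre=config.by_genre)
    records, table = collocation.extract_collocates(
        tokenized, targets, config.window, stats=stats,
        by_genre=config.by_genre, exclusion=exclusion,
    )
    n_occ = sum(table.target_freqs.values())
    logger.info("target occurrences: %d; collocate records retained: %d", n_occ, len(records))
    return records, table, targets


def run_h1(config: PipelineConfig) -> dict:
    """Framing-trend analysis; writes collocates.csv, scores.csv,
    trend_report.csv, comparison.csv (and a trend plot), and returns the
    in-memory results."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()

    records, table, targets = extract_stage(config)
    if config.valence_lexicon_path is None:
        raise ConfigurationError("run_h1 requires a valence lexicon")
    lexicon = ValenceLexicon.from_tsv(config.valence_lexicon_path)

    means = valence.synonym_decade_means(
        records, lexicon, weighted=config.weighted_means, missing=config.missing_rating
    )
    # decade-level synonym frequencies regardless of genre stratification
    freqs: dict[tuple[str, int], int] = {}
    for (term, key), n in table.target_freqs.items():
        decade = key[0] if config.by_genre else key
        freqs[(term, decade)] = freqs.get((term, decade), 0) + n
    scores = valence.cumulative_narrative_score(means, freqs, targets)

    fits = {f: trends.fit_decade_trend(scores, f) for f in scores.framings()}
    framings = scores.framings()
    comparison = trends.compare_slopes(scores.series(framings[0]), scores.series(framings[1]))

    _write_csv(collocation.records_to_frame(records), outdir / "collocates.csv", meta)
    scores.to_csv(outdir / "scores.csv", metadata=meta)
    _write_csv(trends.trend_report(list(fits.values())), outdir / "trend_report.csv", meta)
    _write_csv(
        pd.DataFrame(
            [{"F": comparison.F, "df1": comparison.df1, "df2": comparison.df2,
              "p": comparison.p, "slope_diff": comparison.slope_diff}]
        ),
        outdir / "comparison.csv",
        meta,
    )
    if config.make_plots:
        trends.plot_trends(scores, fits, outdir / "figure_trends.png")
    logger.info(
        "H1: %s",
        "; ".join(
            f"{f}: slope {fit.slope:+.5f}/decade, decline {fit.percent_decline:.2f}%"
            for f, fit in fits.items()
        ),
    )
    return {
        "records": records,
        "scores": scores,
        "fits": fits,
        "comparison": comparison,
        "lexicon": lexicon,
        "targets": targets,
    }


def build_anova_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Long-format mixed-design table from topic labels.

    The repeated-measure unit is a topic slot — (framing, genre, topic_id)
    — paired across the two centuries; units missing either century are
    dropped by the ANOVA's complete-case rule.  Response is 1 for a
    positive/neutral topic, 0 for a negative one.
    """
    rows = []
    for r in labels.itertuples(index=False):
        rows.append(
            {
                "unit": f"{r.framing}|{r.genre}|{r.topic_id}",
                "between": r.framing,
                "within": r.century,
                "response": 1.0 if r.label == topics_mod.POSITIVE_NEUTRAL else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_h2(config: PipelineConfig, h1_results: dict | None = None) -> dict:
    """Topic-valence analysis; writes topics.csv, labels.csv, summary.csv,
    anova.csv (and a proportions plot)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()

    if h1_results is not None:
        records, targets = h1_results["records"], h1_results["targets"]
        lexicon = h1_results["lexicon"]
    else:
        records, _table, targets = extract_stage(config)
        if config.valence_lexicon_path is None:
            raise ConfigurationError("run_h2 requires a valence lexicon")
        lexicon = ValenceLexicon.from_tsv(config.valence_lexicon_path)

    spec = dataclasses.replace(config.topic_spec, seed=config.seed, by_genre=config.by_genre)
    bags = topics_mod.build_topic_documents(records, spec, targets)
    fitted = topics_mod.fit_lda_by_stratum(bags, spec)
    for t in fitted:
        topics_mod.classify_topic_valence(t, lexicon, spec.neutral_threshold)
    summary = topics_mod.positivity_proportions(fitted)
    labels = topics_mod.labels_to_frame(fitted)
    anova_table = build_anova_table(labels)
    anova_res: AnovaResult | None = None
    try:
        anova_res = two_way_mixed_anova(anova_table)
    except DataError as exc:
        logger.warning("mixed ANOVA skipped: %s", exc)

    _write_csv(topics_mod.topics_to_frame(fitted), outdir / "topics.csv", meta)
    _write_csv(labels, outdir / "labels.csv", meta)
    _write_csv(summary.frame, outdir / "summary.csv", meta)
    if anova_res is not None:
        _write_csv(anova_res.table.reset_index(names="effect"), outdir / "anova.csv", meta)
    if config.make_plots:
        _plot_proportions(summary, outdir / "figure_proportions.png")
    return {
        "topics": fitted,
        "summary": summary,
        "anova_table": anova_table,
        "anova": anova_res,
    }


def _plot_proportions(summary, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    frame = summary.frame
    framings = sorted(frame["framing"].unique())
    centuries = sorted(frame["century"].unique())
    width = 0.35
    x = np.arange(len(centuries))
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, f in enumerate(framings):
        vals = [
            100 * frame[(frame.framing == f) & (frame.century == c)]["proportion_positive_neutral"].iloc[0]
            if ((frame.framing == f) & (frame.century == c)).any() else 0.0
            for c in centuries
        ]
        ax.bar(x + (i - (len(framings) - 1) / 2) * width, vals, width, label=f)
    ax.set_xticks(x, centuries)
    ax.set_ylabel("% positive/neutral topics")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
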