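"""End-to-end pipeline: corpus -> readability -> adjudication -> composite
-> summaries, with a deterministic TSV report bundle.

Stages communicate through documented TSVs so each can be run (and tested)
in isolation; floats are written with fixed 4-decimal precision except in
the report-layer tables (summary/topN), which print 1 decimal.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cohort, composite, instruments, model, readability, synthetic
from .errors import ValidationError, WebqualError

logger = logging.getLogger(__name__)

#: Files produced by a full run, in write order.
BUNDLE_FILES = (
    "readability.tsv",
    "scores.tsv",
    "summary.tsv",
    "content_summary.tsv",
    "tests.tsv",
    "topN.tsv",
    "overall.tsv",
    "run.log",
)

_METRIC_COLUMN = {"fk": "fk_grade", "smog": "smog", "fre": "flesch_ease"}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either file inputs or a synthetic corpus."""

    out_dir: Path
    records_path: Optional[Path] = None
    ratings_path: Optional[Path] = None
    synthetic_config: Optional[synthetic.SyntheticConfig] = None
    grade_metric: str = "fk"
    weights: composite.CompositeWeights = field(default_factory=composite.CompositeWeights)
    reference_date: dt.date = model.DEFAULT_REFERENCE_DATE
    top_n: int = 10
    verbose: bool = False

    def __post_init__(self) -> None:
        file_mode = self.records_path is not None and self.ratings_path is not None
        if file_mode == (self.synthetic_config is not None):
            raise ValidationError(
                "exactly one of (records+ratings paths) or a synthetic config is required"
            )
        if self.grade_metric not in _METRIC_COLUMN:
            raise ValidationError(f"grade_metric must be one of {sorted(_METRIC_COLUMN)}")


def compute_readability_table(corpus: model.Corpus, grade_metric: str = "fk") -> pd.DataFrame:
    """Per-site readability TSV rows (spec'd column set)."""
    metric = "smog" if grade_metric == "smog" else "fk"
    rows = []
    for rec in corpus.records:
        prof = readability.readability_profile(rec.text, grade_metric=metric)
        rows.append(
            {
                "id": rec.id,
                "sentences": prof.stats.n_sentences,
                "words": prof.stats.n_words,
                "syllables": prof.stats.n_syllables,
                "polysyllables": prof.stats.n_polysyllables,
                "smog": prof.smog_grade,
                "fk_grade": prof.fk_grade,
                "flesch_ease": prof.flesch_ease,
                "meets_grade6": prof.meets_grade6,
                "short_text_warning": prof.short_text_warning,
            }
        )
    return pd.DataFrame(rows)


def adjudicate_corpus(corpus: model.Corpus) -> list[instruments.WebsiteScores]:
    """Adjudicated instrument scores for every (multi-rated) record."""
    scores = []
    for rec in corpus.records:
        if rec.id in corpus.single_rated_ok:
            logger.warning("website %r is single-rated; excluded from adjudication", rec.id)
            continue
        site_ratings = sorted(corpus.ratings_for(rec.id), key=lambda r: r.rater_id)
        r3 = site_ratings[2] if len(site_ratings) > 2 else None
        scores.append(instruments.score_website(site_ratings[0], site_ratings[1], r3))
    return scores


def build_site_table(
    corpus: model.Corpus,
    read_table: pd.DataFrame,
    scores: list[instruments.WebsiteScores],
    grade_metric: str = "fk",
    weights: composite.CompositeWeights = composite.CompositeWeights(),
    reference_date: dt.date = model.DEFAULT_REFERENCE_DATE,
) -> pd.DataFrame:
    """One row per site: metadata + all scores + composite + rank."""
    read_by_id = read_table.set_index("id")
    metric_col = _METRIC_COLUMN[grade_metric]

    inputs = []
    rec_by_id = {r.id: r for r in corpus.records}
    for ws in scores:
        rec = rec_by_id[ws.website_id]
        inputs.append(
            composite.SiteScoreInput(
                website_id=ws.website_id,
                url=rec.url,
                discern_total=ws.discern.total,
                content_total=ws.content.total,
                jama_total=ws.jama.total,
                readability_grade=float(read_by_id.loc[ws.website_id, metric_col]),
            )
        )
    ranked = {q.website_id: q for q in composite.rank_corpus(
        inputs, weights=weights, readability_metric=grade_metric)}

    rows = []
    for ws, inp in zip(scores, inputs):
        rec = rec_by_id[ws.website_id]
        q = ranked[ws.website_id]
        row = {
            "id": ws.website_id,
            "url": rec.url,
            "category": rec.category,
            "engagement": ";".join(
                sorted(rec.engagement, key=["inform", "activate", "collaborate"].index)
            ),
            "has_date": rec.last_updated is not None,
            "years_since_update": (
                model.years_since_update(rec.last_updated, reference_date)
                if rec.last_updated is not None and rec.last_updated <= reference_date
                else None
            ),
            "discern_total": ws.discern.total,
            "discern_band": ws.discern.band,
            "discern_raters": ws.discern.n_raters_used,
            "jama_total": ws.jama.total,
            "content_total": ws.content.total,
            "weighted_score": q.weighted_score,
            "rank": q.rank,
        }
        for name, v in zip(model.CONTENT_ITEMS, ws.content.items):
            row[f"content_{name}"] = v
        for col in ("smog", "fk_grade", "flesch_ease", "meets_grade6"):
            row[col] = read_by_id.loc[ws.website_id, col]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, decimals: int = 4) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(
                lambda x: "" if pd.isna(x) else f"{x:.{decimals}f}"
            )
        elif pd.api.types.is_bool_dtype(df[col]):
            df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle under ``config.out_dir``.

    On any error all partially written outputs are removed and the error
    propagates (the CLI maps it to a nonzero exit).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        if config.synthetic_config is not None:
            corpus, truth = synthetic.generate_corpus(config.synthetic_config)
            model.write_corpus(corpus, out / "records.csv", out / "ratings.csv")
            truth.to_csv(out / "truth.csv", index=False, float_format="%.4f")
            written += [out / "records.csv", out / "ratings.csv", out / "truth.csv"]
            note(f"synthetic corpus: {len(corpus.records)} sites, "
                 f"seed {config.synthetic_config.seed}")
        else:
            corpus = model.load_corpus(config.records_path, config.ratings_path)
            note(f"loaded corpus: {len(corpus.records)} sites from {config.records_path}")

        note(f"config: {config!r}")

        read_table = compute_readability_table(corpus, config.grade_metric)
        for _, r in read_table[read_table["short_text_warning"]].iterrows():
            note(f"site {r['id']}: fewer than {readability.SMOG_SENTENCE_FLOOR} "
                 "sentences; SMOG flagged short-text")
        _write_tsv(read_table, out / "readability.tsv")
        written.append(out / "readability.tsv")

        scores = adjudicate_corpus(corpus)
        n3 = sum(1 for s in scores if s.discern.n_raters_used == 3)
        note(f"adjudication: {n3}/{len(scores)} sites used a third DISCERN rater")

        site_table = build_site_table(
            corpus, read_table, scores,
            grade_metric=config.grade_metric,
            weights=config.weights,
            reference_date=config.reference_date,
        )
        _write_tsv(site_table, out / "scores.tsv")
        written.append(out / "scores.tsv")

        summary = cohort.describe_corpus(site_table)
        _write_tsv(summary.category_scores, out / "summary.tsv", decimals=1)
        written.append(out / "summary.tsv")
        _write_tsv(summary.category_content, out / "content_summary.tsv", decimals=1)
        written.append(out / "content_summary.tsv")

        tests = cohort.compare_categories(site_table)
        tests_df = pd.DataFrame(
            [
                {"score": name, "H": r.H, "df": r.df, "p": r.p,
                 "significant": r.significant}
                for name, r in tests.items()
            ]
        )
        _write_tsv(tests_df, out / "tests.tsv")
        written.append(out / "tests.tsv")

        inputs = [
            composite.SiteScoreInput(
                website_id=row["id"], url=row["url"],
                discern_total=row["discern_total"],
                content_total=int(row["content_total"]),
                jama_total=int(row["jama_total"]),
                readability_grade=float(row[_METRIC_COLUMN[config.grade_metric]]),
            )
            for _, row in site_table.iterrows()
        ]
        ranked = composite.rank_corpus(inputs, weights=config.weights,
                                       readability_metric=config.grade_metric)
        top = pd.DataFrame(composite.top_n_table(inputs, ranked, n=config.top_n))
        _write_tsv(top, out / "topN.tsv", decimals=1)
        written.append(out / "topN.tsv")

        overall_df = pd.DataFrame(
            sorted(
                (k, f"{v:.4f}" if isinstance(v, float) else v)
                for k, v in summary.overall.items()
                if not isinstance(v, dict)
            ),
            columns=["statistic", "value"],
        )
        _write_tsv(overall_df, out / "overall.tsv")
        written.append(out / "overall.tsv")
        for pattern, count in sorted(summary.overall.get("engagement_counts", {}).items()):
            note(f"engagement pattern {pattern or '(none)'}: {count} sites")

        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        written.append(out / "run.log")
    except WebqualError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {p.name: p for p in written}
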