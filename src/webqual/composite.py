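"""Normalised, weighted composite quality score and corpus ranking.

Each website's DISCERN, content, and JAMA totals are min-max normalised
over their *possible* instrument ranges; readability is normalised over
the *observed* corpus range and reverse-scaled when lower is better
(grade metrics). The composite is 100 times the weighted sum, default
weights 0.30 (readability) / 0.30 (content) / 0.30 (DISCERN) / 0.10 (JAMA).

Scores are corpus-relative: adding a website that extends the observed
readability range changes every normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import DegenerateRangeError, EmptyCorpusError, RangeError, ValidationError
from .instruments import CONTENT_RANGE, DISCERN_RANGE, JAMA_RANGE

logger = logging.getLogger(__name__)

#: Readability metrics where a *lower* value means easier text.
_LOWER_IS_BETTER = {"fk": True, "smog": True, "fre": False}


@dataclass(frozen=True)
class CompositeWeights:
    """Component weights; must be non-negative and sum to 1."""

    w_readability: float = 0.30
    w_content: float = 0.30
    w_discern: float = 0.30
    w_jama: float = 0.10

    def __post_init__(self) -> None:
        vals = (self.w_readability, self.w_content, self.w_discern, self.w_jama)
        if any(w < 0 for w in vals):
            raise ValidationError(f"weights must be non-negative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {sum(vals)!r}")


@dataclass(frozen=True)
class SiteScoreInput:
    """Per-site raw components fed into the composite."""

    website_id: str
    discern_total: float
    content_total: int
    jama_total: int
    readability_grade: float
    url: str = ""
    extra: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class QualityScores:
    website_id: str
    norm_discern: float
    norm_content: float
    norm_jama: float
    norm_readability: float
    weighted_score: float
    rank: int


def normalize_component(value: float, range_min: float, range_max: float,
                        reverse: bool) -> float:
    """Min-max normalise ``value`` into [0,1]; flip when lower is better."""
    if range_min >= range_max:
        raise DegenerateRangeError(
            f"degenerate range [{range_min}, {range_max}] for min-max normalisation"
        )
    if not range_min <= value <= range_max:
        raise RangeError(f"value {value} outside [{range_min}, {range_max}]")
    x = (value - range_min) / (range_max - range_min)
    return 1.0 - x if reverse else x


def weighted_quality_score(
    discern: float,
    content: float,
    jama: float,
    readability_grade: float,
    readability_observed_range: tuple[float, float],
    weights: CompositeWeights = CompositeWeights(),
    readability_metric: str = "fk",
) -> float:
    """Composite quality on a 0-100 scale (higher is better)."""
    reverse = _LOWER_IS_BETTER[readability_metric]
    lo, hi = readability_observed_range
    try:
        norm_read = normalize_component(readability_grade, lo, hi, reverse)
    except DegenerateRangeError:
        logger.warning(
            "observed readability range is degenerate (%s); using 1.0 for all sites", lo
        )
        norm_read = 1.0
    return 100.0 * (
        weights.w_discern * normalize_component(discern, *DISCERN_RANGE, False)
        + weights.w_content * normalize_component(content, *CONTENT_RANGE, False)
        + weights.w_jama * normalize_component(jama, *JAMA_RANGE, False)
        + weights.w_readability * norm_read
    )


def _normalized_components(site: SiteScoreInput, read_range: tuple[float, float],
                           reverse: bool) -> tuple[float, float, float, float]:
    lo, hi = read_range
    try:
        norm_read = normalize_component(site.readability_grade, lo, hi, reverse)
    except DegenerateRangeError:
        norm_read = 1.0
    return (
        normalize_component(site.discern_total, *DISCERN_RANGE, False),
        normalize_component(site.content_total, *CONTENT_RANGE, False),
        normalize_component(site.jama_total, *JAMA_RANGE, False),
        norm_read,
    )


def rank_corpus(
    sites: Sequence[SiteScoreInput],
    weights: CompositeWeights = CompositeWeights(),
    readability_metric: str = "fk",
    readability_range: Optional[tuple[float, float]] = None,
) -> list[QualityScores]:
    """Composite scores and a deterministic 1-based ranking for a corpus.

    The observed readability range defaults to the min/max over ``sites``.
    Ties in the weighted score break by DISCERN desc, content desc,
    readability asc (for lower-is-better metrics), then id.
    """
    if not sites:
        raise EmptyCorpusError("cannot rank an empty corpus")
    reverse = _LOWER_IS_BETTER[readability_metric]
    if readability_range is None:
        grades = [s.readability_grade for s in sites]
        readability_range = (min(grades), max(grades))
    if readability_range[0] == readability_range[1]:
        logger.warning("all sites share readability %s; component fixed at 1.0",
                       readability_range[0])

    rows: list[tuple[SiteScoreInput, tuple[float, float, float, float], float]] = []
    for site in sites:
        norms = _normalized_components(site, readability_range, reverse)
        score = 100.0 * (
            weights.w_discern * norms[0]
            + weights.w_content * norms[1]
            + weights.w_jama * norms[2]
            + weights.w_readability * norms[3]
        )
        rows.append((site, norms, score))

    read_sign = 1.0 if reverse else -1.0
    rows.sort(
        key=lambda r: (
            -r[2],
            -r[0].discern_total,
            -r[0].content_total,
            read_sign * r[0].readability_grade,
            r[0].website_id,
        )
    )
    return [
        QualityScores(
            website_id=site.website_id,
            norm_discern=norms[0],
            norm_content=norms[1],
            norm_jama=norms[2],
            norm_readability=norms[3],
            weighted_score=score,
            rank=i,
        )
        for i, (site, norms, score) in enumerate(rows, start=1)
    ]


def top_n_table(sites: Sequence[SiteScoreInput], ranked: Sequence[QualityScores],
                n: int = 10) -> list[dict]:
    """Top-N report rows (composite printed to 1 decimal at the report layer)."""
    by_id = {s.website_id: s for s in sites}
    out = []
    for q in ranked[:n]:
        s = by_id[q.website_id]
        out.append(
            {
                "id": s.website_id,
                "url": s.url,
                "discern_total": s.discern_total,
                "readability_grade": s.readability_grade,
                "content_total": s.content_total,
                "weighted_score": round(q.weighted_score, 1),
                "rank": q.rank,
            }
        )
    return out
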