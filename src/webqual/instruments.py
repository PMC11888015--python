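"""Instrument totals, quality bands, and multi-rater adjudication.

Three instruments are scored from item-level ratings:

* DISCERN — 16 items on 1..5, total 16..80, banded very poor … excellent.
  Raters whose totals differ by 5 or more points trigger a third rater;
  the final total is the mean of all contributing raters.
* JAMA benchmark — 4 present/absent items, total 0..4.
* Content rubric — 6 items on 0/1/2, total 0..12.

JAMA and content items are adjudicated per item: agreement stands,
disagreement is settled by the third rater (majority, or the third rater's
value when all three differ — only possible on 0/1/2 items).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, TypeVar

from .errors import (
    AdjudicationRequiredError,
    RangeError,
    UnresolvedDisagreementError,
    ValidationError,
)
from .model import RatingSet

logger = logging.getLogger(__name__)

#: Gap in DISCERN totals at which a third rater becomes mandatory.
DISCERN_ADJUDICATION_GAP = 5

DISCERN_RANGE = (16, 80)
CONTENT_RANGE = (0, 12)
JAMA_RANGE = (0, 4)

#: Quality bands over the DISCERN total, half-open on the real line.
#: The top band is closed at 80 (the instrument maximum): the published
#: band table stops at 75, but totals up to 80 are attainable and are
#: treated as excellent.
DISCERN_BANDS: tuple[tuple[float, float, str], ...] = (
    (16.0, 27.0, "very poor"),
    (27.0, 39.0, "poor"),
    (39.0, 51.0, "fair"),
    (51.0, 63.0, "good"),
    (63.0, 80.0, "excellent"),
)

T = TypeVar("T", int, bool)


@dataclass(frozen=True)
class DiscernScore:
    total: float
    band: str
    n_raters_used: int


@dataclass(frozen=True)
class JamaScore:
    total: int
    items: tuple[bool, ...]


@dataclass(frozen=True)
class ContentScore:
    total: int
    items: tuple[int, ...]


@dataclass(frozen=True)
class WebsiteScores:
    """Adjudicated instrument scores for one website."""

    website_id: str
    discern: DiscernScore
    jama: JamaScore
    content: ContentScore


def discern_total(items: Sequence[int]) -> int:
    """Sum of the 16 DISCERN items."""
    if len(items) != 16:
        raise ValidationError(f"DISCERN needs exactly 16 items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not 1 <= int(v) <= 5:
            raise ValidationError(f"DISCERN item q{i} = {v} outside [1,5]")
    return int(sum(items))


def classify_discern_band(total: float) -> str:
    """Quality band for a (possibly fractional) DISCERN total."""
    if not DISCERN_RANGE[0] <= total <= DISCERN_RANGE[1]:
        raise RangeError(f"DISCERN total {total} outside [16,80]")
    for lo, hi, band in DISCERN_BANDS:
        if lo <= total < hi:
            return band
    return DISCERN_BANDS[-1][2]  # total == 80


def jama_total(items: Sequence[bool]) -> int:
    """Count of present JAMA benchmark criteria."""
    if len(items) != 4:
        raise ValidationError(f"JAMA needs exactly 4 items, got {len(items)}")
    return int(sum(bool(v) for v in items))


def content_total(items: Sequence[int]) -> int:
    """Sum of the 6 content-rubric items."""
    if len(items) != 6:
        raise ValidationError(f"content rubric needs exactly 6 items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if int(v) not in (0, 1, 2):
            raise ValidationError(f"content item {i} = {v} not in {{0,1,2}}")
    return int(sum(items))


def adjudicate_discern(
    r1: RatingSet, r2: RatingSet, r3: Optional[RatingSet] = None
) -> DiscernScore:
    """Final DISCERN score for one website.

    Totals within 4 points of each other average directly (a supplied
    third rating is ignored with a logged note); a gap of 5 or more
    requires the third rating and averages all three.
    """
    if r1.website_id != r2.website_id:
        raise ValidationError(
            f"raters scored different websites: {r1.website_id!r} vs {r2.website_id!r}"
        )
    t1, t2 = discern_total(r1.discern), discern_total(r2.discern)
    if abs(t1 - t2) >= DISCERN_ADJUDICATION_GAP:
        if r3 is None:
            raise AdjudicationRequiredError(
                f"website {r1.website_id!r}: DISCERN totals {t1} and {t2} differ by "
                f"{abs(t1 - t2)} (>= {DISCERN_ADJUDICATION_GAP}) and no third rating was supplied"
            )
        total = (t1 + t2 + discern_total(r3.discern)) / 3
        n = 3
    else:
        if r3 is not None:
            logger.info(
                "website %r: third DISCERN rating ignored (totals %d and %d agree)",
                r1.website_id, t1, t2,
            )
        total = (t1 + t2) / 2
        n = 2
    return DiscernScore(total=total, band=classify_discern_band(total), n_raters_used=n)


def adjudicate_items(
    items1: Sequence[T],
    items2: Sequence[T],
    items3: Optional[Sequence[T]] = None,
) -> tuple[T, ...]:
    """Per-item consensus between two raters with optional third-rater tie-break.

    Agreement keeps the value. Disagreement takes the majority of three,
    falling back to the third rater's value when all three differ (possible
    only for 0/1/2 items). Disagreement without a third rater raises
    :class:`UnresolvedDisagreementError` listing the item indices (1-based).
    """
    if len(items1) != len(items2) or (items3 is not None and len(items3) != len(items1)):
        raise ValidationError("rater item vectors have different lengths")
    disagreements = [i for i, (a, b) in enumerate(zip(items1, items2), start=1) if a != b]
    if disagreements and items3 is None:
        raise UnresolvedDisagreementError(
            f"unresolved disagreement at item(s) {disagreements} and no third rater"
        )
    out: list[T] = []
    for i, (a, b) in enumerate(zip(items1, items2)):
        if a == b:
            out.append(a)
            continue
        c = items3[i]  # type: ignore[index]
        if c == a:
            out.append(a)  # majority a
        elif c == b:
            out.append(b)  # majority b
        else:
            out.append(c)  # all three differ: third rater decides
    return tuple(out)


def score_website(
    r1: RatingSet, r2: RatingSet, r3: Optional[RatingSet] = None
) -> WebsiteScores:
    """Adjudicate all three instruments for one website."""
    discern = adjudicate_discern(r1, r2, r3)
    jama_items = adjudicate_items(r1.jama, r2.jama, r3.jama if r3 else None)
    content_items = adjudicate_items(r1.content, r2.content, r3.content if r3 else None)
    return WebsiteScores(
        website_id=r1.website_id,
        discern=discern,
        jama=JamaScore(total=jama_total(jama_items), items=jama_items),
        content=ContentScore(total=content_total(content_items), items=content_items),
    )
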