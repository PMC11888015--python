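"""Shared data model and corpus file I/O.

A corpus is a pair of CSV files:

``records.csv``
    one row per website: ``id,url,category,country,last_updated,engagement,text``
    (or ``text_path`` pointing at a UTF-8 ``.txt`` file next to the CSV).
    ``engagement`` is a semicolon-joined subset of ``{inform,activate,collaborate}``.
    ``last_updated`` is ISO-8601 ``YYYY-MM-DD``; a bare year is accepted,
    completed to July 1 of that year and flagged as partial.

``ratings.csv``
    long form, one row per (website, rater):
    ``website_id,rater_id,discern_q1..discern_q16,jama_authorship,
    jama_attribution,jama_disclosure,jama_currency,content_definition,
    content_risk_factors,content_outcomes,content_signs_symptoms,
    content_delirium_vs_dementia,content_prevalence``.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from dateutil.relativedelta import relativedelta

from .errors import (
    FormatError,
    OrderingError,
    ReferentialError,
    ValidationError,
)

#: The eight website categories (canonical labels, matched case-insensitively).
CATEGORIES: tuple[str, ...] = (
    "hospital-affiliated",
    "commercial",
    "government",
    "foundation/advocacy",
    "regional health authority",
    "academic",
    "general reference/educational",
    "professional organization",
)

ENGAGEMENT_STRATEGIES: frozenset[str] = frozenset({"inform", "activate", "collaborate"})

#: Default reference date for time-since-update (the corpus collection date).
DEFAULT_REFERENCE_DATE = dt.date(2024, 11, 21)

JAMA_ITEMS: tuple[str, ...] = ("authorship", "attribution", "disclosure", "currency")
CONTENT_ITEMS: tuple[str, ...] = (
    "definition",
    "risk_factors",
    "outcomes",
    "signs_symptoms",
    "delirium_vs_dementia",
    "prevalence",
)

RECORD_COLUMNS = ["id", "url", "category", "country", "last_updated", "engagement", "text"]
RATING_COLUMNS = (
    ["website_id", "rater_id"]
    + [f"discern_q{i}" for i in range(1, 17)]
    + [f"jama_{name}" for name in JAMA_ITEMS]
    + [f"content_{name}" for name in CONTENT_ITEMS]
)


def canonical_category(label: str) -> str:
    """Return the canonical category label, matching case-insensitively."""
    key = label.strip().lower()
    for cat in CATEGORIES:
        if key == cat.lower():
            return cat
    raise ValidationError(
        f"unknown category {label!r}; expected one of {', '.join(CATEGORIES)}"
    )


@dataclass
class WebsiteRecord:
    """One website: metadata plus the plain-text page body."""

    id: str
    url: str
    category: str
    text: str
    country: Optional[str] = None
    last_updated: Optional[dt.date] = None
    last_updated_partial: bool = False  # True when only a year was supplied
    engagement: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("website record needs a non-empty id")
        self.category = canonical_category(self.category)
        self.engagement = frozenset(self.engagement)
        unknown = self.engagement - ENGAGEMENT_STRATEGIES
        if unknown:
            raise ValidationError(
                f"website {self.id!r}: unknown engagement strategies {sorted(unknown)}"
            )


@dataclass
class RatingSet:
    """One rater's raw item scores for one website."""

    website_id: str
    rater_id: str
    discern: tuple[int, ...]
    jama: tuple[bool, ...]
    content: tuple[int, ...]

    def __post_init__(self) -> None:
        self.discern = tuple(int(v) for v in self.discern)
        self.jama = tuple(bool(v) for v in self.jama)
        self.content = tuple(int(v) for v in self.content)
        where = f"website {self.website_id!r}, rater {self.rater_id!r}"
        if len(self.discern) != 16:
            raise ValidationError(f"{where}: expected 16 DISCERN items, got {len(self.discern)}")
        for i, v in enumerate(self.discern, start=1):
            if not 1 <= v <= 5:
                raise ValidationError(f"{where}: DISCERN item q{i} = {v} outside [1,5]")
        if len(self.jama) != 4:
            raise ValidationError(f"{where}: expected 4 JAMA items, got {len(self.jama)}")
        if len(self.content) != 6:
            raise ValidationError(f"{where}: expected 6 content items, got {len(self.content)}")
        for name, v in zip(CONTENT_ITEMS, self.content):
            if v not in (0, 1, 2):
                raise ValidationError(f"{where}: content item {name} = {v} not in {{0,1,2}}")

    @property
    def discern_total(self) -> int:
        return sum(self.discern)


@dataclass
class Corpus:
    """A validated set of website records plus their ratings."""

    records: list[WebsiteRecord]
    ratings: list[RatingSet]
    single_rated_ok: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate website id {rec.id!r}")
            seen.add(rec.id)
        raters: dict[str, set[str]] = {rec.id: set() for rec in self.records}
        for rating in self.ratings:
            if rating.website_id not in raters:
                raise ReferentialError(
                    f"rating by {rating.rater_id!r} references unknown website "
                    f"{rating.website_id!r}"
                )
            raters[rating.website_id].add(rating.rater_id)
        for wid, rset in raters.items():
            if len(rset) < 2 and wid not in self.single_rated_ok:
                raise ValidationError(
                    f"website {wid!r} has {len(rset)} distinct rater(s); "
                    "at least 2 required (or flag it single-rated)"
                )

    def ratings_for(self, website_id: str) -> list[RatingSet]:
        return [r for r in self.ratings if r.website_id == website_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.records == other.records and self.ratings == other.ratings


def years_since_update(last_updated: dt.date, reference: dt.date) -> int:
    """Whole elapsed calendar years between two dates (floor).

    Raises :class:`OrderingError` if ``last_updated`` is after ``reference``.
    """
    if last_updated > reference:
        raise OrderingError(
            f"last_updated {last_updated.isoformat()} is after reference "
            f"{reference.isoformat()}"
        )
    return relativedelta(reference, last_updated).years


def _parse_date(raw: str, where: str) -> tuple[Optional[dt.date], bool]:
    raw = raw.strip()
    if not raw:
        return None, False
    if len(raw) == 4 and raw.isdigit():
        # Year-only dates are completed to July 1 and flagged partial.
        return dt.date(int(raw), 7, 1), True
    try:
        return dt.date.fromisoformat(raw), False
    except ValueError as exc:
        raise ValidationError(f"{where}: bad date {raw!r} (expected YYYY-MM-DD or YYYY)") from exc


def _require_columns(have: Sequence[str], want: Iterable[str], path: Path, *,
                     either: Sequence[str] = ()) -> None:
    have_set = set(have)
    for col in want:
        if col not in have_set:
            raise FormatError(f"{path}: missing required column {col!r}")
    if either and not any(col in have_set for col in either):
        raise FormatError(f"{path}: need one of columns {'/'.join(either)}")


def load_corpus(records_path: str | Path, ratings_path: str | Path,
                single_rated_ok: Iterable[str] = ()) -> Corpus:
    """Load and validate a corpus from a records CSV and a ratings CSV."""
    records_path = Path(records_path)
    ratings_path = Path(ratings_path)

    records: list[WebsiteRecord] = []
    with records_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{records_path}: empty file (no header)")
        _require_columns(
            reader.fieldnames,
            ["id", "url", "category", "country", "last_updated", "engagement"],
            records_path,
            either=["text", "text_path"],
        )
        for lineno, row in enumerate(reader, start=2):
            where = f"{records_path}:{lineno}"
            text = row.get("text") or ""
            if not text and row.get("text_path"):
                text = (records_path.parent / row["text_path"]).read_text(encoding="utf-8")
            date, partial = _parse_date(row["last_updated"] or "", where)
            engagement = frozenset(
                s.strip() for s in (row["engagement"] or "").split(";") if s.strip()
            )
            try:
                records.append(
                    WebsiteRecord(
                        id=row["id"],
                        url=row["url"],
                        category=row["category"],
                        text=text,
                        country=(row["country"] or None),
                        last_updated=date,
                        last_updated_partial=partial,
                        engagement=engagement,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from exc

    ratings: list[RatingSet] = []
    with ratings_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{ratings_path}: empty file (no header)")
        _require_columns(reader.fieldnames, RATING_COLUMNS, ratings_path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{ratings_path}:{lineno}"
            try:
                discern = tuple(int(row[f"discern_q{i}"]) for i in range(1, 17))
                jama = tuple(_parse_bool(row[f"jama_{n}"], where) for n in JAMA_ITEMS)
                content = tuple(int(row[f"content_{n}"]) for n in CONTENT_ITEMS)
            except ValueError as exc:
                raise ValidationError(f"{where}: non-numeric item score ({exc})") from exc
            try:
                ratings.append(
                    RatingSet(
                        website_id=row["website_id"],
                        rater_id=row["rater_id"],
                        discern=discern,
                        jama=jama,
                        content=content,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from exc

    return Corpus(records=records, ratings=ratings,
                  single_rated_ok=frozenset(single_rated_ok))


def _parse_bool(raw: str, where: str) -> bool:
    val = raw.strip().lower()
    if val in ("1", "true", "t", "yes"):
        return True
    if val in ("0", "false", "f", "no"):
        return False
    raise ValidationError(f"{where}: bad boolean value {raw!r}")


def write_corpus(corpus: Corpus, records_path: str | Path, ratings_path: str | Path) -> None:
    """Write a corpus so that :func:`load_corpus` reproduces it exactly."""
    records_path = Path(records_path)
    ratings_path = Path(ratings_path)

    with records_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RECORD_COLUMNS)
        writer.writeheader()
        for rec in corpus.records:
            if rec.last_updated is None:
                date_cell = ""
            elif rec.last_updated_partial:
                date_cell = f"{rec.last_updated.year}"
            else:
                date_cell = rec.last_updated.isoformat()
            writer.writerow(
                {
                    "id": rec.id,
                    "url": rec.url,
                    "category": rec.category,
                    "country": rec.country or "",
                    "last_updated": date_cell,
                    "engagement": ";".join(
                        sorted(rec.engagement, key=["inform", "activate", "collaborate"].index)
                    ),
                    "text": rec.text,
                }
            )

    with ratings_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RATING_COLUMNS)
        writer.writeheader()
        for rating in corpus.ratings:
            row: dict[str, object] = {
                "website_id": rating.website_id,
                "rater_id": rating.rater_id,
            }
            for i, v in enumerate(rating.discern, start=1):
                row[f"discern_q{i}"] = v
            for name, v in zip(JAMA_ITEMS, rating.jama):
                row[f"jama_{name}"] = int(v)
            for name, v in zip(CONTENT_ITEMS, rating.content):
                row[f"content_{name}"] = v
            writer.writerow(row)
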