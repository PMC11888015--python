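"""Sentence/word/syllable statistics and the three readability formulas.

Conventions (fixed so that scores are reproducible):

* URLs and markup-ish tokens are stripped before tokenization.
* A word is a maximal run of letters (apostrophes and hyphens allowed
  inside) or a digit group; a digit group counts as 1 word and 1 syllable.
* Sentences end at ``.``, ``!`` or ``?`` followed by whitespace and a
  capital letter, digit or opening quote/bracket — unless the token before
  the period is on a fixed abbreviation stop-list.
* A polysyllable is a word of three or more syllables.

Formulas (exact, no clamping):

* Flesch Reading Ease  = 206.835 − 1.015·(words/sentences) − 84.6·(syllables/words)
* Flesch-Kincaid grade = 0.39·(words/sentences) + 11.8·(syllables/words) − 15.59
* SMOG grade           = 1.0430·sqrt(polysyllables·30/sentences) + 3.1291
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from ._syllables import count_syllables
from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "TextStats",
    "ReadabilityResult",
    "segment_sentences",
    "count_syllables",
    "tokenize_words",
    "text_stats",
    "flesch_reading_ease",
    "flesch_kincaid_grade",
    "smog_grade",
    "readability_profile",
    "SMOG_SENTENCE_FLOOR",
]

#: SMOG's normative sample length; shorter texts get a short-text warning.
SMOG_SENTENCE_FLOOR = 30

#: Token before a period that does NOT end a sentence (lowercased, with dot).
ABBREVIATIONS = frozenset({
    "dr.", "mr.", "mrs.", "ms.", "prof.", "st.", "no.", "fig.", "vs.",
    "e.g.", "i.e.", "etc.", "al.", "et al.",
})

_URL = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_TAG = re.compile(r"<[^>]{1,200}>")
_WORD = re.compile(r"[^\W\d_]+(?:['’-][^\W\d_]+)*|\d+(?:[.,]\d+)*")
_BOUNDARY = re.compile(r"[.!?]+")
_OPENER = re.compile(r"[\"'“‘(\[]?[A-Z0-9]")


@dataclass(frozen=True)
class TextStats:
    """Raw counts feeding the readability formulas."""

    n_sentences: int
    n_words: int
    n_syllables: int
    n_polysyllables: int

    def __post_init__(self) -> None:
        if min(self.n_sentences, self.n_words, self.n_syllables, self.n_polysyllables) < 0:
            raise ValidationError("text statistics must be non-negative")
        if self.n_polysyllables > self.n_words:
            raise ValidationError("more polysyllabic words than words")
        if self.n_words and self.n_syllables < self.n_words:
            raise ValidationError("fewer syllables than words (every word has >= 1)")


@dataclass(frozen=True)
class ReadabilityResult:
    """The three scores for one text plus the grade-6 compliance flag."""

    stats: TextStats
    smog_grade: float
    fk_grade: float
    flesch_ease: float
    grade_metric: str
    meets_grade6: bool
    short_text_warning: bool


def strip_noise(text: str) -> str:
    """Remove URLs and markup tags; web text is noisy."""
    return _TAG.sub(" ", _URL.sub(" ", text))


def segment_sentences(text: str) -> list[str]:
    """Split text into sentences (deterministic, abbreviation-aware)."""
    text = strip_noise(text)
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        tail = text[end:]
        stripped = tail.lstrip()
        at_eof = not stripped
        opens_new = bool(_OPENER.match(stripped)) and len(tail) != len(stripped)
        if not (at_eof or opens_new):
            continue
        # token immediately before the boundary, e.g. "Dr." or "al."
        prev = text[start:m.end()].rsplit(None, 1)
        token = prev[-1].lower() if prev else ""
        if not at_eof and (token in ABBREVIATIONS or _is_initial(token)):
            continue
        candidate = text[start:end].strip()
        if candidate:
            sentences.append(candidate)
        start = end
    trailing = text[start:].strip()
    if trailing and _WORD.search(trailing):
        sentences.append(trailing)
    return sentences


def _is_initial(token: str) -> bool:
    # single-letter initials ("J.") and dotted acronyms ("U.S.")
    return bool(re.fullmatch(r"(?:[a-z]\.)+", token))


def tokenize_words(text: str) -> list[str]:
    """Word tokens of a (noise-stripped) text."""
    return _WORD.findall(strip_noise(text))


def _word_syllables(token: str) -> int:
    if token[0].isdigit():
        return 1  # digit group convention: 1 word, 1 syllable
    return count_syllables(token)


def text_stats(text: str) -> TextStats:
    sentences = segment_sentences(text)
    words = tokenize_words(text)
    syllables = 0
    poly = 0
    for token in words:
        s = _word_syllables(token)
        syllables += s
        if s >= 3:
            poly += 1
    return TextStats(
        n_sentences=len(sentences),
        n_words=len(words),
        n_syllables=syllables,
        n_polysyllables=poly,
    )


def _require(stats: TextStats, need_words: bool = True) -> None:
    if stats.n_sentences == 0:
        raise UndefinedStatisticError("zero sentences: readability undefined")
    if need_words and stats.n_words == 0:
        raise UndefinedStatisticError("zero words: readability undefined")


def flesch_reading_ease(stats: TextStats) -> float:
    _require(stats)
    return (
        206.835
        - 1.015 * (stats.n_words / stats.n_sentences)
        - 84.6 * (stats.n_syllables / stats.n_words)
    )


def flesch_kincaid_grade(stats: TextStats) -> float:
    _require(stats)
    return (
        0.39 * (stats.n_words / stats.n_sentences)
        + 11.8 * (stats.n_syllables / stats.n_words)
        - 15.59
    )


def smog_grade(stats: TextStats) -> float:
    _require(stats, need_words=False)
    return 1.0430 * math.sqrt(stats.n_polysyllables * 30 / stats.n_sentences) + 3.1291


def readability_profile(text: str, grade_metric: str = "fk") -> ReadabilityResult:
    """All three scores for one text.

    ``grade_metric`` ('fk' or 'smog') selects which grade is compared with
    the recommended grade-6 threshold (``meets_grade6`` is true at <= 6.0).
    """
    if grade_metric not in ("fk", "smog"):
        raise ValidationError(f"grade_metric must be 'fk' or 'smog', got {grade_metric!r}")
    stats = text_stats(text)
    fk = flesch_kincaid_grade(stats)
    smog = smog_grade(stats)
    fre = flesch_reading_ease(stats)
    grade = fk if grade_metric == "fk" else smog
    return ReadabilityResult(
        stats=stats,
        smog_grade=smog,
        fk_grade=fk,
        flesch_ease=fre,
        grade_metric=grade_metric,
        meets_grade6=grade <= 6.0,
        short_text_warning=stats.n_sentences < SMOG_SENTENCE_FLOOR,
    )
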