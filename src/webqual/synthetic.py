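"""Synthetic corpus generation with controllable structure.

Texts are assembled from word banks stratified by syllable count so the
achieved Flesch-Kincaid grade tracks a target; rater scores are drawn
around per-site latent instrument totals with a controllable probability
of a forced >= 5-point DISCERN gap (which triggers third-rater
adjudication downstream). The generator also emits a latent truth table
so recovery can be tested end to end.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._syllables import syllable_dictionary
from .errors import GenerationError, ValidationError
from .model import CATEGORIES, Corpus, RatingSet, WebsiteRecord

#: Fixed words-per-sentence of generated text (grade is steered via
#: syllables/word; 12 wpm keeps the solvable grade range at ~[1, 22]).
_WORDS_PER_SENTENCE = 12
_MAX_BANK_SYLLABLES = 5

_ENGAGEMENT_PATTERNS: tuple[tuple[frozenset[str], float], ...] = (
    (frozenset({"inform", "activate", "collaborate"}), 0.58),
    (frozenset({"inform", "activate"}), 0.21),
    (frozenset({"inform"}), 0.16),
    (frozenset({"inform", "collaborate"}), 0.05),
)

_COUNTRIES = ("US", "CA", "GB", "AU", "NZ", None)

# Per-category defaults keyed in CATEGORIES order.
_DEFAULT_CATEGORY_WEIGHTS = (21, 20, 19, 16, 14, 6, 6, 4)
_DEFAULT_DISCERN_MEANS = (37.5, 44.5, 42.0, 46.5, 32.5, 52.5, 40.5, 34.0)
_DEFAULT_JAMA_MEANS = (1.5, 3.0, 1.5, 1.0, 1.3, 1.5, 2.5, 1.5)
_DEFAULT_CONTENT_MEANS = (6.9, 8.3, 7.9, 8.4, 7.2, 9.6, 7.6, 5.9)
_DEFAULT_GRADE_MEANS = (10.0, 11.0, 10.0, 10.0, 9.0, 12.0, 10.0, 11.0)


def _per_category(values) -> dict[str, float]:
    return dict(zip(CATEGORIES, values))


@dataclass(frozen=True)
class LatentScores:
    """Latent (noise-free) instrument values for one site."""

    discern: float
    content: float
    jama: float


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the corpus generator."""

    n_sites: int = 106
    seed: int = 0
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: _per_category(
            np.asarray(_DEFAULT_CATEGORY_WEIGHTS) / sum(_DEFAULT_CATEGORY_WEIGHTS)
        )
    )
    discern_means: Mapping[str, float] = field(
        default_factory=lambda: _per_category(_DEFAULT_DISCERN_MEANS))
    discern_sd: float = 8.0
    content_means: Mapping[str, float] = field(
        default_factory=lambda: _per_category(_DEFAULT_CONTENT_MEANS))
    content_sd: float = 2.0
    jama_means: Mapping[str, float] = field(
        default_factory=lambda: _per_category(_DEFAULT_JAMA_MEANS))
    jama_sd: float = 1.0
    grade_means: Mapping[str, float] = field(
        default_factory=lambda: _per_category(_DEFAULT_GRADE_MEANS))
    grade_sd: float = 2.0
    n_sentences: int = 35
    rater_noise_sd: float = 2.0
    disagreement_rate: float = 0.2
    date_start: dt.date = dt.date(2015, 1, 1)
    date_end: dt.date = dt.date(2024, 11, 20)
    missing_date_prob: float = 0.23

    def __post_init__(self) -> None:
        probs = np.asarray([self.category_probs[c] for c in CATEGORIES], dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("category_probs must be a probability simplex over "
                                  "the 8 categories")
        for name in ("discern_sd", "content_sd", "jama_sd", "grade_sd", "rater_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.disagreement_rate <= 1.0:
            raise ValidationError("disagreement_rate must be in [0,1]")
        if not 0.0 <= self.missing_date_prob <= 1.0:
            raise ValidationError("missing_date_prob must be in [0,1]")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")


def _word_banks() -> dict[int, list[str]]:
    banks: dict[int, list[str]] = {k: [] for k in range(1, _MAX_BANK_SYLLABLES + 1)}
    for word, count in sorted(syllable_dictionary().items()):
        if count in banks:
            banks[count].append(word)
    return banks


def generate_text(target_grade: float, n_sentences: int,
                  seed: Optional[int | np.random.Generator] = None) -> str:
    """Text whose Flesch-Kincaid grade lands near ``target_grade``.

    For ``n_sentences >= 30`` the achieved grade is within ±1.0 of the
    target (in practice much closer: the syllable budget is solved from
    the FK formula and words come from hand-counted banks).
    """
    if not 1.0 <= target_grade <= 22.0:
        raise GenerationError(f"target grade {target_grade} outside supported [1, 22]")
    if n_sentences < 1:
        raise GenerationError("need at least one sentence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    banks = _word_banks()

    wps = _WORDS_PER_SENTENCE
    spw = (target_grade + 15.59 - 0.39 * wps) / 11.8
    if not 1.0 <= spw <= _MAX_BANK_SYLLABLES:
        raise GenerationError(
            f"target grade {target_grade} needs {spw:.2f} syllables/word; "
            f"word banks cover 1..{_MAX_BANK_SYLLABLES}"
        )
    n_words = wps * n_sentences
    total_syllables = int(round(n_words * spw))

    # one syllable per word, then upgrade random slots until the budget is met
    counts = np.ones(n_words, dtype=int)
    deficit = total_syllables - n_words
    while deficit > 0:
        i = int(rng.integers(0, n_words))
        if counts[i] < _MAX_BANK_SYLLABLES:
            counts[i] += 1
            deficit -= 1

    sentences = []
    for s in range(n_sentences):
        chunk = counts[s * wps:(s + 1) * wps]
        words = [banks[int(k)][int(rng.integers(0, len(banks[int(k)])))] for k in chunk]
        words[0] = words[0].capitalize()
        sentences.append(" ".join(words) + ".")
    return " ".join(sentences)


def _spread_total(total: int, n_items: int, lo: int, hi: int) -> tuple[int, ...]:
    """Spread an integer total over items by round-robin filling within caps.

    Guarantees ``sum(result) == total`` whenever ``n*lo <= total <= n*hi``.
    """
    if not n_items * lo <= total <= n_items * hi:
        raise ValidationError(
            f"total {total} not spreadable over {n_items} items in [{lo},{hi}]"
        )
    items = [lo] * n_items
    remaining = total - lo * n_items
    i = 0
    while remaining > 0:
        if items[i] < hi:
            items[i] += 1
            remaining -= 1
        i = (i + 1) % n_items
    return tuple(items)


def _clip_round(x: float, lo: int, hi: int) -> int:
    return int(min(max(round(x), lo), hi))


def generate_ratings(
    website_id: str,
    latent: LatentScores,
    noise_sd: float,
    disagreement_rate: float,
    rng: np.random.Generator,
) -> tuple[list[RatingSet], bool]:
    """Two (or three) rating sets for one site.

    Returns ``(ratings, forced)`` where ``forced`` marks the pair whose
    DISCERN totals were pushed >= 5 apart (probability ``disagreement_rate``
    exactly: non-forced pairs are clamped to a gap <= 4). A third rating,
    centred on the latent values, is attached when the pair was forced or
    when the JAMA/content item vectors disagree.
    """
    if not 16 <= latent.discern <= 80:
        raise ValidationError(f"latent DISCERN {latent.discern} outside [16,80]")
    if not 0 <= latent.content <= 12:
        raise ValidationError(f"latent content {latent.content} outside [0,12]")
    if not 0 <= latent.jama <= 4:
        raise ValidationError(f"latent JAMA {latent.jama} outside [0,4]")

    forced = bool(rng.random() < disagreement_rate)
    if forced:
        # split the forced gap symmetrically around the (noisy) latent so
        # the pair mean stays an unbiased estimate of the latent total
        gap = 5 + int(rng.integers(0, 3))
        centre = latent.discern + rng.normal(0.0, noise_sd)
        t1 = _clip_round(centre - gap / 2, 16, 80 - gap)
        t2 = t1 + gap
        if rng.random() < 0.5:
            t1, t2 = t2, t1
    else:
        t1 = _clip_round(latent.discern + rng.normal(0.0, noise_sd), 16, 80)
        t2 = _clip_round(latent.discern + rng.normal(0.0, noise_sd), 16, 80)
        t2 = min(max(t2, t1 - 4), t1 + 4)  # unforced pairs stay below the gap

    j1 = _clip_round(latent.jama + rng.normal(0.0, noise_sd / 4), 0, 4)
    j2 = _clip_round(latent.jama + rng.normal(0.0, noise_sd / 4), 0, 4)
    c1 = _clip_round(latent.content + rng.normal(0.0, noise_sd / 2), 0, 12)
    c2 = _clip_round(latent.content + rng.normal(0.0, noise_sd / 2), 0, 12)

    def rating(rater: str, t: int, j: int, c: int) -> RatingSet:
        return RatingSet(
            website_id=website_id,
            rater_id=rater,
            discern=_spread_total(t, 16, 1, 5),
            jama=tuple(bool(v) for v in _spread_total(j, 4, 0, 1)),
            content=_spread_total(c, 6, 0, 2),
        )

    ratings = [rating("r1", t1, j1, c1), rating("r2", t2, j2, c2)]
    if forced or j1 != j2 or c1 != c2:
        ratings.append(
            rating(
                "r3",
                _clip_round(latent.discern, 16, 80),
                _clip_round(latent.jama, 0, 4),
                _clip_round(latent.content, 0, 12),
            )
        )
    return ratings, forced


def sample_latents(config: SyntheticConfig, rng: np.random.Generator
                   ) -> list[tuple[str, LatentScores, float]]:
    """Per-site (category, latent scores, target grade) draws."""
    probs = np.asarray([config.category_probs[c] for c in CATEGORIES], dtype=float)
    out = []
    for _ in range(config.n_sites):
        cat = str(rng.choice(np.asarray(CATEGORIES, dtype=object), p=probs))
        latent = LatentScores(
            discern=float(np.clip(rng.normal(config.discern_means[cat], config.discern_sd),
                                  16, 80)),
            content=float(np.clip(rng.normal(config.content_means[cat], config.content_sd),
                                  0, 12)),
            jama=float(np.clip(rng.normal(config.jama_means[cat], config.jama_sd), 0, 4)),
        )
        grade = float(np.clip(rng.normal(config.grade_means[cat], config.grade_sd), 2, 20))
        out.append((cat, latent, grade))
    return out


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, pd.DataFrame]:
    """Full synthetic corpus plus its latent truth table."""
    rng = np.random.default_rng(config.seed)
    draws = sample_latents(config, rng)

    pattern_sets = [p for p, _ in _ENGAGEMENT_PATTERNS]
    pattern_probs = np.asarray([w for _, w in _ENGAGEMENT_PATTERNS])
    pattern_probs = pattern_probs / pattern_probs.sum()
    span_days = (config.date_end - config.date_start).days

    records: list[WebsiteRecord] = []
    ratings: list[RatingSet] = []
    truth_rows = []
    for i, (cat, latent, grade) in enumerate(draws):
        wid = f"w{i:03d}"
        text = generate_text(grade, config.n_sentences, rng)
        if rng.random() < config.missing_date_prob:
            date = None
        else:
            date = config.date_start + dt.timedelta(days=int(rng.integers(0, span_days + 1)))
        engagement = pattern_sets[int(rng.choice(len(pattern_sets), p=pattern_probs))]
        country = _COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))]
        records.append(
            WebsiteRecord(
                id=wid,
                url=f"https://example.org/{wid}",
                category=cat,
                text=text,
                country=country,
                last_updated=date,
                engagement=engagement,
            )
        )
        site_ratings, forced = generate_ratings(
            wid, latent, config.rater_noise_sd, config.disagreement_rate, rng
        )
        # per-site rater ids are unique within the site; make them global-ish
        ratings.extend(site_ratings)
        truth_rows.append(
            {
                "id": wid,
                "category": cat,
                "discern_latent": latent.discern,
                "content_latent": latent.content,
                "jama_latent": latent.jama,
                "grade_target": grade,
                "forced_disagreement": forced,
            }
        )
    corpus = Corpus(records=records, ratings=ratings)
    truth = pd.DataFrame(truth_rows)
    return corpus, truth


def with_category_shift(config: SyntheticConfig, category: str,
                        discern_shift: float) -> SyntheticConfig:
    """Copy of ``config`` with one category's DISCERN mean shifted."""
    means = dict(config.discern_means)
    means[category] = means[category] + discern_shift
    return replace(config, discern_means=means)
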