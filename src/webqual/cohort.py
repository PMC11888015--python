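"""Descriptive summaries and between-category comparisons.

Works on a per-site table (one row per website) with the adjudicated and
composite scores already attached. Quartiles use linear interpolation
between order statistics (numpy's default, type-7); SDs are sample SDs
(ddof=1) and are left blank for single-site groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyCorpusError, InsufficientGroupsError, ValidationError
from .model import CATEGORIES, CONTENT_ITEMS

ALPHA = 0.05

#: Score columns compared across categories with Kruskal-Wallis.
COMPARED_SCORES = ("discern_total", "jama_total", "weighted_score")


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class SummaryTable:
    """Corpus summaries: Table-1-shaped, Table-2-shaped, and overall rows."""

    category_scores: pd.DataFrame   # n, %, median (IQR) of DISCERN/JAMA/weighted
    category_content: pd.DataFrame  # mean (SD) of each content item per category
    overall: dict                   # corpus-level medians/IQRs/counts


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with type-7 (linear interpolation) quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("median of an empty sequence")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _mean_sd(values: np.ndarray) -> tuple[float, float | None]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else None
    return mean, sd


def describe_corpus(table: pd.DataFrame) -> SummaryTable:
    """Summarise a per-site score table by category and overall.

    Expects columns: ``id, category, discern_total, jama_total,
    content_total, content_<item>..., weighted_score, fk_grade, smog,
    flesch_ease, meets_grade6, has_date, engagement``.
    """
    if len(table) == 0:
        raise EmptyCorpusError("cannot summarise an empty corpus")
    n_total = len(table)

    score_rows = []
    content_rows = []
    # iterate canonical category order; skip absent categories
    for cat in CATEGORIES:
        sub = table[table["category"] == cat]
        n = len(sub)
        if n == 0:
            continue
        row: dict = {"category": cat, "n": n, "pct": 100.0 * n / n_total}
        for col, label in (
            ("discern_total", "discern"),
            ("jama_total", "jama"),
            ("weighted_score", "weighted"),
        ):
            med, q1, q3 = median_iqr(sub[col].to_numpy())
            row[f"{label}_median"] = med
            row[f"{label}_q1"] = q1
            row[f"{label}_q3"] = q3
        score_rows.append(row)

        crow: dict = {"category": cat, "n": n, "pct": 100.0 * n / n_total}
        for item in CONTENT_ITEMS:
            mean, sd = _mean_sd(sub[f"content_{item}"].to_numpy(dtype=float))
            crow[f"{item}_mean"] = mean
            crow[f"{item}_sd"] = sd
        content_rows.append(crow)

    category_scores = pd.DataFrame(score_rows)
    category_content = pd.DataFrame(content_rows)

    overall: dict = {"n": n_total}
    for col in ("discern_total", "jama_total", "content_total", "weighted_score",
                "smog", "fk_grade", "flesch_ease"):
        if col in table.columns:
            med, q1, q3 = median_iqr(table[col].to_numpy(dtype=float))
            overall[f"{col}_median"] = med
            overall[f"{col}_q1"] = q1
            overall[f"{col}_q3"] = q3
    if "meets_grade6" in table.columns:
        k = int(table["meets_grade6"].sum())
        overall["n_meets_grade6"] = k
        overall["pct_meets_grade6"] = 100.0 * k / n_total
    if "has_date" in table.columns:
        k = int(table["has_date"].sum())
        overall["n_dated"] = k
        overall["pct_dated"] = 100.0 * k / n_total
    if "engagement" in table.columns:
        counts = table["engagement"].value_counts()
        overall["engagement_counts"] = {str(k): int(v) for k, v in counts.items()}
    if "years_since_update" in table.columns:
        dated = table["years_since_update"].dropna()
        if len(dated):
            med, q1, q3 = median_iqr(dated.to_numpy(dtype=float))
            overall["years_since_update_median"] = med
            overall["years_since_update_q1"] = q1
            overall["years_since_update_q3"] = q3
    return SummaryTable(category_scores=category_scores,
                        category_content=category_content, overall=overall)


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df).

    Identical values across the board are a degenerate no-effect case and
    return H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(groups):
        raise ValidationError("values and groups differ in length")
    samples: dict[str, list[float]] = {}
    for v, g in zip(values, groups):
        samples.setdefault(str(g), []).append(float(v))
    if len(samples) < 2:
        raise InsufficientGroupsError(
            f"Kruskal-Wallis needs >= 2 groups, got {len(samples)}"
        )
    df = len(samples) - 1
    if np.all(values == values[0]):
        return KruskalResult(H=0.0, df=df, p=1.0)
    H, p = sps.kruskal(*samples.values())
    return KruskalResult(H=float(H), df=df, p=float(p))


def compare_categories(table: pd.DataFrame,
                       score_columns: Sequence[str] = COMPARED_SCORES
                       ) -> Mapping[str, KruskalResult]:
    """Kruskal-Wallis of each score column across website categories."""
    return {
        col: kruskal_wallis(table[col].to_numpy(dtype=float), table["category"].tolist())
        for col in score_columns
    }
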