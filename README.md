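# webqual

Evaluation pipeline for the quality, content, and readability of
consumer-health website corpora.

Given a corpus of website records (plain-text page bodies plus metadata)
and per-rater instrument ratings, webqual computes:

* **Readability** — SMOG, Flesch-Kincaid grade level, and Flesch Reading
  Ease from deterministic sentence/word/syllable counting (packaged
  hand-counted syllable dictionary with a heuristic fallback), plus a
  grade-6 compliance flag.
* **Instrument scores** — DISCERN (16 items, 1–5, total 16–80 with quality
  bands), the 4-item JAMA benchmark (0–4), and a 6-item content rubric
  (0/1/2 each, total 0–12), with two-rater adjudication: DISCERN totals
  differing by ≥ 5 points require a third rater and the final score is the
  mean of all raters; JAMA/content items are adjudicated per item by
  majority (third rater decides when all three differ).
* **Composite quality score** — each component min-max normalised (possible
  ranges for the instruments, the observed corpus range for readability,
  which is reverse-scaled), weighted 30 % readability / 30 % content /
  30 % DISCERN / 10 % JAMA onto a 0–100 scale, with a deterministic
  ranking and a top-N report.
* **Cohort statistics** — per-category medians (IQR), per-item content
  means (SD), corpus-level summaries, and Kruskal-Wallis comparisons of
  scores across the eight website categories.
* **Synthetic corpora** — texts with controllable Flesch-Kincaid grade
  (word banks stratified by syllable count) and rater scores with a
  controllable forced-disagreement rate, plus a latent truth table, so the
  whole pipeline is testable offline.

Composite scores are corpus-relative (the readability normalisation uses
the observed range), and the readability component uses a single
configurable metric (Flesch-Kincaid grade by default; SMOG and FRE
available) — the three readability scores are not blended.

## Command line

```sh
# synthetic corpus (records.csv, ratings.csv, truth.csv)
webqual generate --out corpus/ --seed 7 --n-sites 106

# full pipeline on files, or end-to-end on a synthetic corpus
webqual all --records corpus/records.csv --ratings corpus/ratings.csv --out report/
webqual all --synthetic --seed 7 --out report/

# individual stages
webqual readability --records corpus/records.csv --ratings corpus/ratings.csv --out read.tsv
webqual adjudicate  --records corpus/records.csv --ratings corpus/ratings.csv --out adj.tsv
webqual summarize   --records corpus/records.csv --ratings corpus/ratings.csv --out report/
```

`webqual all` writes `readability.tsv`, `scores.tsv`, `summary.tsv`,
`content_summary.tsv`, `tests.tsv`, `topN.tsv`, `overall.tsv`, and
`run.log`. Reruns with the same inputs are byte-identical. Useful flags:
`--grade-metric {fk,smog,fre}`, `--weights r,c,d,j`, `--top N`,
`--reference-date YYYY-MM-DD`.

## File formats

`records.csv`: `id,url,category,country,last_updated,engagement,text`
(`text_path` may replace `text`; `engagement` is a semicolon-joined subset
of inform/activate/collaborate; dates are ISO-8601, a bare year is
completed to July 1 and flagged). `ratings.csv` is long-form, one row per
(website, rater): `website_id,rater_id,discern_q1..q16,jama_*,content_*`.

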