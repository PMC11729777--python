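# lyrictrace

Surveillance of **drug-related lyric quotations** in short social-media
posts. Public health researchers track substance-use signals in
user-generated content; one signal is people quoting established
drug-referencing song lyrics ("If I smoke this blunt ... "). `lyrictrace`
implements the full analysis pipeline for that signal:

1. **Normalization** — posts and lyric lines are tokenized; URLs,
   @-mentions, emojis and punctuation are stripped; tokens are lowercased
   and carry a dictionary-style lemma, a Porter stem, and a stop-word flag.
   A post is eligible only if it keeps ≥ 3 non-stop-word (content) tokens.
2. **Fuzzy keyword screen** — a post survives when some content-token
   lemma matches a drug-lexicon entry with normalized Levenshtein ratio
   `1 − d(a,b)/max(|a|,|b|) ≥ 0.95`. At that threshold a token shorter
   than ~20 characters must match exactly (one edit already costs more
   than the budget), while long pharmaceutical terms tolerate an edit.
3. **Quote detection** — candidate lyric lines sharing ≥ 3 distinct
   content stems with the post are retrieved from an inverted index and
   aligned with **Smith–Waterman local alignment over word stems**
   (+1 match, −1 mismatch, −1 linear gap). The raw score is normalized by
   the shorter sequence length, so 1.0 means the shorter side embeds
   perfectly and 0.0 means no local similarity. A match is accepted when
   ≥ 3 stems match exactly and the normalized score is ≥ 0.5; ties across
   songs resolve to the **earliest release date**.
4. **Trend analytics** — accepted matches aggregate into per-drug /
   per-category tallies, artist-gender and song-genre breakdowns, a
   year-end-chart cross-reference, a follower histogram (100 equal-width
   bins), hourly-batch availability accounting, and a monthly time
   series. The series is split chronologically 2:1, an OLS trend
   `count = m·t + b` is fitted on the training prefix, and evaluated out
   of sample with RMSE and `R² = 1 − SS_res/SS_tot` about the test mean
   (which can be negative).

Because the original post stream is not redistributable, the package
ships a **seeded synthetic-corpus generator** with sidecar ground truth:
background posts draw from a vocabulary stem-disjoint from lyric lines, a
configurable fraction of posts quote (possibly noise-corrupted) lyric
lines, and every post is labelled — so recall and false-positive rates
are exactly measurable.

## Worked example

```bash
python analysis/01_generate_corpus.py
python analysis/02_run_pipeline.py
python analysis/03_detection_quality.py
python analysis/04_trend_forecast.py
```

The first script writes a three-year corpus (46,859 posts in 23,440
hourly batches, 2,864 hours withheld, 10.0% of posts quoting a lyric
line) to `scratch/corpus/`. The second runs the pipeline and prints the
per-year funnel:

```
 year  original  screened  matched
 2015     15406      2127     1313
 2016     15829      2182     1394
 2017     15624      2220     1395
totals: 46859 posts, 6529 screened, 4102 lyric matches
```

i.e. ~14% of posts mention a drug keyword and 4,102 of those are accepted
as lyric quotations. The third script scores detection against ground
truth across noise levels (~10,000 posts per row):

```
 char_edit_rate  recall  false_positive_rate
           0.00  1.0000                  0.0
           0.02  0.8946                  0.0
           0.05  0.6133                  0.0
```

Noise-free quotes are recovered perfectly and background posts never
match; recall decays as per-character corruption breaks exact stem
equality inside the aligner. The fourth script fits the monthly trend
(36 months, 2:1 split) and reports, for this corpus:

```
         model ratio  rmse       r2   slope intercept
           ols   2:1 13.02 -0.23718  0.4422  107.7067
seasonal_naive   2:1 11.29  0.07009
```

The negative out-of-sample R² shows the extrapolated line underperforming
the test-mean predictor — the expected behaviour of a linear trend pushed
beyond a flat, noisy series.

A CLI mirrors the stages (`lyrictrace generate|screen|match|aggregate|
forecast|qa-sample|report|run-all --config config.yaml`).

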