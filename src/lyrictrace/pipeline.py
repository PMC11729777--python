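"""End-to-end orchestration: generate -> screen -> match -> aggregate -> forecast.

Posts are streamed one hourly JSONL batch at a time and processed in
fixed-size buffers.  Every stage writes a flat-file artifact under the
configured output directory plus a structured JSON-Lines run log with
per-stage counts and timing, so a run is fully machine-checkable.  All
randomness flows from named seeds in the configuration; two runs of the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
import yaml

from . import forecasting, trend_analytics
from .errors import ConfigurationError, LyricTraceError
from .keyword_screen import KeywordLexicon, ScreenResult, screen_post
from .lyric_alignment import (InvertedIndex, LyricMatch, MatchCriteria,
                              ScoringScheme, build_index, detect_lyric)
from .synthetic_corpus import (CorpusConfig, PostRecord, SongSpec,
                               build_lexicon, generate_lyrics_db,
                               generate_post_stream, read_lyrics_db,
                               read_post_batches, write_ground_truth,
                               write_lyrics_db, write_post_batches)
from .textnorm import is_eligible, tokenize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "summarize_counts", "screen_stream", "match_screened"]


@dataclass(frozen=True)
class PipelineConfig:
    posts_dir: str = "corpus/posts"
    lyrics_dir: str = "corpus/lyrics"
    lexicon_path: str = "corpus/lexicon.tsv"
    output_dir: str = "output"
    keyword_ratio: float = 0.95
    min_matched_tokens: int = 3
    min_score: float = 0.5
    split_ratio: float = 2 / 3
    histogram_bins: int = 100
    qa_sample_size: int = 1000
    buffer_size: int = 200
    qa_seed: int = 17
    date_range: tuple[dt.date, dt.date] | None = None
    corpus: CorpusConfig = field(default_factory=CorpusConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.keyword_ratio <= 1.0):
            raise ConfigurationError("keyword_ratio outside [0, 1]")
        if not (0.0 <= self.min_score <= 1.0):
            raise ConfigurationError("min_score outside [0, 1]")
        if self.min_matched_tokens < 1:
            raise ConfigurationError("min_matched_tokens must be >= 1")
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigurationError("split_ratio outside (0, 1)")
        if self.buffer_size < 1 or self.histogram_bins < 1:
            raise ConfigurationError("buffer_size/histogram_bins must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        corpus_raw = raw.pop("corpus", {})
        if "date_range" in corpus_raw:
            corpus_raw["date_range"] = tuple(
                dt.date.fromisoformat(d) for d in corpus_raw["date_range"])
        if "lines_per_song" in corpus_raw:
            corpus_raw["lines_per_song"] = tuple(corpus_raw["lines_per_song"])
        if "keyword_category_weights" in corpus_raw:
            corpus_raw["keyword_category_weights"] = tuple(
                corpus_raw["keyword_category_weights"])
        if "follower_distribution" in corpus_raw:
            corpus_raw["follower_distribution"] = tuple(
                corpus_raw["follower_distribution"])
        if "date_range" in raw and raw["date_range"] is not None:
            raw["date_range"] = tuple(
                dt.date.fromisoformat(d) for d in raw["date_range"])
        return cls(corpus=CorpusConfig(**corpus_raw), **raw)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineResult:
    stage_counts: pd.DataFrame          # per-year original/screened/matched
    matches: list[LyricMatch]
    monthly: pd.DataFrame
    output_dir: Path


def summarize_counts(per_year: pd.DataFrame) -> pd.Series:
    """Column-wise totals row over a per-year count table."""
    if len(per_year) < 1:
        raise LyricTraceError("need at least one year of counts")
    return per_year.drop(columns=["year"], errors="ignore").sum()


def _buffered(posts: Sequence[PostRecord],
              size: int) -> Iterator[Sequence[PostRecord]]:
    for i in range(0, len(posts), size):
        yield posts[i:i + size]


def screen_stream(batches: dict[str, list[PostRecord]],
                  lexicon: KeywordLexicon, threshold: float = 0.95,
                  buffer_size: int = 200
                  ) -> list[tuple[PostRecord, ScreenResult]]:
    """Keyword-screen every eligible post of an hourly batch stream."""
    screened: list[tuple[PostRecord, ScreenResult]] = []
    for key in sorted(batches):
        for chunk in _buffered(batches[key], buffer_size):
            for post in chunk:
                seq = tokenize(post.text)
                if not is_eligible(seq):
                    continue
                res = screen_post(seq, lexicon, threshold, post_id=post.id)
                if res is not None:
                    screened.append((post, res))
    return screened


def match_screened(screened: Sequence[tuple[PostRecord, ScreenResult]],
                   songs: list[SongSpec], index: InvertedIndex,
                   criteria: MatchCriteria,
                   scheme: ScoringScheme = ScoringScheme()
                   ) -> list[LyricMatch]:
    """Align each screened post against its candidate lyric lines."""
    matches: list[LyricMatch] = []
    for post, res in screened:
        m = detect_lyric(
            tokenize(post.text), index, songs, criteria, scheme,
            post_id=post.id,
            matched_keyword_categories=frozenset(
                c.value for c in res.categories()),
            matched_keywords=res.keywords(),
            created_at=post.created_at,
            followers_count=post.followers_count)
        if m is not None:
            matches.append(m)
    matches.sort(key=lambda m: m.post_id or "")
    return matches


_MATCH_COLUMNS = ("post_id", "song_id", "line_index", "score",
                  "matched_tokens", "artist", "title", "release_date",
                  "categories", "keywords")


def _matches_frame(matches: Sequence[LyricMatch]) -> pd.DataFrame:
    if not matches:
        return pd.DataFrame(columns=list(_MATCH_COLUMNS))
    return pd.DataFrame([{
        "post_id": m.post_id,
        "song_id": m.song_id,
        "line_index": m.line_index,
        "score": round(m.normalized_score, 6),
        "matched_tokens": m.matched_token_count,
        "artist": m.artist_name,
        "title": m.song_title,
        "release_date": m.release_date.isoformat(),
        "categories": "|".join(sorted(m.matched_keyword_categories)),
        "keywords": "|".join(m.matched_keywords),
    } for m in matches])


def run_pipeline(config: PipelineConfig,
                 generate: bool = False) -> PipelineResult:
    """Execute every stage in order, writing each stage's artifact.

    With ``generate=True`` the synthetic corpus configured under
    ``config.corpus`` is written to the input paths first; otherwise the
    input paths must already hold posts, lyrics and a lexicon.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_entries: list[dict] = []

    def log_stage(stage: str, t0: float, **counts) -> None:
        log_entries.append({"stage": stage,
                            "elapsed_s": round(time.perf_counter() - t0, 3),
                            **counts})

    def fail(stage: str, exc: Exception) -> LyricTraceError:
        return LyricTraceError(f"stage {stage!r} failed: {exc}")

    # -- generate ----------------------------------------------------------
    if generate:
        t0 = time.perf_counter()
        try:
            lexicon = build_lexicon(config.corpus)
            songs = generate_lyrics_db(config.corpus, lexicon)
            stream = generate_post_stream(config.corpus, songs, lexicon)
            lexicon.to_tsv(config.lexicon_path)
            write_lyrics_db(songs, config.lyrics_dir)
            write_post_batches(stream, config.posts_dir)
            write_ground_truth(stream.ground_truth,
                               Path(config.posts_dir).parent
                               / "ground_truth.jsonl")
        except Exception as exc:
            raise fail("generate", exc) from exc
        log_stage("generate", t0, songs=len(songs),
                  posts=sum(len(b) for b in stream.batches.values()),
                  missing_hours=len(stream.missing_hours))

    # -- load inputs -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        lexicon = KeywordLexicon.from_tsv(config.lexicon_path)
        songs = read_lyrics_db(config.lyrics_dir)
        batches = read_post_batches(config.posts_dir)
    except Exception as exc:
        raise fail("load", exc) from exc
    log_stage("load", t0, batches=len(batches), songs=len(songs),
              keywords=len(lexicon))

    if config.date_range is not None:
        date_range = config.date_range
    elif batches:
        keys = sorted(batches)
        date_range = (dt.date.fromisoformat(keys[0][:10]),
                      dt.date.fromisoformat(keys[-1][:10]))
    else:
        date_range = config.corpus.date_range

    # -- screen ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        screened = screen_stream(batches, lexicon, config.keyword_ratio,
                                 config.buffer_size)
        with (out / "screened.jsonl").open("w") as fh:
            for post, res in screened:
                fh.write(json.dumps({
                    "post_id": post.id,
                    "keywords": list(res.keywords()),
                    "ratios": [round(r, 4) for _, r in res.matched_entries],
                }) + "\n")
    except Exception as exc:
        raise fail("screen", exc) from exc
    log_stage("screen", t0, screened=len(screened))

    # -- match -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        index = build_index(songs)
        criteria = MatchCriteria(
            min_matched_content_tokens=config.min_matched_tokens,
            min_normalized_score=config.min_score)
        matches = match_screened(screened, songs, index, criteria)
        _matches_frame(matches).to_csv(out / "matches.csv", index=False)
    except Exception as exc:
        raise fail("match", exc) from exc
    log_stage("match", t0, matches=len(matches))

    # -- aggregate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        tally = trend_analytics.tally_categories(matches, lexicon)
        pd.DataFrame(
            [{"keyword": k, "category": next(
                e.category.value for e in lexicon.entries if e.surface == k),
              "posts": n}
             for k, n in sorted(tally.keyword_counts.items())]
        ).to_csv(out / "category_tally.csv", index=False)

        monthly = trend_analytics.monthly_series(matches, date_range)
        monthly[["year", "month", "count"]].to_csv(
            out / "monthly_counts.csv", index=False)

        summary_rows = []
        if matches:
            summary = trend_analytics.artist_summary(matches, songs)
            summary_rows = (
                [{"dimension": "gender", "value": k,
                  "count": summary.gender_counts[k],
                  "pct": summary.gender_pct[k]}
                 for k in sorted(summary.gender_counts)]
                + [{"dimension": "genre", "value": k,
                    "count": summary.genre_counts[k],
                    "pct": summary.genre_pct[k]}
                   for k in sorted(summary.genre_counts)])
        pd.DataFrame(summary_rows).to_csv(out / "artist_summary.csv",
                                          index=False)

        avail = trend_analytics.availability_report(batches.keys(),
                                                    date_range)
        avail.to_csv(out / "availability.csv", index=False)

        followers = [m.followers_count for m in matches
                     if m.followers_count is not None]
        if followers:
            hist = trend_analytics.follower_histogram(
                followers, config.histogram_bins)
            pd.DataFrame({
                "bin_left": hist.bin_edges[:-1],
                "bin_right": hist.bin_edges[1:],
                "count": hist.bin_counts,
            }).to_csv(out / "follower_histogram.csv", index=False)

        sample = trend_analytics.qa_sample(matches, config.qa_sample_size,
                                           config.min_score, config.qa_seed)
        _matches_frame(sample).to_csv(out / "qa_sample.csv", index=False)
    except Exception as exc:
        raise fail("aggregate", exc) from exc
    log_stage("aggregate", t0, tally_total=tally.grand_total)

    # -- forecast ----------------------------------------------------------
    t0 = time.perf_counter()
    metrics_rows = []
    try:
        if len(monthly) >= 3:
            split = forecasting.split_series(monthly, config.split_ratio)
            fit = forecasting.fit_ols(split.train)
            metrics = forecasting.evaluate(fit, split.test)
            metrics_rows.append({
                "model": "ols", "ratio": "2:1",
                "rmse": round(metrics.rmse, 2),
                "r2": round(metrics.r2, 5) if metrics.r2_defined else "",
                "slope": round(fit.m, 4), "intercept": round(fit.b, 4)})
            naive = forecasting.forecast_adapter(
                "seasonal_naive", split.train, len(split.test))
            y = split.test["count"].to_numpy(dtype=float)
            rmse = float(((y - naive) ** 2).mean() ** 0.5)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = (1.0 - float(((y - naive) ** 2).sum()) / ss_tot
                  if ss_tot > 0 else "")
            metrics_rows.append({
                "model": "seasonal_naive", "ratio": "2:1",
                "rmse": round(rmse, 2),
                "r2": round(r2, 5) if isinstance(r2, float) else "",
                "slope": "", "intercept": ""})
        pd.DataFrame(metrics_rows).to_csv(out / "forecast_metrics.csv",
                                          index=False)
    except Exception as exc:
        raise fail("forecast", exc) from exc
    log_stage("forecast", t0, models=len(metrics_rows))

    # -- stage counts ------------------------------------------------------
    per_year: dict[int, dict[str, int]] = {}
    for key, posts in batches.items():
        year = int(key[:4])
        per_year.setdefault(year, {"original": 0, "screened": 0,
                                   "matched": 0})["original"] += len(posts)
    for post, _ in screened:
        per_year[post.created_at.year]["screened"] += 1
    for m in matches:
        per_year[m.created_at.year]["matched"] += 1
    stage_counts = pd.DataFrame(
        [{"year": y, **counts} for y, counts in sorted(per_year.items())])
    if len(stage_counts):
        assert (stage_counts["screened"] <= stage_counts["original"]).all()
        assert (stage_counts["matched"] <= stage_counts["screened"]).all()
    stage_counts.to_csv(out / "stage_counts.csv", index=False)

    with log_path.open("w") as fh:
        for entry in log_entries:
            fh.write(json.dumps(entry) + "\n")

    return PipelineResult(stage_counts=stage_counts, matches=matches,
                          monthly=monthly, output_dir=out)
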