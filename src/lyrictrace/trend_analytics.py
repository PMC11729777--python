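"""Aggregation of accepted lyric matches into reporting surfaces.

Per-keyword / per-category tallies, a zero-filled monthly time series,
artist gender and song genre breakdowns, a year-end-chart cross-reference,
an equal-width follower histogram, a seeded QA sample for manual review,
and hourly-batch availability accounting.
"""

from __future__ import annotations

import datetime as dt
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (DataIntegrityError, FormatError, UndefinedInputError)
from .keyword_screen import KeywordLexicon
from .lyric_alignment import LyricMatch

__all__ = [
    "CategoryTally", "FollowerHistogram", "tally_categories",
    "aggregate_keyword_counts", "monthly_series", "artist_summary",
    "ArtistSummary", "billboard_crossref", "follower_histogram",
    "qa_sample", "availability_report", "complete_availability",
    "percentage_breakdown",
]


@dataclass(frozen=True)
class CategoryTally:
    keyword_counts: dict[str, int]           # keyword surface -> posts
    category_totals: dict[str, int]          # category -> posts
    grand_total: int


@dataclass(frozen=True)
class FollowerHistogram:
    bin_edges: np.ndarray   # 101 ascending reals
    bin_counts: np.ndarray  # 100 counts


def tally_categories(matches: Sequence[LyricMatch],
                     lexicon: KeywordLexicon) -> CategoryTally:
    """Per-keyword and per-category post counts.

    A match citing k distinct keywords increments each cited keyword once;
    category totals are sums over member keywords.
    """
    by_surface = {e.surface: e for e in lexicon.entries}
    kw_counts: Counter[str] = Counter()
    for m in matches:
        for kw in set(m.matched_keywords):
            if kw not in by_surface:
                raise DataIntegrityError(f"matched keyword {kw!r} not in lexicon")
            kw_counts[kw] += 1
    cat_totals: Counter[str] = Counter()
    for kw, n in kw_counts.items():
        cat_totals[by_surface[kw].category.value] += n
    return CategoryTally(keyword_counts=dict(kw_counts),
                         category_totals=dict(cat_totals),
                         grand_total=sum(cat_totals.values()))


def aggregate_keyword_counts(counts: pd.DataFrame) -> pd.Series:
    """Category totals from a per-keyword count table.

    ``counts`` needs columns ``keyword``, ``category`` and a numeric count
    column (``posts``).  Used to reduce published per-drug summaries the
    same way :func:`tally_categories` reduces detected matches.
    """
    for col in ("keyword", "category", "posts"):
        if col not in counts.columns:
            raise FormatError(f"keyword count table lacks column {col!r}")
    if counts["keyword"].duplicated().any():
        raise FormatError("duplicate keywords in count table")
    return counts.groupby("category")["posts"].sum()


def monthly_series(matches: Sequence[LyricMatch],
                   date_range: tuple[dt.date, dt.date]) -> pd.DataFrame:
    """Matches per calendar month (UTC) over the full date range.

    Returns a DataFrame with columns ``year``, ``month``, ``count`` and a
    0-based month index ``t``; months without matches appear with count 0.
    """
    start, end = date_range
    periods = pd.period_range(start=start, end=end, freq="M")
    counts = pd.Series(0, index=periods, dtype=int)
    for m in matches:
        if m.created_at is None:
            raise DataIntegrityError(f"match {m.post_id} lacks a timestamp")
        p = pd.Period(m.created_at.strftime("%Y-%m"), freq="M")
        if p not in counts.index:
            raise DataIntegrityError(
                f"match {m.post_id} timestamp {m.created_at} outside range")
        counts[p] += 1
    return pd.DataFrame({
        "year": [p.year for p in periods],
        "month": [p.month for p in periods],
        "count": counts.to_numpy(),
        "t": np.arange(len(periods)),
    })


def percentage_breakdown(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of a count mapping, rounded to 2 decimals."""
    total = sum(counts.values())
    if total == 0:
        raise UndefinedInputError("cannot take percentages of zero counts")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


@dataclass(frozen=True)
class ArtistSummary:
    gender_counts: dict[str, int]     # over distinct quoted artists
    gender_pct: dict[str, float]
    genre_counts: dict[str, int]      # over distinct quoted songs
    genre_pct: dict[str, float]


def artist_summary(matches: Sequence[LyricMatch],
                   songs: Sequence) -> ArtistSummary:
    """Gender breakdown over distinct quoted artists and genre breakdown
    over distinct quoted songs."""
    by_id = {s.song_id: s for s in songs}
    artists: dict[str, str] = {}
    genres: dict[str, str] = {}
    for m in matches:
        song = by_id.get(m.song_id)
        if song is None:
            raise DataIntegrityError(f"song {m.song_id} has no metadata")
        artists[song.artist_name] = song.artist_gender.value
        genres[song.song_id] = song.genre.value
    gender_counts = dict(Counter(artists.values()))
    genre_counts = dict(Counter(genres.values()))
    return ArtistSummary(
        gender_counts=gender_counts,
        gender_pct=percentage_breakdown(gender_counts) if artists else {},
        genre_counts=genre_counts,
        genre_pct=percentage_breakdown(genre_counts) if genres else {},
    )


_FEAT_RE = re.compile(r"\s+feat\b.*$")
_PUNCT_RE = re.compile(r"[^\w\s]")


def _norm_title_artist(text: str) -> str:
    text = text.lower()
    text = _PUNCT_RE.sub("", text)
    text = _FEAT_RE.sub("", text)
    return " ".join(text.split())


def billboard_crossref(matches: Sequence[LyricMatch], chart: pd.DataFrame,
                       songs: Sequence,
                       top_k: int = 20) -> dict[int, list[dict]]:
    """Per-year overlap between the top-k most quoted songs and a year-end
    chart fixture with columns ``year, rank, title, artist``.

    The join is a case-insensitive normalized (title, artist) equality;
    featuring credits after "feat" are stripped.
    """
    for col in ("year", "rank", "title", "artist"):
        if col not in chart.columns:
            raise FormatError(f"chart fixture lacks column {col!r}")
    if chart[["title", "artist"]].isna().any().any():
        raise FormatError("chart fixture contains empty title/artist cells")
    by_id = {s.song_id: s for s in songs}

    per_year: dict[int, Counter[str]] = {}
    for m in matches:
        if m.created_at is None:
            raise DataIntegrityError(f"match {m.post_id} lacks a timestamp")
        per_year.setdefault(m.created_at.year, Counter())[m.song_id] += 1

    chart_keys: dict[int, set[tuple[str, str]]] = {}
    for _, row in chart.iterrows():
        chart_keys.setdefault(int(row["year"]), set()).add(
            (_norm_title_artist(str(row["title"])),
             _norm_title_artist(str(row["artist"]))))

    hits: dict[int, list[dict]] = {}
    for year, counter in sorted(per_year.items()):
        ranked = sorted(
            counter.items(),
            key=lambda kv: (-kv[1], by_id[kv[0]].release_date, kv[0]))[:top_k]
        year_hits = []
        for song_id, n_posts in ranked:
            song = by_id[song_id]
            key = (_norm_title_artist(song.title),
                   _norm_title_artist(song.artist_name))
            if key in chart_keys.get(year, set()):
                year_hits.append({"song_id": song_id, "title": song.title,
                                  "artist": song.artist_name,
                                  "posts": n_posts})
        hits[year] = year_hits
    return hits


def follower_histogram(values: Iterable[int],
                       bins: int = 100) -> FollowerHistogram:
    """Equal-width histogram over [min, max] with the maximum value counted
    in the last bin; a degenerate range occupies a single bin."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise UndefinedInputError("follower histogram needs >= 1 value")
    counts, edges = np.histogram(arr, bins=bins,
                                 range=(arr.min(), arr.max()))
    return FollowerHistogram(bin_edges=edges, bin_counts=counts)


def qa_sample(matches: Sequence[LyricMatch], n: int = 1000,
              min_score: float = 0.5, seed: int = 0) -> list[LyricMatch]:
    """Seeded uniform without-replacement sample of matches with
    score >= min_score for manual review; all eligible matches are
    returned when fewer than ``n`` qualify."""
    eligible = [m for m in matches if m.normalized_score >= min_score]
    if len(eligible) <= n:
        return list(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


_BATCH_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})-(\d{2})$")


def availability_report(batch_names: Iterable[str],
                        date_range: tuple[dt.date, dt.date]) -> pd.DataFrame:
    """Per-year day/hour availability of hourly batches.

    A day counts as available when at least one of its hourly batches
    exists.  Missing = total - available for both days and hours.
    """
    start, end = date_range
    seen_hours: set[tuple[dt.date, int]] = set()
    for name in batch_names:
        stem = name.rsplit("/", 1)[-1].removesuffix(".jsonl")
        m = _BATCH_RE.match(stem)
        if m is None:
            raise FormatError(f"batch name {name!r} does not parse as "
                              "YYYY-MM-DD-HH")
        y, mo, d, h = map(int, m.groups())
        try:
            day = dt.date(y, mo, d)
        except ValueError as exc:
            raise FormatError(f"batch name {name!r}: {exc}") from exc
        if not (0 <= h <= 23):
            raise FormatError(f"batch name {name!r}: hour {h} invalid")
        seen_hours.add((day, h))

    rows = []
    for year in range(start.year, end.year + 1):
        y_start = max(start, dt.date(year, 1, 1))
        y_end = min(end, dt.date(year, 12, 31))
        total_days = (y_end - y_start).days + 1
        days_avail = len({d for d, _ in seen_hours if y_start <= d <= y_end})
        hours_avail = len([1 for d, _ in seen_hours if y_start <= d <= y_end])
        rows.append({
            "year": year,
            "total_days": total_days,
            "available_days": days_avail,
            "missing_days": total_days - days_avail,
            "total_hours": total_days * 24,
            "available_hours": hours_avail,
            "missing_hours": total_days * 24 - hours_avail,
        })
    return pd.DataFrame(rows)


def complete_availability(totals: pd.DataFrame) -> pd.DataFrame:
    """Fill in missing_days / missing_hours = total - available on a table
    with columns year, total_days, available_days, total_hours,
    available_hours."""
    need = ("year", "total_days", "available_days", "total_hours",
            "available_hours")
    for col in need:
        if col not in totals.columns:
            raise FormatError(f"availability table lacks column {col!r}")
    out = totals.copy()
    out["missing_days"] = out["total_days"] - out["available_days"]
    out["missing_hours"] = out["total_hours"] - out["available_hours"]
    return out
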