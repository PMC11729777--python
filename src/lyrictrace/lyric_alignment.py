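"""Lyric quote detection: candidate retrieval plus token-level local alignment.

A lyrics database is indexed by the Porter stems of each line's content
tokens.  For a screened post, every line sharing at least ``min_shared``
distinct stems with the post is retrieved (set intersection is an upper
bound on the number of in-order aligned matches, so no line that could
satisfy the acceptance criteria is missed).  Each candidate is then aligned
to the post with Smith-Waterman local alignment over stems -- the classic
dynamic program from biological sequence comparison, applied to words --
with unit scores (+1 match, -1 mismatch, -1 linear gap).  The raw score is
normalized by the length of the shorter sequence, so 1.0 means the shorter
side is perfectly embedded in the longer and 0.0 means no local similarity
at all.

A candidate is accepted when at least 3 stems match exactly in the optimal
local alignment and the normalized score reaches the acceptance floor
(default 0.5).  When several candidates are accepted the post is attributed
to a single song: highest score first, then earliest release date, then
smallest song id.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

from .errors import UndefinedInputError
from .textnorm import TokenSequence, content_view, tokenize

__all__ = [
    "LyricLine", "InvertedIndex", "ScoringScheme", "AlignmentResult",
    "MatchCriteria", "LyricMatch", "build_index", "retrieve_candidates",
    "smith_waterman", "detect_lyric", "select_attribution",
]


@dataclass(frozen=True)
class LyricLine:
    song_id: str
    line_index: int
    content_stems: tuple[str, ...]


@dataclass
class InvertedIndex:
    """Mapping content stem -> sorted postings of (song_id, line_index)."""
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    lines: dict[tuple[str, int], LyricLine] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoringScheme:
    match_reward: int = 1
    mismatch_penalty: int = -1
    gap_penalty: int = -1

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_penalty > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class AlignmentResult:
    raw_score: int
    matched_token_count: int
    normalized_score: float


@dataclass(frozen=True)
class MatchCriteria:
    min_matched_content_tokens: int = 3
    min_normalized_score: float = 0.5


@dataclass(frozen=True)
class LyricMatch:
    post_id: str | None
    song_id: str
    line_index: int
    normalized_score: float
    matched_token_count: int
    artist_name: str
    song_title: str
    release_date: dt.date
    matched_keyword_categories: frozenset[str] = frozenset()
    matched_keywords: tuple[str, ...] = ()
    created_at: dt.datetime | None = None
    followers_count: int | None = None


def build_index(songs: Sequence) -> InvertedIndex:
    """Index the content stems of every line of every song.

    ``songs`` are :class:`~lyrictrace.synthetic_corpus.SongSpec`-like
    objects with ``song_id`` and ``lines`` (raw line strings).
    """
    index = InvertedIndex()
    for song in songs:
        for li, raw in enumerate(song.lines):
            stems = tuple(t.stem for t in content_view(tokenize(raw)))
            line = LyricLine(song.song_id, li, stems)
            index.lines[(song.song_id, li)] = line
            for stem in set(stems):
                index.postings.setdefault(stem, []).append((song.song_id, li))
    for posting in index.postings.values():
        posting.sort()
    return index


def retrieve_candidates(query_stems: Sequence[str], index: InvertedIndex,
                        min_shared: int = 3) -> list[LyricLine]:
    """Lines sharing >= ``min_shared`` distinct stems with the query.

    Any line able to produce >= min_shared exact in-order matches shares at
    least that many distinct stems, so retrieval never loses an acceptable
    candidate.
    """
    distinct = set(query_stems)
    if len(distinct) < min_shared:
        return []
    counts: dict[tuple[str, int], int] = {}
    for stem in distinct:
        for ref in index.postings.get(stem, ()):
            counts[ref] = counts.get(ref, 0) + 1
    return [index.lines[ref]
            for ref in sorted(counts) if counts[ref] >= min_shared]


def smith_waterman(query_stems: Sequence[str], reference_stems: Sequence[str],
                   scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult:
    """Smith-Waterman local alignment over token stems.

    Raw score is the maximum cell of the local-alignment matrix;
    ``matched_token_count`` counts exact stem matches along one optimal
    traceback (diagonal preferred, then up, then left); the normalized
    score is ``max(raw, 0) / (match_reward * min(|query|, |reference|))``.
    """
    if not query_stems or not reference_stems:
        raise UndefinedInputError("cannot align an empty token sequence")
    q, r = list(query_stems), list(reference_stems)
    n, m = len(q), len(r)
    ma, mi, gp = scheme.match_reward, scheme.mismatch_penalty, scheme.gap_penalty

    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        qi = q[i - 1]
        row, above = H[i], H[i - 1]
        for j in range(1, m + 1):
            diag = above[j - 1] + (ma if qi == r[j - 1] else mi)
            val = diag
            if above[j] + gp > val:
                val = above[j] + gp
            if row[j - 1] + gp > val:
                val = row[j - 1] + gp
            if val < 0:
                val = 0
            row[j] = val
            if val > best:
                best, best_pos = val, (i, j)

    matched = 0
    i, j = best_pos
    while i > 0 and j > 0 and H[i][j] > 0:
        eq = q[i - 1] == r[j - 1]
        if H[i][j] == H[i - 1][j - 1] + (ma if eq else mi):
            matched += eq
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gp:
            i -= 1
        else:
            j -= 1

    normalized = max(best, 0) / (ma * min(n, m))
    return AlignmentResult(raw_score=best, matched_token_count=matched,
                           normalized_score=normalized)


def select_attribution(candidates: Sequence[LyricMatch]) -> LyricMatch:
    """Single-song attribution: best score, then earliest release, then
    lexicographically smallest song id.

    The earliest-release rule resolves near-duplicate lines covered by
    several songs in favour of the original recording.
    """
    if not candidates:
        raise ValueError("select_attribution requires at least one candidate")
    return min(candidates,
               key=lambda c: (-c.normalized_score, c.release_date, c.song_id))


def detect_lyric(seq: TokenSequence, index: InvertedIndex, songs: Sequence,
                 criteria: MatchCriteria = MatchCriteria(),
                 scheme: ScoringScheme = ScoringScheme(),
                 post_id: str | None = None,
                 matched_keyword_categories: frozenset[str] = frozenset(),
                 matched_keywords: tuple[str, ...] = (),
                 created_at: dt.datetime | None = None,
                 followers_count: int | None = None) -> LyricMatch | None:
    """Align a (screened, eligible) post against all retrieved candidate
    lines and return the single attributed match, or None."""
    query = [t.stem for t in content_view(seq)]
    if not query:
        return None
    by_id = {s.song_id: s for s in songs}
    accepted: list[LyricMatch] = []
    for line in retrieve_candidates(query, index,
                                    criteria.min_matched_content_tokens):
        res = smith_waterman(query, line.content_stems, scheme)
        if (res.matched_token_count >= criteria.min_matched_content_tokens
                and res.normalized_score >= criteria.min_normalized_score):
            song = by_id[line.song_id]
            accepted.append(LyricMatch(
                post_id=post_id,
                song_id=line.song_id,
                line_index=line.line_index,
                normalized_score=res.normalized_score,
                matched_token_count=res.matched_token_count,
                artist_name=song.artist_name,
                song_title=song.title,
                release_date=song.release_date,
                matched_keyword_categories=matched_keyword_categories,
                matched_keywords=matched_keywords,
                created_at=created_at,
                followers_count=followers_count,
            ))
    if not accepted:
        return None
    return select_attribution(accepted)
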