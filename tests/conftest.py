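import datetime as dt
from pathlib import Path

import pytest

from lyrictrace.lyric_alignment import LyricMatch
from lyrictrace.synthetic_corpus import (CorpusConfig, Gender, Genre,
                                         SongSpec)

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def reference_dir() -> Path:
    return REPO_ROOT / "data" / "reference"


@pytest.fixture(scope="session")
def small_config() -> CorpusConfig:
    """A ~200-post corpus: 4 days of hourly batches at 2 posts/hour."""
    return CorpusConfig(
        n_songs=15, n_drug_keywords=30,
        date_range=(dt.date(2016, 3, 1), dt.date(2016, 3, 4)),
        posts_per_hour=2.0, embed_rate=0.2,
        char_edit_rate=0.0, contraction_rate=0.0, bracket_rate=0.0,
        missing_hour_rate=0.0, seed=5)


@pytest.fixture(scope="session")
def quote_songs() -> list[SongSpec]:
    """Tiny hand-written lyrics database around a canonical quoted hook."""
    return [
        SongSpec(
            song_id="S0001", title="Forget You Tonight",
            artist_name="Test Artist", artist_gender=Gender.MALE,
            genre=Genre.RAP_HIPHOP, release_date=dt.date(2014, 10, 1),
            lines=(
                "And if I smoke this blunt, girl, I'm gon forget you",
                "Rolling through the city with my whole crew tonight",
            )),
        SongSpec(
            song_id="S0002", title="Midnight Lane",
            artist_name="Other Artist", artist_gender=Gender.FEMALE,
            genre=Genre.RNB_SOUL, release_date=dt.date(2016, 2, 2),
            lines=("Diamonds on my wrist and gold chains in the dark",)),
    ]


def make_match(post_id="p1", song_id="S0001", line_index=0, score=1.0,
               matched=4, artist="Test Artist", title="Forget You Tonight",
               release=dt.date(2014, 10, 1), categories=frozenset({"cannabinoid"}),
               keywords=("blunt", "smoke"),
               created=dt.datetime(2016, 3, 1, 12, tzinfo=dt.timezone.utc),
               followers=1200) -> LyricMatch:
    return LyricMatch(
        post_id=post_id, song_id=song_id, line_index=line_index,
        normalized_score=score, matched_token_count=matched,
        artist_name=artist, song_title=title, release_date=release,
        matched_keyword_categories=categories, matched_keywords=keywords,
        created_at=created, followers_count=followers)


@pytest.fixture
def match_factory():
    return make_match
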