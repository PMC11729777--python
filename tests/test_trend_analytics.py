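"""Aggregation surfaces: tallies, series, summaries, histogram, QA, availability."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lyrictrace.errors import (DataIntegrityError, FormatError,
                               UndefinedInputError)
from lyrictrace.keyword_screen import KeywordEntry, KeywordLexicon
from lyrictrace.synthetic_corpus import Gender, Genre, SongSpec
from lyrictrace.trend_analytics import (aggregate_keyword_counts,
                                        artist_summary, availability_report,
                                        billboard_crossref,
                                        complete_availability,
                                        follower_histogram, monthly_series,
                                        percentage_breakdown, qa_sample,
                                        tally_categories)
from tests.conftest import make_match

UTC = dt.timezone.utc


def lexicon():
    return KeywordLexicon((
        KeywordEntry.make("weed", "cannabinoid"),
        KeywordEntry.make("blunt", "cannabinoid"),
        KeywordEntry.make("molly", "stimulant_hallucinogen"),
        KeywordEntry.make("dope", "opioid"),
    ))


class TestTally:
    def test_each_cited_keyword_counted_once_per_match(self):
        matches = [
            make_match(post_id="p1", keywords=("weed", "blunt")),
            make_match(post_id="p2", keywords=("weed",)),
            make_match(post_id="p3", keywords=("dope", "dope")),  # dedup
        ]
        tally = tally_categories(matches, lexicon())
        assert tally.keyword_counts == {"weed": 2, "blunt": 1, "dope": 1}
        assert tally.category_totals == {"cannabinoid": 3, "opioid": 1}
        assert tally.grand_total == 4

    def test_empty_matches_zero_tally(self):
        tally = tally_categories([], lexicon())
        assert tally.keyword_counts == {} and tally.grand_total == 0

    def test_unknown_keyword_rejected(self):
        with pytest.raises(DataIntegrityError):
            tally_categories([make_match(keywords=("unknown",))], lexicon())

    def test_category_totals_from_published_count_table(self, reference_dir):
        counts = pd.read_csv(reference_dir / "keyword_post_counts.csv")
        totals = aggregate_keyword_counts(counts)
        assert totals["cannabinoid"] == 42_430
        assert totals["stimulant_hallucinogen"] == 23_949
        assert totals["opioid"] == 12_958


class TestMonthlySeries:
    RANGE = (dt.date(2015, 1, 1), dt.date(2015, 3, 31))

    def test_counts_land_in_their_month(self):
        matches = [make_match(post_id=f"p{i}",
                              created=dt.datetime(2015, 1, 10 + i, tzinfo=UTC))
                   for i in range(3)]
        series = monthly_series(matches, self.RANGE)
        assert list(series["count"]) == [3, 0, 0]
        assert list(series["t"]) == [0, 1, 2]

    def test_empty_matches_all_zero(self):
        series = monthly_series([], self.RANGE)
        assert list(series["count"]) == [0, 0, 0]

    def test_conservation_under_random_timestamps(self):
        rng = np.random.default_rng(4)
        matches = [
            make_match(post_id=f"p{i}", created=dt.datetime(
                2015, int(rng.integers(1, 4)), int(rng.integers(1, 29)),
                tzinfo=UTC))
            for i in range(200)]
        series = monthly_series(matches, self.RANGE)
        assert series["count"].sum() == 200

    def test_out_of_range_timestamp_rejected(self):
        bad = make_match(created=dt.datetime(2019, 1, 1, tzinfo=UTC))
        with pytest.raises(DataIntegrityError):
            monthly_series([bad], self.RANGE)


def song(song_id, artist, gender=Gender.MALE, genre=Genre.RAP_HIPHOP):
    return SongSpec(song_id=song_id, title=f"T {song_id}", artist_name=artist,
                    artist_gender=gender, genre=genre,
                    release_date=dt.date(2015, 1, 1), lines=("la la la",))


class TestArtistSummary:
    def test_published_gender_split_percentages(self):
        songs, matches = [], []
        for i in range(38):
            gender = Gender.MALE if i < 32 else Gender.FEMALE
            songs.append(song(f"S{i:02d}", f"Artist {i}", gender))
            matches.append(make_match(post_id=f"p{i}", song_id=f"S{i:02d}"))
        summary = artist_summary(matches, songs)
        assert summary.gender_counts == {"male": 32, "female": 6}
        assert summary.gender_pct == {"male": 84.21, "female": 15.79}
        assert abs(sum(summary.gender_pct.values()) - 100.0) <= 0.01

    def test_single_artist_is_hundred_percent(self):
        songs = [song("S1", "Solo", Gender.FEMALE)]
        summary = artist_summary([make_match(song_id="S1")], songs)
        assert summary.gender_pct == {"female": 100.0}

    def test_distinct_artists_not_matches_are_counted(self):
        songs = [song("S1", "A", Gender.MALE), song("S2", "A", Gender.MALE)]
        matches = [make_match(post_id=f"p{i}", song_id="S1") for i in range(5)]
        matches += [make_match(post_id="q", song_id="S2")]
        summary = artist_summary(matches, songs)
        assert summary.gender_counts == {"male": 1}

    def test_missing_metadata_rejected(self):
        with pytest.raises(DataIntegrityError):
            artist_summary([make_match(song_id="SX")], [])


class TestBillboardCrossref:
    def chart(self, rows):
        return pd.DataFrame(rows, columns=["year", "rank", "title", "artist"])

    def songs(self):
        return [song(f"S{i}", f"Artist {i}") for i in range(6)]

    def matches(self, year=2016):
        out = []
        for i in range(6):
            for k in range(6 - i):  # S0 most quoted
                out.append(make_match(
                    post_id=f"p{i}-{k}", song_id=f"S{i}",
                    created=dt.datetime(year, 5, 1, tzinfo=UTC)))
        return out

    def test_empty_chart_no_hits(self):
        hits = billboard_crossref(self.matches(), self.chart([]), self.songs())
        assert hits == {2016: []}

    def test_full_overlap_all_hits(self):
        rows = [(2016, i + 1, f"T S{i}", f"Artist {i}") for i in range(6)]
        hits = billboard_crossref(self.matches(), self.chart(rows),
                                  self.songs())
        assert len(hits[2016]) == 6

    def test_planted_overlap_count(self):
        rows = [(2016, r + 1, f"T S{i}", f"Artist {i}")
                for r, i in enumerate([0, 2, 4, 5])]
        rows += [(2015, 1, "Unrelated", "Nobody")]
        hits = billboard_crossref(self.matches(), self.chart(rows),
                                  self.songs())
        assert {h["song_id"] for h in hits[2016]} == {"S0", "S2", "S4", "S5"}

    def test_feat_credit_and_case_normalization(self):
        rows = [(2016, 1, "t s0!", "ARTIST 0 feat. Somebody Else")]
        hits = billboard_crossref(self.matches(), self.chart(rows),
                                  self.songs())
        assert [h["song_id"] for h in hits[2016]] == ["S0"]

    def test_malformed_chart_rejected(self):
        with pytest.raises(FormatError):
            billboard_crossref(self.matches(),
                               pd.DataFrame({"year": [2016]}), self.songs())


class TestFollowerHistogram:
    def test_uniform_integers_boundary_convention(self):
        hist = follower_histogram(range(101))  # 0..100
        assert len(hist.bin_edges) == 101 and len(hist.bin_counts) == 100
        widths = np.diff(hist.bin_edges)
        assert np.allclose(widths, 1.0)
        assert hist.bin_counts[-1] == 2  # 99 and the max value 100
        assert hist.bin_counts[:-1].tolist() == [1] * 99

    def test_degenerate_range_single_bin(self):
        hist = follower_histogram([7, 7, 7])
        assert hist.bin_counts.sum() == 3
        assert (hist.bin_counts > 0).sum() == 1

    def test_conservation_lognormal(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(6, 2, size=10_000).astype(int)
        hist = follower_histogram(values)
        assert hist.bin_counts.sum() == 10_000

    def test_empty_rejected(self):
        with pytest.raises(UndefinedInputError):
            follower_histogram([])


class TestQaSample:
    def pool(self, n=30):
        return [make_match(post_id=f"p{i:03d}",
                           score=0.5 + 0.5 * (i % 10) / 10) for i in range(n)]

    def test_seeded_determinism(self):
        pool = self.pool()
        a = qa_sample(pool, n=10, seed=3)
        b = qa_sample(pool, n=10, seed=3)
        assert [m.post_id for m in a] == [m.post_id for m in b]

    def test_small_pool_returned_whole(self):
        pool = self.pool(5)
        assert len(qa_sample(pool, n=1000, seed=0)) == 5

    def test_score_floor_applied(self):
        pool = [make_match(post_id="lo", score=0.4),
                make_match(post_id="hi", score=0.9)]
        assert [m.post_id for m in qa_sample(pool, n=10, seed=0)] == ["hi"]

    def test_inclusion_uniformity_chi_square(self):
        pool = self.pool(20)
        counts = np.zeros(20)
        reps, k = 2000, 5
        for seed in range(reps):
            for m in qa_sample(pool, n=k, seed=seed):
                counts[int(m.post_id[1:])] += 1
        expected = reps * k / 20
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)


class TestAvailability:
    def test_full_coverage_no_missing(self):
        names = [f"2016-06-{d:02d}-{h:02d}" for d in (1, 2) for h in range(24)]
        rep = availability_report(names, (dt.date(2016, 6, 1),
                                          dt.date(2016, 6, 2)))
        row = rep.iloc[0]
        assert row["missing_hours"] == 0 and row["missing_days"] == 0

    def test_withheld_hours_counted(self):
        names = [f"2016-06-01-{h:02d}" for h in range(24)]
        withheld = {"2016-06-01-03", "2016-06-01-07", "2016-06-01-11",
                    "2016-06-01-15", "2016-06-01-19"}
        present = [n for n in names if n not in withheld]
        rep = availability_report(present, (dt.date(2016, 6, 1),
                                            dt.date(2016, 6, 1)))
        assert rep.iloc[0]["missing_hours"] == 5
        assert rep.iloc[0]["available_days"] == 1  # >=1 batch exists

    def test_missing_plus_available_equals_total(self):
        rng = np.random.default_rng(1)
        names = [f"2015-{m:02d}-{d:02d}-{h:02d}"
                 for m in range(1, 13) for d in range(1, 28)
                 for h in range(24) if rng.random() < 0.8]
        rep = availability_report(names, (dt.date(2015, 1, 1),
                                          dt.date(2015, 12, 31)))
        for _, row in rep.iterrows():
            assert row["available_hours"] + row["missing_hours"] == \
                row["total_hours"]
            assert row["available_days"] + row["missing_days"] == \
                row["total_days"]

    def test_published_year_arithmetic(self, reference_dir):
        totals = pd.read_csv(reference_dir / "hourly_availability.csv")
        table = complete_availability(totals).set_index("year")
        assert table.loc[2015, "missing_hours"] == 964
        assert table.loc[2015, "missing_days"] == 37
        assert table.loc[2017, "missing_hours"] == 654

    def test_unparseable_batch_name_rejected(self):
        with pytest.raises(FormatError):
            availability_report(["2016-06-01"], (dt.date(2016, 6, 1),
                                                 dt.date(2016, 6, 1)))


class TestPercentages:
    def test_rounding_and_sum(self):
        pct = percentage_breakdown({"a": 1, "b": 1, "c": 1})
        assert pct == {"a": 33.33, "b": 33.33, "c": 33.33}
        assert abs(sum(pct.values()) - 100.0) <= 0.02

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedInputError):
            percentage_breakdown({})
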