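"""Ground-truthed corpus generation: lexicon, lyrics DB, noise, post stream."""

import datetime as dt

import numpy as np
import pytest

from lyrictrace._stopwords import STOPWORDS
from lyrictrace.errors import ConfigurationError
from lyrictrace.keyword_screen import Category
from lyrictrace.synthetic_corpus import (BACKGROUND_VOCAB, LYRIC_VOCAB,
                                         CorpusConfig, apply_char_edits,
                                         build_lexicon, corrupt_text,
                                         generate_lyrics_db,
                                         generate_post_stream,
                                         read_ground_truth, read_lyrics_db,
                                         read_post_batches,
                                         write_ground_truth, write_lyrics_db,
                                         write_post_batches)
from lyrictrace.textnorm import content_view, tokenize


def stems_of(word_list):
    out = set()
    for w in word_list:
        out |= {t.stem for t in content_view(tokenize(w))}
    return out


TWO_DAYS = (dt.date(2016, 6, 1), dt.date(2016, 6, 2))


class TestVocabularies:
    def test_lyric_and_background_vocab_disjoint_to_the_stem(self):
        assert stems_of(LYRIC_VOCAB) & stems_of(BACKGROUND_VOCAB) == set()

    def test_vocab_words_are_content_words(self):
        for w in (*LYRIC_VOCAB, *BACKGROUND_VOCAB):
            assert w not in STOPWORDS
            assert len(content_view(tokenize(w))) == 1


class TestBuildLexicon:
    def test_seeded_determinism(self):
        cfg = CorpusConfig(seed=7, n_drug_keywords=50)
        assert build_lexicon(cfg) == build_lexicon(cfg)

    def test_degenerate_weights_single_category(self):
        cfg = CorpusConfig(n_drug_keywords=30,
                           keyword_category_weights=(1.0, 0.0, 0.0, 0.0))
        lex = build_lexicon(cfg)
        assert all(e.category is Category.CANNABINOID for e in lex.entries)
        assert len(lex) == 30

    def test_uniform_weights_multinomial_balance(self):
        # n=400, p=1/4 per category: SD = sqrt(400*.25*.75) ~ 8.66
        cfg = CorpusConfig(n_drug_keywords=400,
                           keyword_category_weights=(.25, .25, .25, .25),
                           seed=7)
        lex = build_lexicon(cfg)
        counts = {c: len(v) for c, v in lex.by_category().items()}
        for c, n in counts.items():
            assert abs(n - 100) <= 3 * 8.66, (c, n)

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            CorpusConfig(keyword_category_weights=(0.5, 0.5, 0.5, 0.5))

    def test_too_few_keywords_rejected(self):
        with pytest.raises(ConfigurationError):
            build_lexicon(CorpusConfig(n_drug_keywords=3))

    def test_multiword_entries_possible(self):
        lex = build_lexicon(CorpusConfig(n_drug_keywords=60))
        assert any(e.n_words > 1 for e in lex.entries)


class TestGenerateLyricsDb:
    def test_zero_songs_empty_db(self):
        cfg = CorpusConfig(n_songs=0, n_drug_keywords=20)
        assert generate_lyrics_db(cfg, build_lexicon(cfg)) == []

    def test_seeded_determinism(self):
        cfg = CorpusConfig(n_songs=8, n_drug_keywords=20, seed=3)
        lex = build_lexicon(cfg)
        assert generate_lyrics_db(cfg, lex) == generate_lyrics_db(cfg, lex)

    def test_every_line_has_three_content_tokens(self):
        cfg = CorpusConfig(n_songs=10, n_drug_keywords=20, seed=3)
        songs = generate_lyrics_db(cfg, build_lexicon(cfg))
        for song in songs:
            for line in song.lines:
                assert len(content_view(tokenize(line))) >= 3

    def test_song_invariants(self):
        cfg = CorpusConfig(n_songs=12, n_drug_keywords=20, seed=3)
        songs = generate_lyrics_db(cfg, build_lexicon(cfg))
        ids = [s.song_id for s in songs]
        assert len(ids) == len(set(ids)) == 12
        lo, hi = cfg.date_range
        for s in songs:
            assert lo <= s.release_date <= hi
            assert len(s.lines) >= 1

    def test_configured_fraction_of_lines_carry_keywords(self):
        cfg = CorpusConfig(n_songs=30, n_drug_keywords=40, seed=3,
                           keyword_line_rate=0.5)
        lex = build_lexicon(cfg)
        kw_stems = stems_of([e.surface for e in lex.entries])
        songs = generate_lyrics_db(cfg, lex)
        lines = [ln for s in songs for ln in s.lines]
        with_kw = sum(
            1 for ln in lines
            if {t.stem for t in content_view(tokenize(ln))} & kw_stems)
        frac = with_kw / len(lines)
        assert 0.35 < frac < 0.65  # ~3 SD around 0.5 for ~330 lines


class TestCorruptText:
    def test_zero_rates_identity(self):
        cfg = CorpusConfig(char_edit_rate=0, contraction_rate=0,
                           bracket_rate=0)
        rng = np.random.default_rng(0)
        line = "Smoke good weed tonight"
        assert corrupt_text(line, cfg, rng) == line

    def test_full_rate_changes_single_character(self):
        cfg = CorpusConfig(char_edit_rate=1.0, contraction_rate=0,
                           bracket_rate=0)
        rng = np.random.default_rng(1)
        assert corrupt_text("a", cfg, rng) != "a"

    def test_edit_count_binomial_oracle(self):
        # rate 0.05 over 10,000 chars: 500 +- 3*sqrt(10000*.05*.95) ~ 65
        rng = np.random.default_rng(2)
        _, n_edits = apply_char_edits("x" * 10_000, 0.05, rng)
        assert abs(n_edits - 500) <= 3 * np.sqrt(10_000 * 0.05 * 0.95)

    def test_contraction_applied(self):
        cfg = CorpusConfig(char_edit_rate=0, contraction_rate=1.0,
                           bracket_rate=0)
        rng = np.random.default_rng(0)
        assert corrupt_text("i am going to leave", cfg, rng) == \
            "i am gon leave"

    def test_bracket_filler_inserted(self):
        cfg = CorpusConfig(char_edit_rate=0, contraction_rate=0,
                           bracket_rate=1.0)
        rng = np.random.default_rng(0)
        out = corrupt_text("smoke weed tonight", cfg, rng)
        assert "[" in out and "]" in out


class TestPostStream:
    def _generated(self, **overrides):
        kwargs = dict(n_songs=10, n_drug_keywords=20,
                      date_range=TWO_DAYS, posts_per_hour=4.0,
                      missing_hour_rate=0.0, char_edit_rate=0.0,
                      contraction_rate=0.0, bracket_rate=0.0, seed=9)
        kwargs.update(overrides)
        cfg = CorpusConfig(**kwargs)
        lex = build_lexicon(cfg)
        songs = generate_lyrics_db(cfg, lex)
        return cfg, songs, lex, generate_post_stream(cfg, songs, lex)

    def test_embed_rate_zero_only_background(self):
        _, _, _, stream = self._generated(embed_rate=0.0)
        assert all(e.label == "background"
                   for e in stream.ground_truth.values())

    def test_no_missing_hours_means_full_batches(self):
        _, _, _, stream = self._generated()
        assert len(stream.batches) == 48 and stream.missing_hours == []

    def test_batches_plus_missing_cover_every_hour(self):
        _, _, _, stream = self._generated(missing_hour_rate=0.3)
        assert len(stream.batches) + len(stream.missing_hours) == 48
        assert set(stream.batches) & set(stream.missing_hours) == set()

    def test_embedded_count_binomial_oracle(self):
        cfg, songs, lex, stream = self._generated(
            embed_rate=0.1, posts_per_hour=25.0)
        n = len(stream.ground_truth)
        quotes = sum(1 for e in stream.ground_truth.values()
                     if e.label == "quote")
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(quotes - 0.1 * n) <= 3 * sd

    def test_ground_truth_covers_every_post_once(self):
        _, _, _, stream = self._generated(embed_rate=0.2)
        post_ids = [p.id for batch in stream.batches.values() for p in batch]
        assert len(post_ids) == len(set(post_ids))
        assert set(post_ids) == set(stream.ground_truth)

    def test_clean_quotes_are_exact_normalized_substrings(self):
        _, songs, _, stream = self._generated(embed_rate=0.3)
        lines = {(s.song_id, i): [t.surface for t in tokenize(ln).tokens]
                 for s in songs for i, ln in enumerate(s.lines)}
        by_id = {p.id: p for b in stream.batches.values() for p in b}
        quotes = [e for e in stream.ground_truth.values()
                  if e.label == "quote"]
        assert quotes
        for e in quotes:
            post_tokens = [t.surface for t in
                           tokenize(by_id[e.post_id].text).tokens]
            ref = lines[(e.song_id, e.line_index)]
            joined, target = " ".join(post_tokens), " ".join(ref)
            assert target in joined

    def test_bit_identical_regeneration(self):
        cfg, songs, lex, stream1 = self._generated(embed_rate=0.2)
        stream2 = generate_post_stream(cfg, songs, lex)
        assert stream1.batches == stream2.batches
        assert stream1.ground_truth == stream2.ground_truth
        assert stream1.missing_hours == stream2.missing_hours

    def test_empty_date_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CorpusConfig(date_range=(dt.date(2016, 2, 2), dt.date(2016, 1, 1)))


class TestRoundTrips:
    def test_posts_lyrics_and_truth_survive_io(self, tmp_path, small_config):
        cfg = small_config
        lex = build_lexicon(cfg)
        songs = generate_lyrics_db(cfg, lex)
        stream = generate_post_stream(cfg, songs, lex)

        write_post_batches(stream, tmp_path / "posts")
        write_lyrics_db(songs, tmp_path / "lyrics")
        write_ground_truth(stream.ground_truth, tmp_path / "truth.jsonl")

        assert read_post_batches(tmp_path / "posts") == stream.batches
        assert read_lyrics_db(tmp_path / "lyrics") == songs
        assert read_ground_truth(tmp_path / "truth.jsonl") == \
            stream.ground_truth

    def test_batch_files_named_by_hour(self, tmp_path, small_config):
        cfg = small_config
        lex = build_lexicon(cfg)
        songs = generate_lyrics_db(cfg, lex)
        stream = generate_post_stream(cfg, songs, lex)
        write_post_batches(stream, tmp_path / "posts")
        names = sorted(p.name for p in (tmp_path / "posts").glob("*.jsonl"))
        assert names[0] == "2016-03-01-00.jsonl"
        assert len(names) == len(stream.batches)
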