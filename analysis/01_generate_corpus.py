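#!/usr/bin/env python
"""Generate the study-shaped synthetic corpus.

Writes a three-year hourly post stream (2015-2017), a lyrics database and
a drug-keyword lexicon to scratch/corpus/, plus the sidecar ground truth.
Quote posts carry mild realistic noise (2%/char edits, contractions,
bracketed filler); ~11% of hourly batches are withheld to emulate
collection outages.
"""

import datetime as dt
import sys
from pathlib import Path

from lyrictrace.synthetic_corpus import (CorpusConfig, build_lexicon,
                                         generate_lyrics_db,
                                         generate_post_stream,
                                         write_ground_truth, write_lyrics_db,
                                         write_post_batches)

REPO = Path(__file__).resolve().parent.parent
CORPUS_DIR = REPO / "scratch" / "corpus"

CONFIG = CorpusConfig(
    n_songs=60, n_drug_keywords=190,
    date_range=(dt.date(2015, 1, 1), dt.date(2017, 12, 31)),
    posts_per_hour=2.0, embed_rate=0.1,
    char_edit_rate=0.02, contraction_rate=0.1, bracket_rate=0.05,
    missing_hour_rate=0.11, seed=2015)


def main() -> int:
    lexicon = build_lexicon(CONFIG)
    songs = generate_lyrics_db(CONFIG, lexicon)
    stream = generate_post_stream(CONFIG, songs, lexicon)

    lexicon.to_tsv(CORPUS_DIR / "lexicon.tsv")
    write_lyrics_db(songs, CORPUS_DIR / "lyrics")
    write_post_batches(stream, CORPUS_DIR / "posts")
    write_ground_truth(stream.ground_truth, CORPUS_DIR / "ground_truth.jsonl")

    n_posts = sum(len(b) for b in stream.batches.values())
    n_quotes = sum(1 for e in stream.ground_truth.values()
                   if e.label == "quote")
    print(f"corpus written to {CORPUS_DIR}")
    print(f"  {len(lexicon)} keywords, {len(songs)} songs, "
          f"{sum(len(s.lines) for s in songs)} lines")
    print(f"  {n_posts} posts in {len(stream.batches)} hourly batches "
          f"({len(stream.missing_hours)} hours withheld)")
    print(f"  {n_quotes} posts quote a lyric line "
          f"({n_quotes / n_posts:.1%})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
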