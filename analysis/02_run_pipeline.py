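#!/usr/bin/env python
"""Screen, match and aggregate the generated corpus.

Runs the full detection pipeline over scratch/corpus/ (built by
01_generate_corpus.py) and copies the reporting tables -- per-year stage
counts, category tally, artist/genre summary, monthly series, batch
availability and forecast metrics -- into results/.
"""

import datetime as dt
import shutil
import sys
from pathlib import Path

import pandas as pd

from lyrictrace.pipeline import PipelineConfig, run_pipeline, summarize_counts

REPO = Path(__file__).resolve().parent.parent
CORPUS_DIR = REPO / "scratch" / "corpus"
OUT_DIR = REPO / "scratch" / "pipeline_output"
RESULTS = REPO / "results"

TABLES = ("stage_counts.csv", "category_tally.csv", "artist_summary.csv",
          "monthly_counts.csv", "availability.csv", "forecast_metrics.csv")


def main() -> int:
    if not (CORPUS_DIR / "lexicon.tsv").exists():
        print("corpus missing; run analysis/01_generate_corpus.py first",
              file=sys.stderr)
        return 1
    config = PipelineConfig(
        posts_dir=str(CORPUS_DIR / "posts"),
        lyrics_dir=str(CORPUS_DIR / "lyrics"),
        lexicon_path=str(CORPUS_DIR / "lexicon.tsv"),
        output_dir=str(OUT_DIR),
        date_range=(dt.date(2015, 1, 1), dt.date(2017, 12, 31)))
    result = run_pipeline(config)

    RESULTS.mkdir(exist_ok=True)
    for name in TABLES:
        shutil.copy(OUT_DIR / name, RESULTS / name)

    counts = result.stage_counts
    totals = summarize_counts(counts)
    print("per-year stage counts (original -> screened -> matched):")
    print(counts.to_string(index=False))
    print(f"totals: {int(totals['original'])} posts, "
          f"{int(totals['screened'])} screened, "
          f"{int(totals['matched'])} lyric matches")
    tally = pd.read_csv(RESULTS / "category_tally.csv")
    print("\nmatches by drug category:")
    print(tally.groupby("category")["posts"].sum().to_string())
    print(f"\ntables copied to {RESULTS}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
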