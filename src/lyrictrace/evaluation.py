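"""Detection quality against synthetic-corpus ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .lyric_alignment import LyricMatch
from .synthetic_corpus import GroundTruth

__all__ = ["DetectionReport", "score_detection"]


@dataclass(frozen=True)
class DetectionReport:
    n_quotes: int              # embedded quote posts in the ground truth
    n_background: int
    n_detected_true: int       # quotes detected AND attributed to the true song
    n_false_positives: int     # background posts with any accepted match

    @property
    def recall(self) -> float:
        return self.n_detected_true / self.n_quotes if self.n_quotes else 1.0

    @property
    def false_positive_rate(self) -> float:
        return (self.n_false_positives / self.n_background
                if self.n_background else 0.0)


def score_detection(matches: Sequence[LyricMatch],
                    truth: GroundTruth) -> DetectionReport:
    """Recall over embedded quotes (correct-song attribution required) and
    false-positive rate over background posts."""
    by_post = {m.post_id: m for m in matches}
    n_quotes = n_background = n_true = n_fp = 0
    for post_id, entry in truth.items():
        m = by_post.get(post_id)
        if entry.label == "quote":
            n_quotes += 1
            if m is not None and m.song_id == entry.song_id:
                n_true += 1
        else:
            n_background += 1
            if m is not None:
                n_fp += 1
    return DetectionReport(n_quotes=n_quotes, n_background=n_background,
                           n_detected_true=n_true, n_false_positives=n_fp)
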