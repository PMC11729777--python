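"""First-pass drug-keyword screen.

A post survives screening when at least one of its content-token lemmas
(or adjacent-token bigrams, for multiword lexicon entries such as
"mary jane") matches a lexicon keyword with normalized Levenshtein ratio

    ratio(a, b) = 1 - d(a, b) / max(|a|, |b|)

at or above a threshold (default 0.95).  The ratio tolerates small
character-level variance only for long terms: for max(|a|, |b|) <= 19 a
single edit already drops the ratio below 0.95, so short tokens must match
exactly, while e.g. ``tetrahydrocannabinols`` -> ``tetrahydrocannabinol``
(distance 1 over length 21, ratio 0.9524) still passes.

``screen_post`` exploits that algebra: a pair can only pass when
``|len(a) - len(b)| <= (1 - t) * maxlen`` and, if the strings differ, when
``(1 - t) * maxlen >= 1``.  Pairs outside those bounds are skipped without
running the dynamic program; the result is identical to the naive
all-pairs scan (property-tested).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, FormatError
from .textnorm import TokenSequence, content_view, lemmatize

__all__ = [
    "Category", "KeywordEntry", "KeywordLexicon", "ScreenResult",
    "levenshtein", "match_ratio", "screen_post",
]


class Category(str, Enum):
    CANNABINOID = "cannabinoid"
    STIMULANT_HALLUCINOGEN = "stimulant_hallucinogen"
    OPIOID = "opioid"
    OTHER = "other"


@dataclass(frozen=True)
class KeywordEntry:
    surface: str           # lowercased; words separated by single spaces
    lemma: str
    category: Category
    n_words: int

    @classmethod
    def make(cls, surface: str, category: Category | str) -> "KeywordEntry":
        surface = " ".join(surface.lower().split())
        lemma = " ".join(lemmatize(w) for w in surface.split())
        return cls(surface=surface, lemma=lemma,
                   category=Category(category), n_words=len(surface.split()))


@dataclass(frozen=True)
class KeywordLexicon:
    entries: tuple[KeywordEntry, ...]

    def __post_init__(self) -> None:
        surfaces = [e.surface for e in self.entries]
        if len(surfaces) != len(set(surfaces)):
            raise ConfigurationError("duplicate keyword surfaces in lexicon")

    def __len__(self) -> int:
        return len(self.entries)

    def by_category(self) -> dict[Category, list[KeywordEntry]]:
        out: dict[Category, list[KeywordEntry]] = {c: [] for c in Category}
        for e in self.entries:
            out[e.category].append(e)
        return out

    def surfaces(self) -> set[str]:
        return {e.surface for e in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{e.surface}\t{e.category.value}" for e in self.entries]
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordLexicon":
        entries = []
        for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'keyword<TAB>category'")
            try:
                entries.append(KeywordEntry.make(parts[0], parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
        return cls(entries=tuple(entries))


@dataclass(frozen=True)
class ScreenResult:
    post_id: str | None
    matched_entries: tuple[tuple[KeywordEntry, float], ...]

    def categories(self) -> frozenset[Category]:
        return frozenset(e.category for e, _ in self.matched_entries)

    def keywords(self) -> tuple[str, ...]:
        return tuple(sorted({e.surface for e, _ in self.matched_entries}))


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b`` (unit costs)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1,          # deletion
                           cur[j - 1] + 1,       # insertion
                           prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


def match_ratio(a: str, b: str) -> float:
    """Length-normalized Levenshtein similarity in [0, 1].

    Two empty strings are defined to match perfectly (ratio 1.0).
    """
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def _pairs_to_compare(token_lemma: str, entry: KeywordEntry,
                      threshold: float) -> float | None:
    """Ratio of the pair if it can possibly reach the threshold, else None."""
    a, b = token_lemma, entry.lemma
    maxlen = max(len(a), len(b))
    if maxlen == 0:
        return 1.0
    budget = (1.0 - threshold) * maxlen  # largest edit distance that passes
    if abs(len(a) - len(b)) > budget:
        return None
    if a == b:
        return 1.0
    if budget < 1.0:
        return None  # unequal strings need at least one edit
    r = match_ratio(a, b)
    return r


def screen_post(seq: TokenSequence, lexicon: KeywordLexicon,
                threshold: float = 0.95,
                post_id: str | None = None) -> ScreenResult | None:
    """Return all lexicon matches at ratio >= threshold, or None.

    Comparison is on lemmas; multiword entries are matched against the
    space-joined bigrams of adjacent content tokens.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError(f"threshold {threshold} outside [0, 1]")
    content = content_view(seq)
    if not content:
        return None
    unigrams = [t.lemma for t in content]
    bigrams = [f"{a} {b}" for a, b in zip(unigrams, unigrams[1:])]

    # An unequal pair needs maxlen >= 1/(1-t) and |len diff| <= (1-t)*maxlen,
    # which is only satisfiable when the entry lemma has length >= t/(1-t)
    # (19 characters at the default threshold).  Shorter entries can only
    # match exactly, so they are resolved by hash lookup.
    fuzzy_min_len = threshold / (1.0 - threshold) if threshold < 1.0 else None

    hits: dict[KeywordEntry, float] = {}
    uni_set, bi_set = set(unigrams), set(bigrams)
    for entry in lexicon.entries:
        grams = uni_set if entry.n_words == 1 else bi_set
        if entry.lemma in grams:
            hits[entry] = 1.0
            continue
        if fuzzy_min_len is None or len(entry.lemma) < fuzzy_min_len:
            continue
        queries: Iterable[str] = unigrams if entry.n_words == 1 else bigrams
        best = None
        for q in queries:
            r = _pairs_to_compare(q, entry, threshold)
            if r is not None and r >= threshold:
                best = r if best is None else max(best, r)
        if best is not None:
            hits[entry] = best
    if not hits:
        return None
    matched = tuple(sorted(hits.items(), key=lambda kv: kv[0].surface))
    return ScreenResult(post_id=post_id, matched_entries=matched)
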