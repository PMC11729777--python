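"""Deterministic post and lyric normalization.

A post or lyric line is reduced to an ordered :class:`TokenSequence`:
URLs, @-mentions, emojis and punctuation are stripped, bracketed
annotations lose their brackets but keep their words, the remaining words
are lowercased, and every token carries its lemma (used by the keyword
screen), its Porter stem (used by the alignment stage) and a stop-word
flag.  Apostrophes are dropped without splitting, so ``I'm`` becomes the
single token ``im``.

Both the screening and alignment stages operate on the *content view* of
a sequence -- the non-stop-word tokens in original order -- and a post is
eligible for lyric matching only if that view holds at least three tokens.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from ._porter import porter_stem
from ._stopwords import STOPWORDS

__all__ = ["Token", "TokenSequence", "tokenize", "content_view", "is_eligible"]


@dataclass(frozen=True)
class Token:
    surface: str          # lowercased, apostrophes removed
    lemma: str
    stem: str
    is_stopword: bool
    char_span: tuple[int, int]  # [start, end) offsets into the source text


@dataclass(frozen=True)
class TokenSequence:
    source_text: str
    tokens: tuple[Token, ...]

    def __len__(self) -> int:  # number of tokens, stop words included
        return len(self.tokens)


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")

# Unicode blocks treated as emoji / pictographs.
_EMOJI_RANGES = (
    (0x1F000, 0x1FAFF),   # mahjong .. symbols & pictographs extended
    (0x2600, 0x27BF),     # misc symbols, dingbats
    (0x2B00, 0x2BFF),
    (0xFE00, 0xFE0F),     # variation selectors
    (0x200D, 0x200D),     # zero-width joiner
)

_APOSTROPHES = {"'", "’", "ʼ"}

# Irregular noun plurals the suffix rules below cannot reach.
_IRREGULAR_LEMMAS = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose", "lives": "life",
    "leaves": "leaf", "wives": "wife", "knives": "knife",
}


def is_emoji(char: str) -> bool:
    """True for characters in emoji/pictograph blocks or symbol categories."""
    cp = ord(char)
    if any(lo <= cp <= hi for lo, hi in _EMOJI_RANGES):
        return True
    return unicodedata.category(char) in ("So", "Sk", "Cs")


def lemmatize(surface: str) -> str:
    """Noun-style lemma: map plural surface forms to their singular base.

    Deliberately light -- it mirrors dictionary-lookup lemmatization run
    with a default noun part of speech, which is what keyword screening
    needs (drug terms are nouns).
    """
    w = surface
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if len(w) > 3 and w.endswith(("ches", "shes", "xes", "zes")):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def _removal_spans(text: str) -> list[tuple[int, int]]:
    spans = [m.span() for m in _URL_RE.finditer(text)]
    spans += [m.span() for m in _MENTION_RE.finditer(text)]
    return sorted(spans)


def tokenize(text: str) -> TokenSequence:
    """Normalize ``text`` into a TokenSequence.

    Empty input yields an empty sequence.  Deterministic, and idempotent on
    text that is already in normalized surface form.
    """
    skip = _removal_spans(text)
    skip_iter = iter(skip)
    cur_skip = next(skip_iter, None)

    tokens: list[Token] = []
    buf: list[str] = []
    start = end = -1

    def flush() -> None:
        nonlocal buf, start, end
        if buf:
            surface = "".join(buf)
            lemma = lemmatize(surface)
            tokens.append(
                Token(
                    surface=surface,
                    lemma=lemma,
                    stem=porter_stem(surface),
                    is_stopword=surface in STOPWORDS,
                    char_span=(start, end),
                )
            )
        buf, start, end = [], -1, -1

    for i, ch in enumerate(text):
        while cur_skip is not None and i >= cur_skip[1]:
            cur_skip = next(skip_iter, None)
        if cur_skip is not None and cur_skip[0] <= i < cur_skip[1]:
            flush()
            continue
        if ch in _APOSTROPHES:
            continue  # joins the surrounding word without splitting it
        if ch.isalnum() and not is_emoji(ch):
            if not buf:
                start = i
            buf.append(ch.lower())
            end = i + 1
        else:
            flush()
    flush()
    return TokenSequence(source_text=text, tokens=tuple(tokens))


def content_view(seq: TokenSequence) -> list[Token]:
    """Non-stop-word tokens in original order (idempotent)."""
    return [t for t in seq.tokens if not t.is_stopword]


def is_eligible(seq: TokenSequence) -> bool:
    """True iff the sequence has at least 3 content tokens.

    Quotes matched on fewer than three non-stop-word tokens are not
    specific enough to attribute to a song, so such posts are excluded
    before alignment.
    """
    return len(content_view(seq)) >= 3
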