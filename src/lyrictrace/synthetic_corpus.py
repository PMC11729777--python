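"""Seeded, ground-truthed synthetic stand-in for a post stream + lyrics DB.

The generator emulates the shape of the study inputs end to end: a drug
keyword lexicon partitioned into four categories, a database of songs whose
lines sometimes name those drugs, and an hourly stream of short posts, a
configurable fraction of which quote a (possibly noise-corrupted) lyric
line.  Every post is labelled in a sidecar ground-truth table, so detection
recall and false-positive rates are measurable exactly.

Three structural choices make the evaluation controllable:

* background (non-quote) posts draw from a word list disjoint -- down to
  Porter stems -- from the lyric vocabulary, so a background post can share
  at most the stems of one deliberately injected drug keyword with any
  lyric line and can never reach the 3-shared-stem retrieval floor;
* quoted lines are drawn from the keyword-bearing lines (a quotable "drug
  lyric" names a drug, as in real drug-lyric hooks, which is also what the
  keyword screen upstream of the aligner presumes);
* no generated line is an ordered stem-subsequence of another, so a clean
  quote is always attributed to its true song.

Noise emulates how lyrics are quoted in the wild: independent
per-character edits, contraction substitutions ("going to" -> "gon"), and
bracketed filler insertions ("[and]").
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .keyword_screen import Category, KeywordEntry, KeywordLexicon
from .textnorm import content_view, tokenize

__all__ = [
    "Gender", "Genre", "SongSpec", "PostRecord", "CorpusConfig",
    "GroundTruthEntry", "GroundTruth", "StreamResult",
    "build_lexicon", "generate_lyrics_db", "corrupt_text", "apply_char_edits",
    "generate_post_stream", "write_post_batches", "write_lyrics_db",
    "write_ground_truth", "read_post_batches", "read_lyrics_db",
    "read_ground_truth", "LYRIC_VOCAB", "BACKGROUND_VOCAB",
]


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Genre(str, Enum):
    RAP_HIPHOP = "rap_hiphop"
    RNB_SOUL = "rnb_soul"
    POP_ALTERNATIVE = "pop_alternative"
    OTHER = "other"


@dataclass(frozen=True)
class SongSpec:
    song_id: str
    title: str
    artist_name: str
    artist_gender: Gender
    genre: Genre
    release_date: dt.date
    lines: tuple[str, ...]
    language: str = "en"

    def __post_init__(self) -> None:
        if not self.lines or any(not ln.strip() for ln in self.lines):
            raise ValueError("a song needs >= 1 non-empty line")


@dataclass(frozen=True)
class PostRecord:
    id: str
    created_at: dt.datetime  # UTC
    text: str
    followers_count: int


@dataclass(frozen=True)
class GroundTruthEntry:
    post_id: str
    label: str  # "quote" | "background"
    song_id: str | None
    line_index: int | None
    has_drug_keyword: bool


GroundTruth = dict[str, GroundTruthEntry]


@dataclass
class StreamResult:
    batches: dict[str, list[PostRecord]]  # hour key "YYYY-MM-DD-HH" -> posts
    ground_truth: GroundTruth
    missing_hours: list[str]


# --------------------------------------------------------------------------
# Fixed vocabularies.  LYRIC_VOCAB and BACKGROUND_VOCAB are disjoint down to
# Porter stems (asserted in the test suite), which is what makes background
# posts structurally unable to align with lyric lines.

LYRIC_VOCAB: tuple[str, ...] = tuple("""
ride night city light shine gold chain cash hustle grind street block fame
game dream heart soul fire flame burn drip wave vibe crew squad gang ice
diamond whip lane race chase fly star moon dark cold heat storm rain pain
scar tear cry laugh smile girl shorty homie player boss king queen crown
throne trap bando stack band rack bread guap bag flex floss ball hoop court
beat bass drum track verse hook rhyme flow mic stage show tour club party
dance floor roll spin slide glide bounce rock swag style fresh fit kick lace
brand label deal sign fan hater rival beef drama story life death grave
ghost demon angel heaven sin pray faith hope trust loyal real fake mask
face eye lip kiss touch hold feel miss need want forget gon low high slow
fast wild free lost found gone stay leave wait late soon forever young rich
broke hood corner summer winter midnight dawn
""".split())

BACKGROUND_VOCAB: tuple[str, ...] = tuple("""
meeting coffee morning office traffic weather sunday monday friday
breakfast lunch dinner laptop computer email website garden recipe soccer
football tennis homework school teacher student exam grade library book
novel author movie cinema ticket airport flight train station bus subway
bicycle highway museum gallery painting photo camera kitchen oven salad
pasta pizza burger cheese tomato onion garlic butter flour market grocery
store price discount coupon budget invoice report deadline project manager
client customer service phone battery charger screen keyboard printer
internet router update software hardware download upload folder document
spreadsheet calendar schedule reminder appointment doctor dentist hospital
nurse weekend holiday vacation beach mountain hiking camping tent trail
river lake forest picnic barbecue neighbor garage driveway lawn mower paint
ladder hammer screw drill plumber furnace window curtain carpet sofa pillow
blanket laundry detergent vacuum recycle compost umbrella puddle sidewalk
elevator escalator stapler envelope postage parcel receipt warranty
""".split())

# Real "pharmaceutical" and "street" terms seed each category; when a
# configuration asks for more keywords than the pools hold, extra
# pseudo-slang surfaces are synthesized from syllables.
_KEYWORD_POOLS: dict[Category, tuple[str, ...]] = {
    Category.CANNABINOID: (
        "weed", "blunt", "joint", "dank", "marijuana", "420", "mary jane",
        "smoke", "kush", "ganja", "reefer", "hash", "spliff", "doobie",
        "cannabis", "hemp", "indica", "sativa", "tetrahydrocannabinols",
        "zaza", "loud",
    ),
    Category.STIMULANT_HALLUCINOGEN: (
        "molly", "cocaine", "coke", "powder", "cigarette", "crack",
        "mushroom", "ketamine", "acid", "ecstasy", "speed", "meth",
        "adderall", "shrooms", "lsd", "mdma", "blow", "snow", "yayo",
        "methamphetamines", "psilocybin",
    ),
    Category.OPIOID: (
        "dope", "heroin", "oxy", "lean", "codeine", "fentanyl", "percocet",
        "morphine", "opium", "smack", "vicodin", "oxycodone", "hydrocodone",
        "tramadol", "purple drank",
    ),
    Category.OTHER: (
        "liquor", "wine", "xan", "xanax", "vodka", "whiskey", "tequila",
        "henny", "brandy", "valium", "ambien", "nicotine", "tobacco",
        "hookah", "gin",
    ),
}

_CONTRACTIONS: tuple[tuple[str, str], ...] = (
    ("going to", "gon"),
    ("want to", "wanna"),
    ("got to", "gotta"),
    ("kind of", "kinda"),
    ("out of", "outta"),
    ("i am", "im"),
)

_BRACKET_FILLERS = ("[and]", "[yeah]", "[uh]", "[girl]", "[okay]", "[hook]")

_STOPWORD_FILLERS = ("i", "the", "my", "your", "in", "on", "with", "to",
                     "a", "and", "so", "all", "this", "that", "up", "out")

_ARTIST_PREFIXES = ("Lil", "Big", "Yung", "MC", "DJ", "Young", "King",
                    "Lady", "Don", "Baby")

_ONSETS = ("br", "dr", "gr", "kr", "pr", "tr", "bl", "fl", "gl", "sk",
           "sl", "sn", "sp", "st", "sw", "ch", "sh", "th", "b", "d", "f",
           "g", "j", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z")
_NUCLEI = ("a", "e", "i", "o", "u", "oo", "ee", "ay", "ow", "izz", "azz")
_CODAS = ("", "x", "z", "zo", "ko", "mo", "lo", "g", "k", "p", "sta", "rra")


@dataclass(frozen=True)
class CorpusConfig:
    n_songs: int = 60
    lines_per_song: tuple[int, int] = (8, 14)
    n_drug_keywords: int = 190
    keyword_category_weights: tuple[float, float, float, float] = (
        0.35, 0.30, 0.20, 0.15)
    date_range: tuple[dt.date, dt.date] = (dt.date(2015, 1, 1),
                                           dt.date(2017, 12, 31))
    posts_per_hour: float = 2.0
    embed_rate: float = 0.1
    char_edit_rate: float = 0.0
    contraction_rate: float = 0.1
    bracket_rate: float = 0.05
    follower_distribution: tuple[float, float] = (6.0, 2.0)  # log-normal
    missing_hour_rate: float = 0.11
    keyword_line_rate: float = 0.35
    background_keyword_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "embed_rate": self.embed_rate,
            "char_edit_rate": self.char_edit_rate,
            "contraction_rate": self.contraction_rate,
            "bracket_rate": self.bracket_rate,
            "missing_hour_rate": self.missing_hour_rate,
            "keyword_line_rate": self.keyword_line_rate,
            "background_keyword_rate": self.background_keyword_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigurationError("empty date_range")
        if self.posts_per_hour <= 0:
            raise ConfigurationError("posts_per_hour must be > 0")
        if len(self.keyword_category_weights) != 4:
            raise ConfigurationError("need 4 keyword category weights")
        if abs(sum(self.keyword_category_weights) - 1.0) > 1e-9:
            raise ConfigurationError("keyword category weights must sum to 1")

    def replace(self, **kwargs) -> "CorpusConfig":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# Lexicon


def _synth_word(rng: np.random.Generator, taken: set[str]) -> str:
    for _ in range(1000):
        n_syll = int(rng.integers(1, 3))
        word = ""
        for _ in range(n_syll):
            word += str(rng.choice(_ONSETS)) + str(rng.choice(_NUCLEI))
        word += str(rng.choice(_CODAS))
        if 3 <= len(word) <= 10 and word not in taken:
            return word
    raise RuntimeError("could not synthesize a fresh pseudo-word")


def build_lexicon(config: CorpusConfig) -> KeywordLexicon:
    """Deterministically build the drug-keyword lexicon.

    Category sizes are multinomial in ``keyword_category_weights``; each
    category is filled from its curated pool of real terms first, then
    topped up with synthesized pseudo-slang so any ``n_drug_keywords`` is
    reachable.
    """
    if config.n_drug_keywords < 4:
        raise ConfigurationError("need at least 4 drug keywords")
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n_drug_keywords,
                             config.keyword_category_weights)
    taken: set[str] = set(LYRIC_VOCAB) | set(BACKGROUND_VOCAB)
    for pool in _KEYWORD_POOLS.values():
        taken |= set(pool)
    entries: list[KeywordEntry] = []
    used: set[str] = set()
    for category, n_cat in zip(Category, counts):
        pool = list(_KEYWORD_POOLS[category])
        for i in range(int(n_cat)):
            if i < len(pool):
                surface = pool[i]
            else:
                surface = _synth_word(rng, taken | used)
            used.add(surface)
            entries.append(KeywordEntry.make(surface, category))
    return KeywordLexicon(entries=tuple(entries))


# --------------------------------------------------------------------------
# Lyrics database


def _keyword_stems(lexicon: KeywordLexicon) -> set[str]:
    stems: set[str] = set()
    for e in lexicon.entries:
        stems |= {t.stem for t in content_view(tokenize(e.surface))}
    return stems


def _line_stems(raw: str) -> tuple[str, ...]:
    return tuple(t.stem for t in content_view(tokenize(raw)))


def _is_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    it = iter(long)
    return all(s in it for s in short)


def _compose_line(rng: np.random.Generator, vocab: list[str],
                  keywords: list[str], with_keyword: bool) -> str:
    n_content = int(rng.integers(5, 10))
    words = [str(w) for w in rng.choice(vocab, size=n_content, replace=False)]
    if with_keyword and keywords:
        n_kw = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
        n_kw = min(n_kw, len(keywords), n_content - 2)
        positions = rng.choice(n_content, size=n_kw, replace=False)
        chosen = rng.choice(len(keywords), size=n_kw, replace=False)
        for pos, ki in zip(positions, chosen):
            words[int(pos)] = keywords[int(ki)]
    out: list[str] = []
    for w in words:
        if rng.random() < 0.35:
            out.append(str(rng.choice(_STOPWORD_FILLERS)))
        out.append(w)
    line = " ".join(out)
    return line[0].upper() + line[1:]


def generate_lyrics_db(config: CorpusConfig,
                       lexicon: KeywordLexicon) -> list[SongSpec]:
    """Generate the synthetic song database.

    ``keyword_line_rate`` of the lines carry 1-3 lexicon keywords (real
    drug-lyric hooks typically name both a drug and its use, e.g. a
    "smoke"/"blunt" pair, so multi-keyword lines are the common case).
    Lines are rejection-sampled so that no line is an ordered
    stem-subsequence of another, which makes clean-quote attribution exact.
    """
    rng = np.random.default_rng(config.seed + 1)
    kw_stems = _keyword_stems(lexicon)
    vocab = [w for w in LYRIC_VOCAB
             if _line_stems(w) and _line_stems(w)[0] not in kw_stems]
    single_word_keywords = [e.surface for e in lexicon.entries]

    n_artists = max(1, int(round(config.n_songs * 0.6)))
    artists: list[tuple[str, Gender]] = []
    for _ in range(n_artists):
        name = f"{rng.choice(_ARTIST_PREFIXES)} " + _synth_word(
            rng, set()).capitalize()
        gender = Gender.MALE if rng.random() < 0.84 else Gender.FEMALE
        artists.append((name, gender))

    genre_weights = [0.90, 0.04, 0.04, 0.02]
    release_lo, release_hi = config.date_range
    release_span = (release_hi - release_lo).days

    songs: list[SongSpec] = []
    seen_lines: list[tuple[str, ...]] = []
    lo, hi = config.lines_per_song
    for si in range(config.n_songs):
        artist, gender = artists[int(rng.integers(0, n_artists))]
        genre = list(Genre)[int(rng.choice(4, p=genre_weights))]
        release = release_lo + dt.timedelta(days=int(rng.integers(0, release_span + 1)))
        title_words = rng.choice(vocab, size=int(rng.integers(1, 4)), replace=False)
        title = " ".join(str(w).capitalize() for w in title_words)
        n_lines = int(rng.integers(lo, hi + 1))
        lines: list[str] = []
        for _ in range(n_lines):
            for _attempt in range(200):
                with_kw = rng.random() < config.keyword_line_rate
                raw = _compose_line(rng, vocab, single_word_keywords, with_kw)
                stems = _line_stems(raw)
                if len(stems) < 3:
                    continue
                clash = any(
                    _is_subsequence(stems, other) or _is_subsequence(other, stems)
                    for other in seen_lines)
                if not clash:
                    break
            else:  # pragma: no cover - vocabulary large enough in practice
                raise RuntimeError("could not generate a distinctive line")
            lines.append(raw)
            seen_lines.append(stems)
        songs.append(SongSpec(
            song_id=f"S{si:04d}", title=title, artist_name=artist,
            artist_gender=gender, genre=genre, release_date=release,
            lines=tuple(lines)))
    return songs


# --------------------------------------------------------------------------
# Noise model


def apply_char_edits(text: str, rate: float,
                     rng: np.random.Generator) -> tuple[str, int]:
    """Independent per-character edits at probability ``rate``.

    Each affected character is, with equal probability, substituted by a
    random letter, deleted, or preceded by an inserted random letter.
    Returns the noisy string and the number of edits applied.
    """
    if rate <= 0.0:
        return text, 0
    letters = "abcdefghijklmnopqrstuvwxyz"
    out: list[str] = []
    n_edits = 0
    for ch in text:
        if rng.random() < rate:
            n_edits += 1
            op = int(rng.integers(0, 3))
            if op == 0:  # substitute
                repl = letters[int(rng.integers(0, 26))]
                while repl == ch:
                    repl = letters[int(rng.integers(0, 26))]
                out.append(repl)
            elif op == 1:  # delete
                pass
            else:  # insert before
                out.append(letters[int(rng.integers(0, 26))])
                out.append(ch)
        else:
            out.append(ch)
    return "".join(out), n_edits


def corrupt_text(line: str, config: CorpusConfig,
                 rng: np.random.Generator) -> str:
    """Apply the full quote-noise model to one line.

    Per-character edits at ``char_edit_rate``, then a contraction
    substitution with probability ``contraction_rate``, then a bracketed
    filler insertion with probability ``bracket_rate``.  With all rates 0
    the line is returned unchanged.
    """
    if not line:
        raise ValueError("line must be non-empty")
    text, _ = apply_char_edits(line, config.char_edit_rate, rng)
    if config.contraction_rate > 0 and rng.random() < config.contraction_rate:
        lowered = text.lower()
        for pattern, repl in _CONTRACTIONS:
            pos = lowered.find(pattern)
            if pos >= 0:
                text = text[:pos] + repl + text[pos + len(pattern):]
                break
    if config.bracket_rate > 0 and rng.random() < config.bracket_rate:
        words = text.split(" ")
        pos = int(rng.integers(0, len(words) + 1))
        filler = str(rng.choice(_BRACKET_FILLERS))
        text = " ".join(words[:pos] + [filler] + words[pos:])
    return text


# --------------------------------------------------------------------------
# Post stream


def _hour_key(ts: dt.datetime) -> str:
    return ts.strftime("%Y-%m-%d-%H")


def _hours_in_range(date_range: tuple[dt.date, dt.date]) -> list[dt.datetime]:
    start, end = date_range
    cur = dt.datetime(start.year, start.month, start.day,
                      tzinfo=dt.timezone.utc)
    stop = dt.datetime(end.year, end.month, end.day,
                       tzinfo=dt.timezone.utc) + dt.timedelta(days=1)
    hours = []
    while cur < stop:
        hours.append(cur)
        cur += dt.timedelta(hours=1)
    return hours


def generate_post_stream(config: CorpusConfig, songs: list[SongSpec],
                         lexicon: KeywordLexicon) -> StreamResult:
    """Generate the hourly post stream plus its ground truth.

    Each hour of the configured date range either yields a batch (Poisson
    post count at ``posts_per_hour``) or is withheld with probability
    ``missing_hour_rate``.  Each post is a corrupted lyric quote with
    probability ``embed_rate``, otherwise background chatter; background
    posts carry one injected drug keyword with probability
    ``background_keyword_rate``.
    """
    rng = np.random.default_rng(config.seed + 2)
    kw_stems = _keyword_stems(lexicon)

    embeddable: list[tuple[SongSpec, int]] = []
    for song in songs:
        for li, raw in enumerate(song.lines):
            stems = _line_stems(raw)
            if len(stems) >= 3 and set(stems) & kw_stems:
                embeddable.append((song, li))
    if config.embed_rate > 0 and not embeddable:
        raise ConfigurationError(
            "embed_rate > 0 requires at least one keyword-bearing lyric line")

    keywords = [e.surface for e in lexicon.entries]
    mu, sigma = config.follower_distribution

    batches: dict[str, list[PostRecord]] = {}
    truth: GroundTruth = {}
    missing: list[str] = []
    counter = 0
    for hour in _hours_in_range(config.date_range):
        key = _hour_key(hour)
        if rng.random() < config.missing_hour_rate:
            missing.append(key)
            continue
        n_posts = int(rng.poisson(config.posts_per_hour))
        posts: list[PostRecord] = []
        for _ in range(n_posts):
            post_id = f"t{counter:09d}"
            counter += 1
            ts = hour + dt.timedelta(seconds=int(rng.integers(0, 3600)))
            followers = max(0, int(rng.lognormal(mu, sigma)))
            if config.embed_rate > 0 and rng.random() < config.embed_rate:
                song, li = embeddable[int(rng.integers(0, len(embeddable)))]
                text = corrupt_text(song.lines[li], config, rng)
                if rng.random() < 0.5:
                    lead = rng.choice(BACKGROUND_VOCAB,
                                      size=int(rng.integers(1, 4)),
                                      replace=False)
                    text = " ".join(str(w) for w in lead) + " " + text
                if rng.random() < 0.5:
                    tail = rng.choice(BACKGROUND_VOCAB,
                                      size=int(rng.integers(1, 4)),
                                      replace=False)
                    text = text + " " + " ".join(str(w) for w in tail)
                truth[post_id] = GroundTruthEntry(
                    post_id=post_id, label="quote", song_id=song.song_id,
                    line_index=li, has_drug_keyword=True)
            else:
                n_words = int(rng.integers(5, 15))
                words = [str(w) for w in rng.choice(
                    BACKGROUND_VOCAB, size=n_words, replace=False)]
                has_kw = rng.random() < config.background_keyword_rate
                if has_kw:
                    pos = int(rng.integers(0, n_words + 1))
                    words.insert(pos, keywords[int(rng.integers(0, len(keywords)))])
                out: list[str] = []
                for w in words:
                    if rng.random() < 0.3:
                        out.append(str(rng.choice(_STOPWORD_FILLERS)))
                    out.append(w)
                text = " ".join(out)
                truth[post_id] = GroundTruthEntry(
                    post_id=post_id, label="background", song_id=None,
                    line_index=None, has_drug_keyword=has_kw)
            posts.append(PostRecord(id=post_id, created_at=ts, text=text,
                                    followers_count=followers))
        batches[key] = posts
    return StreamResult(batches=batches, ground_truth=truth,
                        missing_hours=missing)


# --------------------------------------------------------------------------
# External interfaces (JSON Lines / JSON documents)


def write_post_batches(result: StreamResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in sorted(result.batches):
        lines = []
        for p in result.batches[key]:
            lines.append(json.dumps({
                "id": p.id,
                "created_at": p.created_at.strftime("%Y-%m-%dT%H:%M:%SZ"),
                "text": p.text,
                "followers_count": p.followers_count,
            }))
        (out_dir / f"{key}.jsonl").write_text("\n".join(lines) + "\n"
                                              if lines else "")


def read_post_batches(in_dir: str | Path) -> dict[str, list[PostRecord]]:
    batches: dict[str, list[PostRecord]] = {}
    for path in sorted(Path(in_dir).glob("*.jsonl")):
        posts = []
        for raw in path.read_text().splitlines():
            if not raw.strip():
                continue
            d = json.loads(raw)
            ts = dt.datetime.strptime(
                d["created_at"], "%Y-%m-%dT%H:%M:%SZ").replace(
                    tzinfo=dt.timezone.utc)
            posts.append(PostRecord(id=d["id"], created_at=ts,
                                    text=d["text"],
                                    followers_count=d["followers_count"]))
        batches[path.stem] = posts
    return batches


def write_lyrics_db(songs: list[SongSpec], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in songs:
        (out_dir / f"{s.song_id}.json").write_text(json.dumps({
            "song_id": s.song_id,
            "title": s.title,
            "artist_name": s.artist_name,
            "artist_gender": s.artist_gender.value,
            "genre": s.genre.value,
            "release_date": s.release_date.isoformat(),
            "lines": list(s.lines),
            "language": s.language,
        }, indent=2))


def read_lyrics_db(in_dir: str | Path) -> list[SongSpec]:
    songs = []
    for path in sorted(Path(in_dir).glob("*.json")):
        d = json.loads(path.read_text())
        songs.append(SongSpec(
            song_id=d["song_id"], title=d["title"],
            artist_name=d["artist_name"],
            artist_gender=Gender(d["artist_gender"]),
            genre=Genre(d["genre"]),
            release_date=dt.date.fromisoformat(d["release_date"]),
            lines=tuple(d["lines"]), language=d.get("language", "en")))
    return songs


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for post_id in sorted(truth):
        e = truth[post_id]
        lines.append(json.dumps({
            "post_id": e.post_id, "label": e.label, "song_id": e.song_id,
            "line_index": e.line_index,
            "has_drug_keyword": e.has_drug_keyword,
        }))
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_ground_truth(path: str | Path) -> GroundTruth:
    truth: GroundTruth = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        d = json.loads(raw)
        truth[d["post_id"]] = GroundTruthEntry(
            post_id=d["post_id"], label=d["label"], song_id=d["song_id"],
            line_index=d["line_index"],
            has_drug_keyword=d["has_drug_keyword"])
    return truth
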