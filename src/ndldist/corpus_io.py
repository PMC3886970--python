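"""Corpus containers and IPA transcription parsing.

A pronunciation corpus is a flat table of (speaker, meaning, transcription,
frequency) rows, read from UTF-8 tab-separated files.  Transcriptions are
sequences of phone segments: one base IPA character plus any attached
diacritics (combining marks or spacing modifier letters).  The ``'#'``
character is reserved as the word-boundary marker used by cue extraction and
may never occur inside a pronunciation.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd

BOUNDARY = "#"

DiacriticsMode = Literal["keep", "strip"]

#: Spacing characters treated as diacritics in addition to Unicode combining
#: marks (category Mn/Mc/Me).  These are the IPA modifier letters and symbols
#: that attach to the preceding base segment: aspiration and secondary
#: articulation superscripts, length marks, stress marks, the rhotic hook and
#: similar.  The table is deliberately explicit so users can audit and extend
#: it (see :func:`parse_ipa`'s ``extra_diacritics``).
MODIFIER_DIACRITICS: frozenset[str] = frozenset(
    # Spacing Modifier Letters block (U+02B0..U+02FF): ʰ ʲ ʷ ˠ ˤ ː ˑ ˈ ˌ ˞ ...
    [chr(cp) for cp in range(0x02B0, 0x0300)]
    # Phonetic Extensions superscripts commonly used in IPA: ᵐ ᵑ ᶬ ...
    + [chr(cp) for cp in range(0x1D2C, 0x1DC0)]
    # Superscript n and misc
    + ["ⁿ"]
)


def _is_combining(ch: str) -> bool:
    return unicodedata.category(ch) in ("Mn", "Mc", "Me")


@dataclass(frozen=True)
class Segment:
    """One phone: a base IPA character with attached diacritic marks."""

    base: str
    diacritics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.base:
            raise ValueError("segment base must be non-empty")
        if self.base == BOUNDARY:
            raise ValueError("'#' is the reserved boundary marker, not a segment")

    def render(self) -> str:
        return self.base + "".join(self.diacritics)

    def strip(self) -> "Segment":
        """Drop diacritics, keeping only the base character."""
        return Segment(self.base) if self.diacritics else self

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class Transcription:
    """An ordered, non-empty sequence of segments for one word token."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("transcription must contain at least one segment")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def render(self) -> str:
        return "".join(s.render() for s in self.segments)

    def strip_diacritics(self) -> "Transcription":
        return Transcription(tuple(s.strip() for s in self.segments))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_ipa(
    text: str,
    diacritics_mode: DiacriticsMode = "strip",
    extra_diacritics: Iterable[str] = (),
) -> Transcription:
    """Parse a UTF-8 IPA string into a :class:`Transcription`.

    Enclosing brackets ``[...]`` or ``/.../`` and surrounding whitespace are
    removed.  Every character that is not a diacritic starts a new segment; a
    diacritic (combining mark, or a spacing modifier listed in
    :data:`MODIFIER_DIACRITICS` or ``extra_diacritics``) attaches to the
    preceding base character.  Tie bars (e.g. the affricate tie U+0361) are
    combining marks and therefore attach to the *left* base, giving a
    deterministic single pass.

    With ``diacritics_mode='strip'`` all diacritics are discarded and each
    segment is a bare base character.
    """
    if diacritics_mode not in ("keep", "strip"):
        raise ValueError(f"diacritics_mode must be 'keep' or 'strip', got {diacritics_mode!r}")
    cleaned = text.strip().strip("[]/").strip()
    if not cleaned:
        raise ValueError("empty transcription")
    extra = frozenset(extra_diacritics)

    segments: list[Segment] = []
    base: str | None = None
    marks: list[str] = []
    for ch in cleaned:
        if ch.isspace():
            continue
        if ch == BOUNDARY:
            raise ValueError("'#' is reserved as the word-boundary marker and may not occur in a pronunciation")
        if _is_combining(ch) or ch in MODIFIER_DIACRITICS or ch in extra:
            if base is None:
                raise ValueError(f"combining mark U+{ord(ch):04X} ({unicodedata.name(ch, '?')}) has no preceding base character")
            marks.append(ch)
        else:
            if base is not None:
                segments.append(Segment(base, tuple(marks)))
            base, marks = ch, []
    if base is not None:
        segments.append(Segment(base, tuple(marks)))
    if not segments:
        raise ValueError("empty transcription")
    t = Transcription(tuple(segments))
    return t.strip_diacritics() if diacritics_mode == "strip" else t


@dataclass(frozen=True)
class PronunciationRecord:
    """One token: a speaker pronouncing one meaning with some frequency."""

    speaker: str
    meaning: str
    transcription: Transcription
    frequency: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        object.__setattr__(self, "meaning", self.meaning.casefold())


@dataclass
class Corpus:
    """A list of pronunciation records plus free-form provenance metadata."""

    records: list[PronunciationRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PronunciationRecord]:
        return iter(self.records)

    def speakers(self) -> list[str]:
        """Distinct speaker ids in first-appearance order."""
        return list(dict.fromkeys(r.speaker for r in self.records))

    def meanings(self) -> list[str]:
        """Distinct meanings in first-appearance order."""
        return list(dict.fromkeys(r.meaning for r in self.records))

    def subset_speakers(self, speakers: Iterable[str]) -> "Corpus":
        keep = set(speakers)
        return Corpus([r for r in self.records if r.speaker in keep], dict(self.metadata))

    def by_speaker(self) -> dict[str, list[PronunciationRecord]]:
        out: dict[str, list[PronunciationRecord]] = {}
        for r in self.records:
            out.setdefault(r.speaker, []).append(r)
        return out

    def scale_frequencies(self, factor: float) -> "Corpus":
        return Corpus(
            [
                PronunciationRecord(r.speaker, r.meaning, r.transcription, r.frequency * factor)
                for r in self.records
            ],
            dict(self.metadata),
        )


@dataclass
class RatingsTable:
    """Perceptual ratings: one row per (rater, sample) judgement."""

    rows: list[tuple[str, str, int]]
    scale: tuple[int, int] = (1, 7)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        for rater, sample, score in self.rows:
            if not lo <= score <= hi:
                raise ValueError(f"score {score} for ({rater}, {sample}) outside scale [{lo}, {hi}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rater", "sample", "score"])


CORPUS_COLUMNS = ["Speaker", "Outcome", "Pronunciation", "Frequency"]


def read_corpus(path: str | Path, diacritics_mode: DiacriticsMode = "strip") -> Corpus:
    """Read a corpus TSV with header ``Speaker Outcome Pronunciation Frequency``.

    Meanings are case-folded; pronunciations are parsed with
    :func:`parse_ipa`.  Repeated (speaker, meaning) rows are kept as separate
    tokens of the same word.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing}; found columns {list(df.columns)}")
    if df.empty:
        raise ValueError(f"no records in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        freq = float(getattr(row, "Frequency"))
        if freq <= 0:
            raise ValueError(f"{path}: non-positive frequency {freq} at row {i}")
        records.append(
            PronunciationRecord(
                speaker=str(row.Speaker),
                meaning=str(row.Outcome),
                transcription=parse_ipa(str(row.Pronunciation), diacritics_mode),
                frequency=freq,
            )
        )
    return Corpus(records, metadata={"path": str(path), "diacritics": diacritics_mode})


def write_corpus(corpus: Corpus, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(CORPUS_COLUMNS) + "\n")
        for r in corpus.records:
            fh.write(f"{r.speaker}\t{r.meaning}\t{r.transcription.render()}\t{r.frequency!r}\n")


def read_ratings(path: str | Path, scale: tuple[int, int] = (1, 7)) -> RatingsTable:
    """Read a ratings TSV with header ``Rater Sample Score``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("Rater", "Sample", "Score") if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing}; found columns {list(df.columns)}")
    rows = [(str(r.Rater), str(r.Sample), int(r.Score)) for r in df.itertuples(index=False)]
    return RatingsTable(rows, scale)


def write_ratings(table: RatingsTable, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("Rater\tSample\tScore\n")
        for rater, sample, score in table.rows:
            fh.write(f"{rater}\t{sample}\t{score}\n")


def split_frequency(total_frequency: float, n_pronunciations: int) -> float:
    """Divide a meaning's total frequency equally over its pronunciations.

    A word with total corpus frequency 580,000 shared by 58 distinct
    pronunciations gives each pronunciation token frequency 10,000.
    """
    if total_frequency <= 0:
        raise ValueError(f"total_frequency must be positive, got {total_frequency}")
    if n_pronunciations < 1:
        raise ValueError(f"n_pronunciations must be >= 1, got {n_pronunciations}")
    return total_frequency / n_pronunciations


def tokenize_paragraph(text: str) -> list[str]:
    """Split an elicitation paragraph into case-folded word tokens.

    Tokens are whitespace-separated; leading/trailing punctuation is stripped;
    empty tokens are dropped.  Word-internal apostrophes and hyphens survive.
    """
    tokens = []
    for raw in text.split():
        tok = raw.strip(".,;:!?\"'()[]{}…«»“”‘’").casefold()
        if tok:
            tokens.append(tok)
    return tokens
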