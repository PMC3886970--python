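"""Synthetic corpora with controlled accent/dialect structure.

Real validation data for pronunciation distances are elicitation corpora: a
shared word list read by many speakers, with per-variety segmental
deviations, plus Likert ratings of native-likeness.  This module emulates
that setting: a canonical lexicon over a small segment inventory with
Zipf-distributed word frequencies, speakers derived from it by i.i.d.
per-segment substitutions/insertions/deletions at controlled rates, and
noisy ratings generated as a monotone-decreasing function of true distance.

Everything is bit-reproducible under a fixed seed; each derived speaker
draws from its own RNG stream keyed by (seed, speaker id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, PronunciationRecord, RatingsTable, Segment, Transcription


def _speaker_rng(seed: int | None, speaker_id: str) -> np.random.Generator:
    # stable per-speaker stream: spawn key from a CRC of the id
    return np.random.default_rng(np.random.SeedSequence([seed or 0, zlib.crc32(speaker_id.encode("utf-8"))]))


def ring_confusion_map(inventory: Sequence[str]) -> dict[str, str]:
    """Default confusion map: each segment maps to its right neighbour in the
    ordered inventory, a crude stand-in for phonetic similarity."""
    inv = list(inventory)
    return {s: inv[(i + 1) % len(inv)] for i, s in enumerate(inv)}


@dataclass
class PerturbationModel:
    """Per-segment i.i.d. edit rates defining one variety's deviation."""

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    inventory: Sequence[str] = ()
    confusion: Mapping[str, str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1], got {r}")


def generate_lexicon(
    n_words: int,
    inventory: Sequence[str],
    length_range: tuple[int, int] = (3, 7),
    zipf_exponent: float = 1.0,
    seed: int | None = None,
    speaker_id: str = "canonical",
) -> Corpus:
    """Generate a canonical one-speaker lexicon.

    Words are distinct random segment strings over the inventory with
    uniformly drawn lengths; word r (1-based, in generation order) gets
    frequency proportional to r**(-zipf_exponent), scaled so the most
    frequent word has frequency 10,000.  Exponent 0 gives equal frequencies.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    inv = list(inventory)
    if len(inv) < 3:
        raise ValueError("inventory must contain at least 3 segments")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    n_possible = sum(len(inv) ** L for L in range(lo, hi + 1))
    if n_words > n_possible:
        raise ValueError(f"inventory supports only {n_possible} distinct words of length {lo}..{hi}, requested {n_words}")
    rng = np.random.default_rng(seed)
    words: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(words) < n_words:
        L = int(rng.integers(lo, hi + 1))
        w = tuple(inv[i] for i in rng.integers(0, len(inv), size=L))
        if w not in seen:
            seen.add(w)
            words.append(w)
    ranks = np.arange(1, n_words + 1, dtype=float)
    freqs = ranks ** (-zipf_exponent)
    freqs = freqs / freqs[0] * 10_000.0
    records = [
        PronunciationRecord(
            speaker=speaker_id,
            meaning=f"word{r:03d}",
            transcription=Transcription(tuple(Segment(s) for s in w)),
            frequency=float(f),
        )
        for r, (w, f) in enumerate(zip(words, freqs), start=1)
    ]
    return Corpus(records, metadata={"generator": "lexicon", "seed": seed, "n_words": n_words})


def perturb_speaker(canonical: Corpus, model: PerturbationModel, speaker_id: str) -> Corpus:
    """Derive a new speaker by per-segment i.i.d. edits of the canonical forms.

    Each segment is independently substituted (via the confusion map),
    deleted, or followed by an inserted segment drawn uniformly from the
    inventory.  A word that would lose all its segments is redrawn; with
    all-zero rates the copy is segment-identical under the new speaker id.
    """
    inv = list(model.inventory) or sorted({s.base for r in canonical for s in r.transcription})
    confusion = dict(model.confusion) if model.confusion is not None else ring_confusion_map(inv)
    rng = _speaker_rng(model.seed, speaker_id)
    records = []
    for r in canonical:
        while True:
            out: list[Segment] = []
            for seg in r.transcription:
                u = rng.random(3)
                if u[0] < model.deletion:
                    pass
                elif u[1] < model.substitution:
                    out.append(Segment(confusion.get(seg.base, seg.base), seg.diacritics))
                else:
                    out.append(seg)
                if u[2] < model.insertion:
                    out.append(Segment(inv[int(rng.integers(0, len(inv)))]))
            if out:
                break
        records.append(PronunciationRecord(speaker_id, r.meaning, Transcription(tuple(out)), r.frequency))
    return Corpus(records, metadata={**canonical.metadata, "perturbed_from": canonical.metadata.get("generator")})


def generate_ratings(
    true_distances: Mapping[str, float],
    noise_sd: float = 0.5,
    scale: tuple[int, int] = (1, 7),
    n_raters: int = 10,
    seed: int | None = None,
) -> RatingsTable:
    """Likert ratings as a noisy monotone-decreasing function of distance.

    The observed distance range maps linearly onto the rating scale with the
    smallest distance at the top of the scale (most native-like); each
    rater's score adds Gaussian noise before rounding and clipping.  With
    ``noise_sd=0`` ratings are a deterministic decreasing step function of
    distance.
    """
    if not true_distances:
        raise ValueError("no distances to rate")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    lo, hi = scale
    samples = list(true_distances)
    d = np.array([true_distances[s] for s in samples], dtype=float)
    span = d.max() - d.min()
    ideal = np.full_like(d, (lo + hi) / 2) if span == 0 else hi - (d - d.min()) / span * (hi - lo)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_raters):
        noisy = ideal + rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else ideal
        scores = np.clip(np.rint(noisy), lo, hi).astype(int)
        rows.extend((f"rater{k:02d}", s, int(v)) for s, v in zip(samples, scores))
    return RatingsTable(rows, scale)
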