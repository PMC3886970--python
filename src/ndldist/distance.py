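"""Pronunciation distances from meaning activations.

A listener model (a trained weight matrix) hears a pronunciation as its cue
set and activates the intended meaning to some degree; familiar cue
combinations activate strongly, foreign ones weakly or not at all.  The
distance between a speaker and a reference baseline is the mean, over the
shared word list, of the per-meaning activation shortfall relative to that
baseline.  Because each listener has its own weights, distances between two
varieties need not be symmetric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, DiacriticsMode, PronunciationRecord
from .cues import extract_cues_multi
from .ndl import WeightMatrix, activation, build_events, estimate_equilibrium

logger = logging.getLogger(__name__)

DistanceMode = Literal["signed", "absolute"]


def _speaker_outcome_activations(
    weights: WeightMatrix,
    records: Iterable[PronunciationRecord],
    ns: tuple[int, ...],
    diacritics_mode: DiacriticsMode,
) -> dict[str, float]:
    """Token-averaged activation of each meaning a speaker produced.

    When a word occurs more than once in the speaker's material, the
    activations of its pronunciations are averaged first.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    known = set(weights.outcomes)
    for r in records:
        if r.meaning not in known:
            continue
        cues = extract_cues_multi(r.transcription, ns, diacritics_mode)
        a = activation(weights, cues, r.meaning)
        sums[r.meaning] = sums.get(r.meaning, 0.0) + a
        counts[r.meaning] = counts.get(r.meaning, 0) + 1
    return {m: sums[m] / counts[m] for m in sums}


def baseline_profile(
    weights: WeightMatrix,
    reference_corpus: Corpus,
    n: int | Sequence[int] = 3,
    diacritics_mode: DiacriticsMode = "strip",
) -> dict[str, float]:
    """Per-meaning baseline activation of the listener for reference speech.

    Activations are token-averaged within each reference speaker first, then
    averaged across speakers, so a speaker with many tokens of a word does
    not dominate the baseline.
    """
    ns = (n,) if isinstance(n, int) else tuple(n)
    per_speaker = [
        _speaker_outcome_activations(weights, records, ns, diacritics_mode)
        for records in reference_corpus.by_speaker().values()
    ]
    out: dict[str, float] = {}
    for meaning in reference_corpus.meanings():
        vals = [p[meaning] for p in per_speaker if meaning in p]
        if not vals:
            raise ValueError(f"meaning {meaning!r} unknown to the listener model in every reference speaker")
        out[meaning] = float(np.mean(vals))
    return out


@dataclass
class SpeakerDistance:
    """One speaker's distance to a baseline: per-meaning differences and their mean."""

    speaker: str
    per_outcome: dict[str, float]
    aggregate: float

    def __post_init__(self) -> None:
        if self.per_outcome:
            assert math.isclose(self.aggregate, float(np.mean(list(self.per_outcome.values()))), abs_tol=1e-12)


def speaker_distance(
    weights: WeightMatrix,
    baseline: Mapping[str, float],
    speaker_records: Sequence[PronunciationRecord],
    mode: DistanceMode = "signed",
    n: int | Sequence[int] = 3,
    diacritics_mode: DiacriticsMode = "strip",
) -> SpeakerDistance:
    """Distance of one speaker's pronunciations from a baseline profile.

    Per meaning: baseline activation minus the speaker's (token-averaged)
    activation, optionally in absolute value; the aggregate is the mean over
    the meanings the speaker covers.  Meanings the speaker never produced
    are skipped with a warning rather than scored.
    """
    if not speaker_records:
        raise ValueError("speaker has no records")
    ns = (n,) if isinstance(n, int) else tuple(n)
    speaker = speaker_records[0].speaker
    acts = _speaker_outcome_activations(weights, speaker_records, ns, diacritics_mode)
    diffs: dict[str, float] = {}
    missing = []
    for meaning, base in baseline.items():
        if meaning not in acts:
            missing.append(meaning)
            continue
        d = base - acts[meaning]
        diffs[meaning] = abs(d) if mode == "absolute" else d
    if missing:
        logger.warning("speaker %s lacks %d of %d baseline meanings; skipped", speaker, len(missing), len(baseline))
    if not diffs:
        raise ValueError(f"speaker {speaker!r} covers no baseline meaning")
    return SpeakerDistance(speaker=speaker, per_outcome=diffs, aggregate=float(np.mean(list(diffs.values()))))


def accent_distance_resampled(
    corpus: Corpus,
    reference_group: Sequence[str],
    n_reps: int = 100,
    train_fraction: float = 0.5,
    seed: int | None = None,
    mode: DistanceMode = "signed",
    n: int | Sequence[int] = 3,
    diacritics_mode: DiacriticsMode = "strip",
) -> dict[str, tuple[float, float]]:
    """Accent distances against a resampled native baseline.

    Each repetition randomly splits the reference group: ``ceil(fraction*N)``
    speakers train the listener model and the remainder form the baseline
    (average reference speech).  Every speaker in the corpus is scored
    against that baseline once per repetition.  Returns, per speaker, the
    mean and standard deviation of its distance over repetitions.
    """
    refs = list(reference_group)
    if len(refs) < 2:
        raise ValueError("reference group must contain at least 2 speakers to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = math.ceil(train_fraction * len(refs))
    if n_train == len(refs):
        n_train -= 1
    by_speaker = corpus.by_speaker()
    ns = (n,) if isinstance(n, int) else tuple(n)

    per_speaker: dict[str, list[float]] = {s: [] for s in corpus.speakers()}
    for _ in range(n_reps):
        perm = rng.permutation(len(refs))
        train_ids = [refs[i] for i in perm[:n_train]]
        base_ids = [refs[i] for i in perm[n_train:]]
        train_corpus = corpus.subset_speakers(train_ids)
        weights = estimate_equilibrium(build_events(train_corpus, ns, diacritics_mode))
        baseline = baseline_profile(weights, corpus.subset_speakers(base_ids), ns, diacritics_mode)
        for s, records in by_speaker.items():
            d = speaker_distance(weights, baseline, records, mode, ns, diacritics_mode)
            per_speaker[s].append(d.aggregate)
    return {
        s: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for s, v in per_speaker.items()
    }


@dataclass
class AsymmetricDistanceMatrix:
    """Listener (row) × speaker (column) distances with an exactly-zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")

    def cell(self, listener: str, speaker: str) -> float:
        return float(self.values[self.labels.index(listener), self.labels.index(speaker)])

    def off_diagonal(self) -> list[float]:
        k = len(self.labels)
        return [float(self.values[i, j]) for i in range(k) for j in range(k) if i != j]

    def write_tsv(self, path, decimals: int = 3, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("Listener\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.{decimals}f}" for v in row) + "\n")


def dialect_matrix(
    per_dialect_corpora: Mapping[str, Corpus],
    n: int | Sequence[int] = 3,
    diacritics_mode: DiacriticsMode = "strip",
    mode: DistanceMode = "signed",
) -> AsymmetricDistanceMatrix:
    """All pairwise listener-dependent distances between dialects.

    Row i is a listener trained on dialect i's own pronunciations; its
    baseline is the activation of its own speech.  Cell (i, j) is the mean
    activation shortfall of dialect j's pronunciations under listener i.
    The diagonal is identically 0 (a dialect heard by its own listener
    reproduces the baseline) and off-diagonal cells need not be symmetric.
    """
    labels = list(per_dialect_corpora)
    if len(labels) < 2:
        raise ValueError("need at least 2 dialects")
    for lab, c in per_dialect_corpora.items():
        if len(c) == 0:
            raise ValueError(f"dialect {lab!r} has an empty corpus")
    ns = (n,) if isinstance(n, int) else tuple(n)
    k = len(labels)
    values = np.zeros((k, k))
    for i, li in enumerate(labels):
        own = per_dialect_corpora[li]
        weights = estimate_equilibrium(build_events(own, ns, diacritics_mode))
        baseline = baseline_profile(weights, own, ns, diacritics_mode)
        for j, lj in enumerate(labels):
            if i == j:
                continue  # self-distance is 0 by construction
            other = per_dialect_corpora[lj]
            per_meaning: list[float] = []
            for records in other.by_speaker().values():
                d = speaker_distance(weights, baseline, records, mode, ns, diacritics_mode)
                per_meaning.append(d.aggregate)
            values[i, j] = float(np.mean(per_meaning))
    return AsymmetricDistanceMatrix(labels=labels, values=values)


def log_transform(
    distances: Sequence[float],
    epsilon_policy: Literal["exclude", "epsilon"] = "exclude",
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of non-negative distances.

    Exact zeros are either excluded (default; the count is logged) or shifted
    by a documented epsilon.  Returns ``(kept_mask, transformed)`` where
    ``transformed`` has one entry per kept distance.  Order among positive
    values is preserved, so correlations are invariant to the log base.
    """
    arr = np.asarray(distances, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    if epsilon_policy == "epsilon":
        return np.ones(len(arr), dtype=bool), np.log(arr + epsilon)
    mask = arr > 0
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("log_transform: excluded %d zero distance(s)", n_dropped)
    return mask, np.log(arr[mask])
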