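"""Shared fixtures: worked-example corpora and the synthetic accent pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from ndldist import (
    Corpus,
    PronunciationRecord,
    WeightMatrix,
    aggregate_levenshtein,
    baseline_profile,
    build_events,
    estimate_equilibrium,
    generate_lexicon,
    parse_ipa,
    perturb_speaker,
    speaker_distance,
)
from ndldist.synthetic import PerturbationModel

#: The shared elicitation paragraph read by every speaker in the accent corpus.
STELLA_PARAGRAPH = (
    "Please call Stella. Ask her to bring these things with her from the "
    "store: six spoons of fresh snow peas, five thick slabs of blue cheese, "
    "and maybe a snack for her brother Bob. We also need a small plastic "
    "snake and a big toy frog for the kids. She can scoop these things into "
    "three red bags, and we will go meet her Wednesday at the train station."
)

INVENTORY = list("ptkbdgmnslrieaou")


@pytest.fixture
def table3_corpus() -> Corpus:
    """The published 4-row training excerpt: two speakers, two words."""
    return Corpus(
        [
            PronunciationRecord("english23", "with", parse_ipa("[wɪθ]"), 28_169_384),
            PronunciationRecord("english167", "with", parse_ipa("[wɪð]"), 28_169_384),
            PronunciationRecord("english23", "her", parse_ipa("[hɚɹ]"), 852_131),
            PronunciationRecord("english167", "her", parse_ipa("[ɚ]"), 852_131),
        ]
    )


@pytest.fixture
def table4_weights() -> WeightMatrix:
    """The published association strengths of the simulated native listener
    (estimated from 58 speakers; here taken as printed, 4 decimals)."""
    cues = ["#wɪ", "wɪθ", "ɪθ#", "wɪð", "ɪð#", "#hɚ", "hɚɹ", "ɚɹ#", "#ɚ#"]
    V = np.array(
        [
            [0.2519, 0.0],
            [0.3738, 0.0],
            [0.3738, 0.0],
            [0.3741, 0.0],
            [0.3741, 0.0],
            [0.0, 0.4973],
            [0.0, 0.2433],
            [0.0, 0.2594],
            [0.0, 1.0000],
        ]
    )
    return WeightMatrix(cues=cues, outcomes=["with", "her"], V=V)


def run_accent_pipeline(
    seed: int,
    rates: tuple[float, ...] = (0.0, 0.1, 0.3),
    n_words: int = 30,
    extra_speakers: int = 0,
    rate_span: tuple[float, float] = (0.02, 0.4),
):
    """Train a listener on a canonical synthetic lexicon and score perturbed
    speakers against it.

    Returns (ndl_distances, lev_distances): dicts keyed by speaker id, with
    the speakers at the requested ``rates`` named ``rate<i>`` and optional
    extra speakers (rates spread over ``rate_span``) named ``spk<i>``.
    """
    canonical = generate_lexicon(n_words, INVENTORY, seed=seed)
    weights = estimate_equilibrium(build_events(canonical, 3))
    baseline = baseline_profile(weights, canonical, 3)

    speakers: dict[str, tuple[float, str]] = {}
    for i, r in enumerate(rates):
        speakers[f"rate{i}"] = (r, f"rate{i}")
    for i, r in enumerate(np.linspace(*rate_span, extra_speakers)):
        speakers[f"spk{i:02d}"] = (float(r), f"spk{i:02d}")

    ndl: dict[str, float] = {}
    lev: dict[str, float] = {}
    for name, (rate, sid) in speakers.items():
        model = PerturbationModel(
            substitution=rate, insertion=rate / 3, deletion=rate / 3, inventory=INVENTORY, seed=seed
        )
        spk = perturb_speaker(canonical, model, sid)
        ndl[name] = speaker_distance(weights, baseline, spk.records, "signed", 3).aggregate
        lev[name] = aggregate_levenshtein(canonical, spk)
    return ndl, lev
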