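"""N-gram cue extraction.

A listener model's input features ("cues") are contiguous windows of n phone
segments over the boundary-padded transcription.  For n >= 2 the word is
padded with one ``'#'`` on each side, so a k-segment word yields k trigram
windows (or k+1 bigram windows); a single-segment word [a] yields the lone
trigram ``#a#``.  Unigram cues are the bare segments without boundary
padding, since a boundary unigram would co-occur with every word and carry no
discriminative information.

Cues are *types*: a window occurring twice in one word contributes one cue.
"""

from __future__ import annotations

from typing import Iterable

from .corpus_io import BOUNDARY, DiacriticsMode, Transcription

VALID_N = (1, 2, 3)


def extract_cues(
    t: Transcription,
    n: int = 3,
    diacritics_mode: DiacriticsMode = "strip",
) -> frozenset[str]:
    """Return the set of n-gram cue labels for one pronunciation token.

    Each cue label is the concatenation of the rendered segments in the
    window (boundary positions render as ``'#'``).  In ``strip`` mode
    diacritics are removed before rendering, so two pronunciations differing
    only in diacritics map to the same cues.
    """
    if n not in VALID_N:
        raise ValueError(f"n must be one of {VALID_N}, got {n}")
    if diacritics_mode == "strip":
        t = t.strip_diacritics()
    symbols = [s.render() for s in t.segments]
    if n == 1:
        return frozenset(symbols)
    padded = [BOUNDARY, *symbols, BOUNDARY]
    return frozenset("".join(padded[i : i + n]) for i in range(len(padded) - n + 1))


def extract_cues_multi(
    t: Transcription,
    ns: Iterable[int],
    diacritics_mode: DiacriticsMode = "strip",
) -> frozenset[str]:
    """Union of cue sets for several n-gram orders (e.g. unigrams+trigrams)."""
    out: frozenset[str] = frozenset()
    for n in ns:
        out |= extract_cues(t, n, diacritics_mode)
    if not out:
        raise ValueError("at least one n-gram order required")
    return out
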