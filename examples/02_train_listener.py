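"""Train a tiny listener model and inspect weights and activations.

Two speakers pronounce two words; trigram cues over the boundary-padded
transcriptions are linked to the word meanings, and the equilibrium
association weights are solved directly.  A foreign pronunciation then
activates its meaning only through the cues the listener already knows.
"""

from ndldist import (
    Corpus,
    PronunciationRecord,
    activation,
    build_events,
    estimate_equilibrium,
    extract_cues,
    parse_ipa,
)

corpus = Corpus(
    [
        PronunciationRecord("english23", "with", parse_ipa("[wɪθ]"), 28_169_384),
        PronunciationRecord("english167", "with", parse_ipa("[wɪð]"), 28_169_384),
        PronunciationRecord("english23", "her", parse_ipa("[hɚɹ]"), 852_131),
        PronunciationRecord("english167", "her", parse_ipa("[ɚ]"), 852_131),
    ]
)

weights = estimate_equilibrium(build_events(corpus, n=3))
print(f"{len(weights.cues)} cues x {len(weights.outcomes)} outcomes, solver residual {weights.residual:.1e}")
print(weights.to_frame().round(4), "\n")

# a native token activates its meaning fully...
native = extract_cues(parse_ipa("[wɪθ]"), 3)
print(f"activation('with' | [wɪθ]) = {activation(weights, native, 'with'):.4f}")

# ...while an accented one only gets credit for the cues the listener knows
accented = extract_cues(parse_ipa("[wɪz]"), 3)
print(f"activation('with' | [wɪz]) = {activation(weights, accented, 'with'):.4f}")
print("(only the familiar '#wɪ' cue contributes; 'wɪz' and 'ɪz#' were never seen)")
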