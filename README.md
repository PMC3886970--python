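# ndldist

Pronunciation distances grounded in discriminative learning, for
dialectometry, sociolinguistics and second-language research.

Measures of how far apart two pronunciations are underpin work on dialect
relationships, comprehensibility between related varieties, and the
native-likeness of accented speech. The standard tool, Levenshtein edit
distance over phonetic transcriptions, is symmetric by construction — but
perceptual distances between varieties often are not: listeners understand
some other varieties better than those varieties understand them. This
package implements a distance that models the *listener*: it learns, from a
variety's own transcribed speech, how strongly sound sequences predict word
meanings, and measures how much a new pronunciation under-activates the
intended meaning for that trained listener.

## The model

A listener is a Rescorla–Wagner learner. Cues are phone **trigrams** over the
boundary-padded transcription (for `[wɪθ]`: `#wɪ`, `wɪθ`, `ɪθ#`; unigram and
bigram cues are also supported); outcomes are word meanings; each
pronunciation token is a learning event weighted by word frequency. Rather
than simulating learning trial by trial, the stable adult weights are
obtained directly from the equilibrium conditions

&nbsp;&nbsp;&nbsp;&nbsp; Σⱼ P(cⱼ | cᵢ) · V(cⱼ, O) = P(O | cᵢ) for every cue cᵢ,

a linear system per outcome in the cue–cue and cue–outcome conditional
probabilities (solved by minimum-norm least squares; trigram cues routinely
co-occur perfectly and make the system rank-deficient). The **activation**
of an outcome for a presented pronunciation is the sum of the learned
weights of its cues; cues never seen in training contribute exactly 0.

The **pronunciation distance** from a reference variety to a speaker is the
mean, over the shared word list, of the baseline activation (what the
listener gets from reference speech) minus the speaker's activation. A
listener trained on dialect *i* scoring dialect *j* gives cell (*i*, *j*) of
an asymmetric dialect-distance matrix whose diagonal is exactly zero.

Also included: plain and cost-weighted Levenshtein alignment as the
comparator method, PMI-learned segment costs, Pearson/Cronbach evaluation
utilities for perceptual rating studies, an incremental Rescorla–Wagner
simulator (for cross-checking the equilibrium solver and classic effects
such as blocking), and seeded synthetic corpus/ratings generators.

## Worked example

```python
from ndldist import (Corpus, PronunciationRecord, parse_ipa, build_events,
                     estimate_equilibrium, extract_cues, activation)

corpus = Corpus([
    PronunciationRecord("english23",  "with", parse_ipa("[wɪθ]"), 28_169_384),
    PronunciationRecord("english167", "with", parse_ipa("[wɪð]"), 28_169_384),
    PronunciationRecord("english23",  "her",  parse_ipa("[hɚɹ]"),    852_131),
    PronunciationRecord("english167", "her",  parse_ipa("[ɚ]"),      852_131),
])
weights = estimate_equilibrium(build_events(corpus, n=3))   # 9 cues x 2 outcomes
print(activation(weights, extract_cues(parse_ipa("[wɪθ]"), 3), "with"))
print(activation(weights, extract_cues(parse_ipa("[wɪz]"), 3), "with"))
```

prints

```
1.0000
0.5000
```

The native token `[wɪθ]` activates its meaning fully; the accented `[wɪz]`
gets credit only for the one familiar cue `#wɪ` — the cues `wɪz` and `ɪz#`
were never encountered in training and contribute nothing. The
`examples/` directory has one short script per capability (alignment,
training, the asymmetric dialect matrix, the full synthetic accent
pipeline), each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
ndldist train corpus.tsv -o weights.tsv
ndldist dialect-matrix d1.tsv d2.tsv d3.tsv -o matrix.tsv
ndldist accent-distance corpus.tsv -r ref1,ref2,ref3 -o dist.tsv --reps 100 --seed 1
ndldist evaluate --distances dist.tsv --ratings ratings.tsv
```

All file formats are UTF-8 TSV (`Speaker Outcome Pronunciation Frequency`
corpora, `Rater Sample Score` ratings, cue × outcome weight matrices);
`#` is reserved as the word-boundary marker and cannot occur in a
pronunciation.

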