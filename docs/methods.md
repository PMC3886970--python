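# Methods

## Model

A listener model is a table V of association strengths between cues (phone
n-grams) and outcomes (word meanings), the asymptotic state of
Rescorla–Wagner error-driven learning. On each learning trial with cue set
S and outcome O, every present cue c updates by

    ΔV(c, O')  =  αβ₁ (λ − Σ_{c'∈S} V(c', O'))   if O' = O occurred
    ΔV(c, O')  =  αβ₂ (0 − Σ_{c'∈S} V(c', O'))   otherwise

with asymptote λ = 1, a shared cue salience α and learning rates β₁ = β₂, so
only the product αβ matters. Absent cues are untouched. The order-independent
fixed point of this process satisfies, per outcome O and for every trained
cue cᵢ,

    Σⱼ P(cⱼ | cᵢ) V(cⱼ, O) = P(O | cᵢ),

where the conditional probabilities are frequency-weighted co-occurrence
ratios over the learning events. `estimate_equilibrium` builds this linear
system once over the full cue set and solves it for all outcomes
simultaneously.

The activation of outcome O for a presented cue set is Σ_{c∈S} V(c, O),
summing only over cues with a trained row; unknown cues contribute exactly
zero (this rule lives in `activation`, not in storage, so weight matrices
contain only trained cues).

## Distances

For an accent study, a reference speaker group is split: one half trains the
listener, the other half's speech defines the per-meaning **baseline**
activation (token-averaged within speaker first, then averaged across
speakers, so prolific speakers do not dominate). A speaker's distance is the
mean over covered meanings of (baseline − speaker activation), token-averaged
per meaning. The split is resampled (default 100 repetitions, train fraction
0.5) and per-speaker means and standard deviations over repetitions are
reported. For a dialect study with one corpus per dialect, listener i is
trained on dialect i and its own activations are the baseline; cell (i, j)
is the mean shortfall of dialect j under listener i. The diagonal is
identically zero and is set to zero exactly rather than recomputed.

Signed differences are the default (`mode="signed"`): foreign cues can only
fail to contribute weight, so negative aggregates are rare and, when they
occur, interpretable (the test variety activates meanings *better* than the
baseline). An absolute mode is available. Meanings a test speaker never
produces are skipped with a warning rather than scored — in the intended
elicitation design every speaker reads the full word list, so no penalty
convention is invented for the missing case.

Distances are often log-transformed before correlating with perceptual
ratings (the relationship is typically logarithmic). Exact zeros are
excluded by default, with an epsilon-shift policy as the alternative; Pearson
correlations are invariant to the log base.

## Cues

For n ≥ 2 the segment sequence is padded with one `#` per side and every
contiguous window of n symbols is a cue; a k-segment word yields k trigrams
(a one-segment word yields the single trigram `#a#`). Unigram cues omit the
boundary, which would co-occur with every word and carry no discrimination.
Cue sets have *type* semantics: a window occurring twice in one word counts
once, consistent with the presence/absence formulation of the equilibrium
equations. Mixed registries (e.g. unigrams + trigrams) are unions of the
per-order sets.

Diacritics are stripped by default (`diacritics_mode="strip"`) and can be
kept, in which case they travel with their base segment into cue labels. A
codepoint counts as a diacritic iff it is a Unicode combining mark
(categories Mn/Mc/Me) or appears in an explicit table of spacing modifier
letters (the U+02B0–U+02FF block and phonetic-extension superscripts);
the table is visible in `corpus_io.MODIFIER_DIACRITICS` and extensible per
call. Tie bars attach to the left base, giving deterministic single-pass
parsing. Multi-character affricates/diphthongs are one segment per base
character; no digraph table is applied by default.

## Numerical choices

- **Rank deficiency.** Trigram cues that always co-occur make the cue–cue
  conditional probability matrix singular. The system is solved by
  minimum-norm least squares (`numpy.linalg.lstsq`), which is deterministic
  and coincides with the weights incremental learning reaches from zero
  initialisation (updates stay in the row space). The worst per-outcome
  residual ‖P·V − b‖∞ is recorded on the result; it is ≤ 1e−8 whenever the
  system is consistent.
- **Scale invariance.** Only conditional probabilities enter the system, so
  multiplying all corpus frequencies by a constant leaves V unchanged (to
  1e−10 in tests); frequency *ratios* between words are what matters.
- **Simulator regimes.** `simulate_rw` expands events into a deterministic
  frequency-proportional interleaved stream (largest-remainder quotas,
  evenly spread) or samples trials multinomially under a seed. Convergence
  to the equilibrium is governed by two opposing effects: the residual
  limit-cycle amplitude shrinks with αβ, while convergence time along small
  co-occurrence eigenvalues grows as 1/(αβ). αβ = 0.02 with 10⁵ trials
  lands within 0.02 of the equilibrium on all tested instances.
- **Alignment tie-breaks.** The Levenshtein backtrace prefers
  match/substitution over deletion over insertion, making alignments (not
  just totals) deterministic.
- **PMI costs.** Segment costs are learned by iterating alignment and
  counting: PMI(x,y) = log₂ p(x,y)/(p(x)p(y)) with additive smoothing 0.5
  over the observed alphabet (gap included as a pseudo-segment), mapped
  linearly so the highest observed PMI gets cost 0 and the lowest cost 1;
  identity pairs stay at 0. The mapping is a documented, pluggable choice —
  the PMI-to-distance normalisation used in prior dialectometry work is not
  fully published, so no equivalence is claimed. Iteration stops at an
  alignment fixed point or the iteration cap (default 5).
- **Cronbach's alpha** treats raters as items and samples as observations.
  With incomplete rating designs the default pairwise policy uses each
  rater's variance over the samples they rated and scales per-sample mean
  scores to full-panel totals; this can push alpha marginally past 1 for
  near-perfectly consistent raters. A complete-case policy is available.

## Synthetic data

`generate_lexicon` emulates an elicitation word list: distinct random
segment strings over a configurable inventory (default lengths 3–7),
frequencies Zipf-distributed with exponent 1 and the top word at 10,000 —
word-frequency distributions in natural corpora are approximately Zipfian,
and the equilibrium solver only uses ratios. `perturb_speaker` derives a
variety by i.i.d. per-segment substitution / insertion / deletion;
substitutions follow a confusion map defaulting to a nearest-neighbour ring
over the ordered inventory (a crude stand-in for phonetic similarity), and
words are redrawn rather than allowed to become empty. `generate_ratings`
maps the observed distance range linearly onto a 1–7 Likert scale, most
native-like at the top, adds Gaussian rater noise, rounds and clips. Every
generator is bit-reproducible under a fixed seed, with per-speaker RNG
streams keyed by (seed, CRC32 of the speaker id).

What the generators do *not* emulate: phonologically structured variation
(sound changes conditioned on context), within-variety speaker variation
beyond the i.i.d. edit model, suprasegmental features, or transcription
noise. Passing synthetic tests therefore shows that the pipeline recovers
distances from segmental divergence under controlled conditions, not that
it matches human perceptual data — validation against real rating studies
requires the external archives those studies used.

Test and acceptance problem sizes — 20–30 word lexicons, a dozen speakers,
20 Monte-Carlo seeds — keep each equilibrium solve in the hundreds of cues,
where the full pipeline runs in seconds while leaving every qualitative
contract (monotonicity in perturbation rate, negative rating correlations,
agreement with the Levenshtein comparator) clearly resolvable.

## Known limitations

- Continuous cues (duration, intonation) are out of scope; only discrete
  segmental n-grams are supported.
- The equilibrium solve is dense O(C³) in the number of cues; corpora far
  beyond elicitation-paragraph scale would need sparse or iterative solvers.
- Asymmetric distances from single-speaker dialect corpora conflate
  speaker idiosyncrasy with dialect difference; multiple speakers per
  variety sharpen the estimates.
- `accent_distance_resampled` reports dispersion as the standard deviation
  over resampling repetitions; it is not a confidence interval.
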