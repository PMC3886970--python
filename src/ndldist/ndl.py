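"""Discriminative learning of cue→outcome association strengths.

Two estimators are provided for the same quantity, the Rescorla–Wagner
association weight matrix V (cues × outcomes):

* :func:`estimate_equilibrium` solves the Danks equilibrium equations
  directly.  For each outcome O the long-run weights satisfy, for every
  cue c_i seen in training,

      sum_j P(c_j | c_i) * V(c_j, O)  =  P(O | c_i),

  where both conditional probabilities are frequency-weighted co-occurrence
  ratios over the learning events.  This is the order-independent fixed
  point of incremental learning and is what the distance pipeline uses.

* :func:`simulate_rw` runs the incremental Rescorla–Wagner update
  trial-by-trial.  It exists as an independent route to the same weights
  (at small learning rates and long runs) and to expose classic phenomena
  such as blocking.

Activations of an outcome for a presented cue set are sums of the learned
weights; cues never seen in training contribute exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, DiacriticsMode
from .cues import extract_cues_multi


@dataclass(frozen=True)
class Event:
    """One learning event: a cue set paired with a single meaning outcome."""

    cues: frozenset[str]
    outcome: str
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if not self.cues:
            raise ValueError("event must have at least one cue")
        if self.frequency <= 0:
            raise ValueError(f"event frequency must be positive, got {self.frequency}")


@dataclass(frozen=True)
class RWParams:
    """Rescorla–Wagner learning parameters.

    lambda_max is the asymptote of the total association an outcome can
    accrue (1 by default); alpha is the (shared) cue salience and
    beta_present / beta_absent the learning rates on outcome-present and
    outcome-absent trials.  The standard configuration keeps all saliences
    equal and the two betas equal, so only the product alpha*beta matters.
    """

    lambda_max: float = 1.0
    alpha: float = 0.1
    beta_present: float = 0.1
    beta_absent: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be positive")
        for name in ("alpha", "beta_present", "beta_absent"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class WeightMatrix:
    """Learned association strengths V for trained cues × outcomes.

    Only cues seen in training have a row; the unknown-cue → zero rule lives
    in :func:`activation`, not in storage.
    """

    cues: list[str]
    outcomes: list[str]
    V: np.ndarray  # shape (n_cues, n_outcomes)
    residual: float = 0.0
    _cue_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.V.shape != (len(self.cues), len(self.outcomes)):
            raise ValueError("V shape does not match cue/outcome labels")
        if not np.all(np.isfinite(self.V)):
            raise ValueError("weight matrix contains non-finite entries")
        self._cue_index = {c: i for i, c in enumerate(self.cues)}

    def weight(self, cue: str, outcome: str) -> float:
        i = self._cue_index.get(cue)
        if i is None:
            return 0.0
        return float(self.V[i, self.outcomes.index(outcome)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.cues, columns=self.outcomes)

    def write_tsv(self, path: str | Path, decimals: int = 10, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("Cue\t" + "\t".join(self.outcomes) + "\n")
            for cue, row in zip(self.cues, self.V):
                cells = "\t".join(f"{v:.{decimals}f}" for v in row)
                fh.write(f"{cue}\t{cells}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "WeightMatrix":
        # cue labels legitimately contain '#', so only leading '# '-prefixed
        # header lines are comments; parse the body by hand
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        body = [ln for ln in lines if ln and not ln.startswith("# ")]
        header = body[0].split("\t")
        if header[0] != "Cue":
            raise ValueError(f"not a weight-matrix TSV: header starts with {header[0]!r}")
        outcomes = header[1:]
        cues, rows = [], []
        for ln in body[1:]:
            cells = ln.split("\t")
            cues.append(cells[0])
            rows.append([float(v) for v in cells[1:]])
        return cls(cues=cues, outcomes=outcomes, V=np.asarray(rows))


def build_events(
    corpus: Corpus,
    n: int | Sequence[int] = 3,
    diacritics_mode: DiacriticsMode = "strip",
) -> list[Event]:
    """Convert a corpus into learning events: one event per pronunciation token.

    ``n`` may be a single n-gram order or several (their cue sets are
    unioned).
    """
    if len(corpus) == 0:
        raise ValueError("corpus has no records")
    ns = (n,) if isinstance(n, int) else tuple(n)
    return [
        Event(
            cues=extract_cues_multi(r.transcription, ns, diacritics_mode),
            outcome=r.meaning,
            frequency=r.frequency,
        )
        for r in corpus
    ]


def _index_events(events: Sequence[Event]) -> tuple[list[str], list[str]]:
    cues = list(dict.fromkeys(c for e in events for c in sorted(e.cues)))
    outcomes = list(dict.fromkeys(e.outcome for e in events))
    return cues, outcomes


def estimate_equilibrium(events: Sequence[Event]) -> WeightMatrix:
    """Solve the Danks equilibrium equations for all outcomes at once.

    Builds the cue–cue conditional probability matrix
    P[i, j] = freq(c_i and c_j) / freq(c_i) and the cue–outcome conditional
    probabilities b[i, O] = freq(c_i and O) / freq(c_i), then solves
    P @ V = b per outcome.  Cue co-occurrence matrices are routinely rank
    deficient (trigrams that always travel together), so the system is
    solved by minimum-norm least squares; the worst residual across outcomes
    is recorded on the result.

    The conditional probabilities make the solution invariant to a global
    rescaling of the event frequencies.
    """
    if not events:
        raise ValueError("no events to learn from")
    cues, outcomes = _index_events(events)
    ci = {c: i for i, c in enumerate(cues)}
    oi = {o: i for i, o in enumerate(outcomes)}
    n_c, n_o = len(cues), len(outcomes)

    cooc = np.zeros((n_c, n_c))
    cue_out = np.zeros((n_c, n_o))
    for e in events:
        idx = np.fromiter((ci[c] for c in e.cues), dtype=int)
        cooc[np.ix_(idx, idx)] += e.frequency
        cue_out[idx, oi[e.outcome]] += e.frequency

    totals = np.diag(cooc).copy()
    # every indexed cue occurs in >=1 event with positive frequency
    P = cooc / totals[:, None]
    b = cue_out / totals[:, None]

    V, res, rank, _ = np.linalg.lstsq(P, b, rcond=None)
    residual = float(np.max(np.abs(P @ V - b)))
    return WeightMatrix(cues=cues, outcomes=outcomes, V=V, residual=residual)


def _frequency_schedule(events: Sequence[Event], n_trials: int) -> list[int]:
    """Deterministic frequency-proportional interleaving (largest remainder).

    Returns event indices, length n_trials, in which each event appears a
    number of times proportional to its frequency, spread evenly through the
    stream (round-robin over quota-weighted positions).
    """
    freqs = np.array([e.frequency for e in events], dtype=float)
    quota = freqs / freqs.sum() * n_trials
    counts = np.floor(quota).astype(int)
    short = n_trials - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    # interleave by scheduling each event's k-th copy at fractional position k/count
    slots: list[tuple[float, int]] = []
    for i, c in enumerate(counts):
        for k in range(c):
            slots.append(((k + 0.5) / c, i))
    slots.sort(key=lambda t: (t[0], t[1]))
    return [i for _, i in slots]


def simulate_rw(
    events: Sequence[Event],
    params: RWParams = RWParams(),
    n_trials: int = 10_000,
    seed: int | None = None,
    regime: Literal["interleave", "sample"] = "interleave",
    initial: WeightMatrix | None = None,
) -> WeightMatrix:
    """Run incremental Rescorla–Wagner learning over a trial stream.

    On each trial the presented cues share the prediction for every outcome;
    present cues are updated by alpha*beta1*(lambda - V_total) when the
    outcome occurred and by alpha*beta2*(0 - V_total) when it did not, where
    V_total sums the present cues' current weights for that outcome.  Absent
    cues are untouched.

    ``regime='interleave'`` expands the events into a deterministic
    frequency-proportional stream; ``regime='sample'`` draws trials
    multinomially with the given seed.  ``initial`` seeds the run with
    previously learned weights (e.g. to stage a blocking experiment).
    """
    if not events:
        raise ValueError("no events to learn from")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cues, outcomes = _index_events(events)
    if initial is not None:
        cues = list(dict.fromkeys(initial.cues + cues))
        outcomes = list(dict.fromkeys(initial.outcomes + outcomes))
    ci = {c: i for i, c in enumerate(cues)}
    oi = {o: i for i, o in enumerate(outcomes)}
    V = np.zeros((len(cues), len(outcomes)))
    if initial is not None:
        for a, cue in enumerate(initial.cues):
            for b, out in enumerate(initial.outcomes):
                V[ci[cue], oi[out]] = initial.V[a, b]

    if regime == "sample":
        rng = np.random.default_rng(seed)
        freqs = np.array([e.frequency for e in events], dtype=float)
        stream = rng.choice(len(events), size=n_trials, p=freqs / freqs.sum())
    elif regime == "interleave":
        stream = _frequency_schedule(events, n_trials)
    else:
        raise ValueError(f"unknown regime {regime!r}")

    ab1 = params.alpha * params.beta_present
    ab2 = params.alpha * params.beta_absent
    lam = params.lambda_max
    event_cue_idx = [np.fromiter((ci[c] for c in e.cues), dtype=int) for e in events]
    for ev in stream:
        idx = event_cue_idx[ev]
        present_total = V[idx].sum(axis=0)  # per outcome
        delta = -ab2 * present_total
        j = oi[events[ev].outcome]
        delta[j] = ab1 * (lam - present_total[j])
        V[idx] += delta
        if not np.all(np.isfinite(V[idx])):
            raise FloatingPointError("association weights diverged; lower the learning rate")
    return WeightMatrix(cues=cues, outcomes=outcomes, V=V)


def activation(weights: WeightMatrix, cues: Iterable[str], outcome: str) -> float:
    """Sum association strengths of the presented cues for one outcome.

    Cues absent from the weight matrix were never seen in training, carry no
    association strength, and contribute exactly 0.
    """
    if outcome not in weights.outcomes:
        raise KeyError(f"unknown outcome {outcome!r}; known outcomes: {sorted(weights.outcomes)}")
    j = weights.outcomes.index(outcome)
    total = 0.0
    for c in cues:
        i = weights._cue_index.get(c)
        if i is not None:
            total += weights.V[i, j]
    return float(total)


def activation_profile(weights: WeightMatrix, cues: Iterable[str]) -> dict[str, float]:
    """Activations of every known outcome for one presented cue set."""
    cue_list = list(cues)
    idx = [weights._cue_index[c] for c in cue_list if c in weights._cue_index]
    if not idx:
        return {o: 0.0 for o in weights.outcomes}
    sums = weights.V[idx].sum(axis=0)
    return {o: float(s) for o, s in zip(weights.outcomes, sums)}
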