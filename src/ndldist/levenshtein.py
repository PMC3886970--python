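"""Levenshtein alignment between phone-segment strings.

The comparator method: a dynamic-programming alignment over segment
sequences, either with unit costs (the classic edit distance) or with a
symmetric table of segment–segment and segment–gap costs in [0, 1].
Sensitive costs can be learned from corpus alignments via pointwise mutual
information: segment pairs that align more often than chance get a low
substitution cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Transcription

#: Sentinel label for an alignment gap (insertion/deletion partner).
GAP = "-"


def _labels(t: "Transcription | Sequence[str]") -> list[str]:
    if isinstance(t, Transcription):
        return [s.render() for s in t.segments]
    return list(t)


class SegmentCostTable:
    """Symmetric (segment | gap) pair costs in [0, 1]; cost(x, x) = 0.

    Pairs absent from the table fall back to ``default`` (1 by default,
    i.e. unit cost), so a partial table degrades gracefully to plain
    Levenshtein behaviour.
    """

    def __init__(self, costs: Mapping[tuple[str, str], float] | None = None, default: float = 1.0):
        self.default = float(default)
        self._costs: dict[tuple[str, str], float] = {}
        if costs:
            for (x, y), c in costs.items():
                self[x, y] = c

    def __setitem__(self, pair: tuple[str, str], cost: float) -> None:
        x, y = pair
        if cost < 0:
            raise ValueError(f"negative cost {cost} for pair ({x!r}, {y!r})")
        self._costs[(x, y)] = float(cost)
        self._costs[(y, x)] = float(cost)

    def cost(self, x: str, y: str) -> float:
        if x == y:
            return 0.0
        return self._costs.get((x, y), self.default)

    def items(self):
        return self._costs.items()

    def write_tsv(self, path: str | Path, decimals: int = 6) -> None:
        seen = set()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Seg1\tSeg2\tCost\n")
            for (x, y), c in sorted(self._costs.items()):
                if (y, x) in seen:
                    continue
                seen.add((x, y))
                fh.write(f"{x}\t{y}\t{c:.{decimals}f}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, default: float = 1.0) -> "SegmentCostTable":
        table = cls(default=default)
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                x, y, c = line.rstrip("\n").split("\t")
                table[x, y] = float(c)
        return table


@dataclass
class AlignmentResult:
    """An optimal alignment: paired segments (with gaps), their costs, the total."""

    pairs: list[tuple[str, str]]
    costs: list[float]
    total: float

    def __post_init__(self) -> None:
        assert math.isclose(self.total, sum(self.costs), abs_tol=1e-9)

    def side(self, which: int) -> list[str]:
        """One input sequence recovered by dropping gap sentinels."""
        return [p[which] for p in self.pairs if p[which] != GAP]


def align(
    t1: "Transcription | Sequence[str]",
    t2: "Transcription | Sequence[str]",
    costs: SegmentCostTable | None = None,
) -> AlignmentResult:
    """Optimal alignment of two segment sequences by dynamic programming.

    With ``costs=None`` every substitution, insertion and deletion costs 1
    and the total is the classic Levenshtein distance.  Ties on the
    backtrace break deterministically: match, then substitution, then
    deletion (gap in ``t2``), then insertion.
    """
    a, b = _labels(t1), _labels(t2)
    table = costs if costs is not None else SegmentCostTable()
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        D[i, 0] = D[i - 1, 0] + table.cost(a[i - 1], GAP)
    for j in range(1, m + 1):
        D[0, j] = D[0, j - 1] + table.cost(GAP, b[j - 1])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + table.cost(a[i - 1], b[j - 1]),
                D[i - 1, j] + table.cost(a[i - 1], GAP),
                D[i, j - 1] + table.cost(GAP, b[j - 1]),
            )

    pairs: list[tuple[str, str]] = []
    step_costs: list[float] = []
    i, j = n, m
    tol = 1e-12
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            c = table.cost(a[i - 1], b[j - 1])
            if abs(D[i, j] - (D[i - 1, j - 1] + c)) < tol:
                pairs.append((a[i - 1], b[j - 1]))
                step_costs.append(c)
                i, j = i - 1, j - 1
                continue
        if i > 0:
            c = table.cost(a[i - 1], GAP)
            if abs(D[i, j] - (D[i - 1, j] + c)) < tol:
                pairs.append((a[i - 1], GAP))
                step_costs.append(c)
                i -= 1
                continue
        c = table.cost(GAP, b[j - 1])
        pairs.append((GAP, b[j - 1]))
        step_costs.append(c)
        j -= 1
    pairs.reverse()
    step_costs.reverse()
    return AlignmentResult(pairs=pairs, costs=step_costs, total=float(D[n, m]))


def learn_pmi_costs(
    word_pairs: Sequence[tuple["Transcription | Sequence[str]", "Transcription | Sequence[str]"]],
    n_iterations: int = 5,
    smoothing: float = 0.5,
) -> SegmentCostTable:
    """Learn segment costs from alignment frequencies via PMI.

    Iterates: align every word pair with the current cost table (unit costs
    initially), count the aligned segment pairs over the whole corpus (gaps
    count as a pseudo-segment), compute additively smoothed pointwise mutual
    information PMI(x, y) = log2 p(x, y) / (p(x) p(y)), and map it linearly
    to a cost in [0, 1]: the highest observed PMI becomes cost 0, the lowest
    cost 1.  Identity pairs keep cost 0.  Stops early when the alignments
    reach a fixed point.
    """
    if not word_pairs:
        raise ValueError("no word pairs to learn from")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    table = SegmentCostTable()
    prev_alignments: list[tuple[tuple[str, str], ...]] | None = None
    for _ in range(n_iterations):
        counts: dict[tuple[str, str], float] = {}
        marg: dict[str, float] = {}
        alignments = []
        for t1, t2 in word_pairs:
            res = align(t1, t2, table)
            alignments.append(tuple(res.pairs))
            for x, y in res.pairs:
                key = (x, y) if x <= y else (y, x)
                counts[key] = counts.get(key, 0.0) + 1.0
                marg[x] = marg.get(x, 0.0) + 1.0
                marg[y] = marg.get(y, 0.0) + 1.0
        if not counts:
            raise ValueError("no alignable pairs")
        if alignments == prev_alignments:
            break
        prev_alignments = alignments

        alphabet = sorted(marg)
        n_pairs = sum(counts.values())
        n_types = len(alphabet) * (len(alphabet) + 1) / 2
        pmi: dict[tuple[str, str], float] = {}
        for x in alphabet:
            for y in alphabet:
                if y < x:
                    continue
                joint = (counts.get((x, y), 0.0) + smoothing) / (n_pairs + smoothing * n_types)
                px = marg[x] / (2 * n_pairs)
                py = marg[y] / (2 * n_pairs)
                pmi[(x, y)] = math.log2(joint / (px * py))
        non_identity = {k: v for k, v in pmi.items() if k[0] != k[1]}
        hi = max(non_identity.values())
        lo = min(non_identity.values())
        span = hi - lo
        table = SegmentCostTable()
        for (x, y), v in non_identity.items():
            table[x, y] = 0.0 if span == 0 else (hi - v) / span
    return table


def aggregate_levenshtein(
    corpus_a: Corpus,
    corpus_b: Corpus,
    costs: SegmentCostTable | None = None,
    normalize: str = "none",
) -> float:
    """Mean alignment cost over the shared word list of two corpora.

    For each meaning present in both corpora, every token pair across the
    two sides is aligned and the costs averaged; the per-meaning means are
    then averaged over the shared word list.  ``normalize='length'`` divides
    each word's cost by its alignment length.
    """
    if normalize not in ("none", "length"):
        raise ValueError("normalize must be 'none' or 'length'")
    by_meaning_a: dict[str, list[Transcription]] = {}
    for r in corpus_a:
        by_meaning_a.setdefault(r.meaning, []).append(r.transcription)
    by_meaning_b: dict[str, list[Transcription]] = {}
    for r in corpus_b:
        by_meaning_b.setdefault(r.meaning, []).append(r.transcription)
    shared = [m for m in by_meaning_a if m in by_meaning_b]
    if not shared:
        raise ValueError("corpora share no meanings")
    word_means = []
    for m in shared:
        vals = []
        for ta in by_meaning_a[m]:
            for tb in by_meaning_b[m]:
                res = align(ta, tb, costs)
                vals.append(res.total / len(res.pairs) if normalize == "length" else res.total)
        word_means.append(float(np.mean(vals)))
    return float(np.mean(word_means))
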