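"""Comparison of computed distances with perceptual ratings.

Perceptual validation works on aggregated Likert judgements: per-sample mean
ratings, their internal consistency (Cronbach's alpha over raters), and the
Pearson correlation between the mean ratings and computed pronunciation
distances, on the raw and the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import RatingsTable
from .distance import log_transform


def mean_ratings(ratings: RatingsTable) -> pd.DataFrame:
    """Per-sample mean rating and rating count."""
    df = ratings.to_frame()
    out = df.groupby("sample")["score"].agg(mean="mean", count="size")
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(x, y).statistic)


def cronbach_alpha(ratings: RatingsTable, policy: str = "pairwise") -> float:
    """Internal consistency of raters over samples.

    alpha = k/(k-1) * (1 - sum(item variances) / variance of totals)
    with raters as the k items and samples as the observations, the usual
    orientation for inter-rater consistency.  Raters typically judge only a
    subset of samples; ``policy='pairwise'`` uses each rater's variance over
    the samples they rated and scales per-sample mean scores to totals,
    while ``policy='complete'`` first drops samples not rated by every
    rater.
    """
    df = ratings.to_frame().pivot_table(index="sample", columns="rater", values="score", aggfunc="mean")
    if policy == "complete":
        df = df.dropna(axis=0, how="any")
    k = df.shape[1]
    if k < 2:
        raise ValueError("need at least 2 raters")
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    item_vars = df.var(axis=0, ddof=1, skipna=True)
    # per-sample totals: mean over available raters scaled to k items, so
    # partially rated samples contribute on the same scale as complete ones
    totals = df.mean(axis=1, skipna=True) * k
    total_var = totals.var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance in sample totals")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def rater_consensus_correlation(ratings: RatingsTable, leave_one_out: bool = True) -> float:
    """Mean correlation of each rater's scores with the per-sample mean rating.

    With ``leave_one_out`` the rater's own scores are removed from the means
    they are compared against.
    """
    df = ratings.to_frame()
    sums = df.groupby("sample")["score"].sum()
    counts = df.groupby("sample")["score"].size()
    rs = []
    for rater, sub in df.groupby("rater"):
        sub = sub.groupby("sample")["score"].mean()
        if leave_one_out:
            denom = counts.loc[sub.index] - 1
            ok = denom > 0
            consensus = (sums.loc[sub.index] - sub) / denom
            sub, consensus = sub[ok], consensus[ok]
        else:
            consensus = sums.loc[sub.index] / counts.loc[sub.index]
        if len(sub) >= 3 and sub.std() > 0 and consensus.std() > 0:
            rs.append(pearson(sub.to_numpy(), consensus.to_numpy()))
    if not rs:
        raise ValueError("no rater had enough overlapping ratings")
    return float(np.mean(rs))


@dataclass
class EvaluationReport:
    """Correlation of distances with mean ratings, raw and log-transformed."""

    n: int
    r_raw: float
    r_log: float
    n_log: int
    alpha: float | None
    sample_means: pd.DataFrame


def evaluate(
    distances: Mapping[str, float],
    ratings: RatingsTable,
    compute_alpha: bool = True,
) -> EvaluationReport:
    """Correlate per-sample distances with per-sample mean ratings.

    Samples present in both inputs are used.  The log correlation drops
    exact-zero distances (there is no meaningful log distance for them).
    """
    means = mean_ratings(ratings)
    samples = [s for s in means.index if s in distances]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with both a rating and a distance")
    d = np.array([distances[s] for s in samples], dtype=float)
    m = means.loc[samples, "mean"].to_numpy()
    r_raw = pearson(d, m)
    mask, d_log = log_transform(d, epsilon_policy="exclude")
    r_log = pearson(d_log, m[mask]) if mask.sum() >= 3 else float("nan")
    alpha = cronbach_alpha(ratings) if compute_alpha else None
    return EvaluationReport(
        n=len(samples), r_raw=r_raw, r_log=r_log, n_log=int(mask.sum()), alpha=alpha, sample_means=means
    )
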