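"""Comparison baselines: dependent-DTW 1-NN and multivariate multiscale
permutation entropy.

Dependent DTW (DTWD) warps all channels along one shared path; the
per-step cost pools the m channels at the aligned time pair.  With one
nearest neighbour it is the standard distance-based reference for
multivariate time series classification.

Multivariate multiscale permutation entropy (MMSPE) coarse-grains every
channel at integer scales 1..S, counts ordinal patterns of length d at
lag ``lag`` pooled across channels, and reports the Shannon entropy of
the pattern frequencies — one feature per scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import LabeledCollection, MultivariateSeries
from .multiscale import coarse_grain


# ---------------------------------------------------------------------------
# Dependent DTW
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_dp(cost: np.ndarray) -> float:  # pragma: no cover - numba kernel
    n, m = cost.shape
    d = np.empty((n, m))
    d[0, 0] = cost[0, 0]
    for i in range(1, n):
        d[i, 0] = d[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        d[0, j] = d[0, j - 1] + cost[0, j]
    for i in range(1, n):
        for j in range(1, m):
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = cost[i, j] + best
    return d[n - 1, m - 1]


def dtwd_distance(
    a: MultivariateSeries | np.ndarray,
    b: MultivariateSeries | np.ndarray,
    cost: str = "squared",
) -> float:
    """Dependent multivariate DTW distance between two series.

    One warping path is shared by all channels; the per-step cost is the
    squared Euclidean distance across the m channels at the aligned time
    pair (``cost="squared"``; ``"abs"`` gives the absolute-sum
    alternative).  No warping-window constraint is applied.  For the
    squared cost the square root of the accumulated optimum is returned,
    so two length-1 series give the plain Euclidean distance.
    """
    xa = a.values if isinstance(a, MultivariateSeries) else np.asarray(a, float)
    xb = b.values if isinstance(b, MultivariateSeries) else np.asarray(b, float)
    if xa.ndim == 1:
        xa = xa[:, None]
    if xb.ndim == 1:
        xb = xb[:, None]
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(f"channel mismatch: {xa.shape[1]} vs {xb.shape[1]}")
    diff = xa[:, None, :] - xb[None, :, :]
    if cost == "squared":
        c = np.einsum("ijk,ijk->ij", diff, diff)
        return math.sqrt(_dtw_dp(np.ascontiguousarray(c)))
    elif cost == "abs":
        c = np.abs(diff).sum(axis=2)
        return float(_dtw_dp(np.ascontiguousarray(c)))
    raise ValueError(f"unknown cost {cost!r}")


def dtwd_distance_matrix(
    collection_a: LabeledCollection, collection_b: LabeledCollection | None = None
) -> np.ndarray:
    """Pairwise DTWD distances; symmetric-half computation when b is a."""
    insts_a = collection_a.instances
    if collection_b is None:
        n = len(insts_a)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dtwd_distance(insts_a[i], insts_a[j])
        return d
    return np.array(
        [[dtwd_distance(a, b) for b in collection_b.instances] for a in insts_a]
    )


def nn1_dtwd_classify(
    train: LabeledCollection,
    test: LabeledCollection,
    distances: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray]:
    """1-nearest-neighbour classification under DTWD.

    Each test instance receives the label of its nearest training
    instance (distance ties broken by the lowest train index).  The
    returned score, used for ROC curves, is the margin between the
    nearest positive-class and nearest negative-class neighbours:
    ``d(nearest negative) - d(nearest positive)``, larger meaning more
    positive.

    ``distances`` may carry a precomputed test-by-train DTWD matrix.
    """
    if not train.instances:
        raise ValueError("empty training collection")
    if distances is None:
        distances = dtwd_distance_matrix(test, train)
    labels_arr = np.array(train.labels)
    pos = labels_arr == train.positive_label
    predicted: list[str] = []
    scores = np.empty(len(test.instances))
    for i, row in enumerate(distances):
        predicted.append(str(labels_arr[int(np.argmin(row))]))
        d_pos = row[pos].min() if pos.any() else np.inf
        d_neg = row[~pos].min() if (~pos).any() else np.inf
        scores[i] = d_neg - d_pos
    return predicted, scores


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinalPatternDistribution:
    """Ordinal pattern counts pooled over channels."""

    embedding: int
    lag: int
    counts: dict[tuple[int, ...], int]
    source_channels: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _pattern_counts(channel: np.ndarray, d: int, lag: int) -> dict[tuple[int, ...], int]:
    n = channel.shape[0]
    span = (d - 1) * lag
    if n < span + 1:
        raise ValueError(f"length {n} < (d-1)*lag + 1 = {span + 1}")
    counts: dict[tuple[int, ...], int] = {}
    for start in range(n - span):
        window = channel[start : start + span + 1 : lag]
        # stable argsort: equal values ranked by order of occurrence
        pattern = tuple(int(i) for i in np.argsort(window, kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def ordinal_pattern_distribution(
    series: MultivariateSeries | np.ndarray, d: int = 3, lag: int = 1
) -> OrdinalPatternDistribution:
    """Pool ordinal-pattern counts over all channels of a series."""
    x = series.values if isinstance(series, MultivariateSeries) else np.asarray(series, float)
    if x.ndim == 1:
        x = x[:, None]
    pooled: dict[tuple[int, ...], int] = {}
    for j in range(x.shape[1]):
        for pat, c in _pattern_counts(x[:, j], d, lag).items():
            pooled[pat] = pooled.get(pat, 0) + c
    return OrdinalPatternDistribution(d, lag, pooled, x.shape[1])


def _entropy_of_counts(counts: dict[tuple[int, ...], int]) -> float:
    freqs = np.array(list(counts.values()), dtype=float)
    p = freqs / freqs.sum()
    return max(float(-(p * np.log(p)).sum()), 0.0)


def permutation_entropy(channel: np.ndarray, d: int = 3, lag: int = 1) -> float:
    """Shannon entropy (nats) of a channel's ordinal-pattern frequencies.

    Patterns are length-``d`` rank orderings of points ``lag`` apart;
    ties are ranked by order of occurrence.  Ranges over [0, log d!]:
    zero for a monotone series, log d! when all patterns are equally
    frequent.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 1:
        raise ValueError("permutation_entropy expects a single channel")
    return _entropy_of_counts(_pattern_counts(channel, d, lag))


def mmspe_features(
    series: MultivariateSeries,
    scales: tuple[int, ...] = (1, 2, 3, 4, 5),
    d: int = 3,
    lag: int = 1,
    aggregation: str = "pooled",
) -> np.ndarray:
    """Multivariate multiscale permutation entropy feature vector.

    For each integer scale the channels are block-averaged at that
    scale, ordinal patterns (embedding ``d``, lag ``lag``) are counted,
    and one entropy value per scale is returned.  ``aggregation``:
    ``"pooled"`` merges pattern counts across channels before the
    entropy; ``"mean"`` averages per-channel entropies instead.
    """
    out = []
    for s in scales:
        if int(s) != s or s < 1:
            raise ValueError(f"scales must be positive integers, got {s}")
        coarse = np.column_stack(
            [coarse_grain(series.values[:, j], float(int(s))) for j in range(series.m)]
        )
        if aggregation == "pooled":
            dist = ordinal_pattern_distribution(coarse, d, lag)
            out.append(_entropy_of_counts(dist.counts))
        elif aggregation == "mean":
            out.append(
                float(np.mean([permutation_entropy(coarse[:, j], d, lag) for j in range(coarse.shape[1])]))
            )
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return np.array(out)


def mmspe_matrix(collection: LabeledCollection, scales: tuple[int, ...] = (1, 2, 3, 4, 5),
                 d: int = 3, lag: int = 1):
    """MMSPE feature matrix for a collection, as a SignatureMatrix."""
    from .signatures import SignatureMatrix

    rows = [mmspe_features(inst, scales, d, lag) for inst in collection.instances]
    return SignatureMatrix(
        features=np.vstack(rows),
        column_names=tuple(f"mmspe_s{s}" for s in scales),
        labels=collection.labels,
        positive_label=collection.positive_label,
    )


def all_patterns(d: int) -> list[tuple[int, ...]]:
    """All d! ordinal patterns (helper for tests and diagnostics)."""
    return list(itertools.permutations(range(d)))
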