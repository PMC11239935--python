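"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the
correlation-magnitude matrix is assembled in exact rational arithmetic,
DTW is solved by exhaustive enumeration of monotone warping paths, and
permutation entropy by literal pattern counting.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def cstar_exact(window: np.ndarray) -> np.ndarray:
    """C* of a window via exact rational Gram sums.

    With d_ij = x_ij - mean_j (exact rationals), the entry is
    C*_jk = sum_i |d_ij||d_ik| / sqrt(sum_i d_ij^2 * sum_i d_ik^2);
    only the final square root leaves exact arithmetic.
    """
    n, m = window.shape
    cols = [[Fraction(x).limit_denominator(10**12) for x in window[:, j]] for j in range(m)]
    devs = []
    for col in cols:
        mu = sum(col, Fraction(0)) / n
        devs.append([abs(v - mu) for v in col])
    gram = [[sum(devs[j][i] * devs[k][i] for i in range(n)) for k in range(m)]
            for j in range(m)]
    out = np.empty((m, m))
    for j in range(m):
        for k in range(m):
            denom = math.sqrt(float(gram[j][j]) * float(gram[k][k]))
            out[j, k] = float(gram[j][k]) / denom if denom else (1.0 if j == k else 0.0)
    return out


def eigen_entropy_brute(cstar: np.ndarray) -> float:
    """EE from an eigen-decomposition, written independently."""
    m = cstar.shape[0]
    lams = np.linalg.eigvalsh(cstar)
    lams = np.where(np.abs(lams) < 1e-12, 0.0, lams)
    p = lams / m
    return float(-sum(pi * math.log(pi) for pi in p if pi > 0))


def ee_profile_brute(values: np.ndarray, window_ends) -> np.ndarray:
    """EE of each cumulative prefix via the exact C* oracle."""
    return np.array(
        [eigen_entropy_brute(cstar_exact(values[:end])) for end in window_ends]
    )


def dtw_enumerate(a: np.ndarray, b: np.ndarray) -> float:
    """DTWD by exhaustive enumeration of all monotone warping paths.

    Per-step cost is the squared Euclidean distance across channels;
    returns the square root of the minimal accumulated cost.  Only
    feasible for short series.
    """
    a = np.atleast_2d(a.T).T if a.ndim == 1 else a
    b = np.atleast_2d(b.T).T if b.ndim == 1 else b
    n, m = a.shape[0], b.shape[0]
    cost = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    best = [math.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


def permutation_entropy_brute(channel, d: int, lag: int) -> float:
    """PE by literal pattern counting with positional tie-breaks."""
    channel = list(channel)
    counts: dict[tuple, int] = {}
    span = (d - 1) * lag
    for start in range(len(channel) - span):
        window = channel[start : start + span + 1 : lag]
        order = sorted(range(d), key=lambda i: (window[i], i))
        key = tuple(order)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def auc_pairwise(labels: np.ndarray, scores: np.ndarray, positive) -> float:
    """AUC as the fraction of (positive, negative) pairs won, ties 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def all_monotone_patterns(d: int):
    return list(itertools.permutations(range(d)))
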