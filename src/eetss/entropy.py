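"""Eigen-entropy of a multivariate window.

Given an ``n x m`` window, each channel is standardized with the
population mean and standard deviation, the standardized deviations are
replaced by their absolute values, and the Gram matrix of the resulting
columns (divided by n) gives the correlation-magnitude matrix C*: a
symmetric positive semi-definite matrix with unit diagonal that treats
correlation and anti-correlation identically.  Eigen-entropy is the
Shannon entropy of the normalized eigenvalue spectrum p_i = lambda_i/m:

    EE = -sum_i p_i log p_i,   0 <= EE <= log m.

EE is maximal (log m) when all eigenvalues equal 1, i.e. the channels
are mutually uncorrelated in magnitude, and shrinks toward 0 as the
channels co-move: strong cross-channel correlation concentrates the
spectrum on one eigenvalue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_EIG_CLIP_TOL = 1e-10  # per unit of m; below -tol*m is a hard error


@dataclass(frozen=True)
class WindowStats:
    """Per-channel population mean and standard deviation (divisor n)."""

    means: np.ndarray
    stds: np.ndarray
    n: int


@dataclass(frozen=True)
class CorrelationMagnitudeMatrix:
    """C* (absolute-deviation Gram matrix) plus the signed correlation C.

    ``cstar`` is symmetric PSD with unit diagonal and non-negative
    off-diagonal entries; ``corr`` is the ordinary signed correlation
    matrix, kept as a diagnostic only.
    """

    cstar: np.ndarray
    corr: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.cstar.shape[0]


@dataclass(frozen=True)
class EigenSpectrum:
    """Descending eigenvalues of C*, their proportions p = lambda/m and EE."""

    lambdas: np.ndarray
    proportions: np.ndarray
    entropy: float


def window_stats(window: np.ndarray) -> WindowStats:
    """Population mean and standard deviation of each channel."""
    window = np.asarray(window, dtype=float)
    n, m = _check_window(window)
    return WindowStats(window.mean(axis=0), window.std(axis=0, ddof=0), n)


def correlation_magnitude(
    window: np.ndarray, with_signed: bool = True
) -> CorrelationMagnitudeMatrix:
    """Build the correlation-magnitude matrix C* of a window.

    Channels with zero variance inside the window are treated as
    uncorrelated with unit self-correlation (off-diagonal zeros,
    diagonal one) and logged — this preserves positive semi-definiteness
    and trace m.
    """
    window = np.asarray(window, dtype=float)
    n, m = _check_window(window)
    stats = window_stats(window)
    # relative test: an affinely shifted constant column can pick up an
    # O(eps)-level std and must still count as degenerate
    scale = np.abs(window).max(axis=0)
    degenerate = stats.stds <= 1e-12 * np.maximum(scale, 1e-300)
    if degenerate.any():
        logger.warning(
            "window of length %d: %d zero-variance channel(s) treated as "
            "uncorrelated", n, int(degenerate.sum()),
        )
    safe_std = np.where(degenerate, 1.0, stats.stds)
    dev = window - stats.means
    xs = dev / safe_std
    xs_abs = np.abs(xs)
    xs[:, degenerate] = 0.0
    xs_abs[:, degenerate] = 0.0
    cstar = xs_abs.T @ xs_abs / n
    corr = xs.T @ xs / n if with_signed else None
    np.fill_diagonal(cstar, 1.0)
    if corr is not None:
        np.fill_diagonal(corr, 1.0)
    cstar = (cstar + cstar.T) / 2.0
    return CorrelationMagnitudeMatrix(cstar, corr)


def eigen_entropy(
    cstar: CorrelationMagnitudeMatrix | np.ndarray, log_base: float | None = None
) -> EigenSpectrum:
    """Eigen-decompose C* and return its spectrum entropy.

    Eigenvalues in ``[-1e-10*m, 0)`` are clipped to zero (numerical
    noise on a PSD matrix); anything more negative raises, since it
    signals an upstream bug.  ``0 * log 0`` is taken as 0.  ``log_base``
    defaults to e (entropy in nats, maximum log m).
    """
    mat = cstar.cstar if isinstance(cstar, CorrelationMagnitudeMatrix) else np.asarray(cstar, float)
    m = mat.shape[0]
    if mat.shape != (m, m) or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("C* must be a symmetric square matrix")
    lambdas = np.linalg.eigvalsh(mat)[::-1].copy()
    tol = _EIG_CLIP_TOL * m
    if lambdas.min() < -tol:
        raise FloatingPointError(
            f"eigenvalue {lambdas.min():.3e} below -{tol:.1e}: matrix is not PSD"
        )
    lambdas = np.clip(lambdas, 0.0, None)
    p = lambdas / m
    nz = p > 0
    ee = float(-(p[nz] * np.log(p[nz])).sum())
    if log_base is not None:
        ee /= np.log(log_base)
    ee = max(ee, 0.0)
    return EigenSpectrum(lambdas, p, ee)


def window_eigen_entropy(
    window: np.ndarray, log_base: float | None = None
) -> EigenSpectrum:
    """Eigen-entropy of a raw window: C* construction then decomposition."""
    return eigen_entropy(correlation_magnitude(window, with_signed=False), log_base)


def _check_window(window: np.ndarray) -> tuple[int, int]:
    if window.ndim != 2:
        raise ValueError(f"window must be 2-D, got shape {window.shape}")
    n, m = window.shape
    if n < 2:
        raise ValueError(f"window needs >=2 time points, got {n}")
    if m < 2:
        raise ValueError(f"window needs >=2 channels, got {m}")
    return n, m
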