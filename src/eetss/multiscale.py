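"""Dense-multiscale coarse-graining of time series channels.

Classic multiscale analysis averages non-overlapping blocks of tau raw
points, restricting the scale factor tau to integers.  The dense
variant admits fractional tau on a grid of step alpha (tau = Q * alpha,
Q integer): the channel is first upsampled by zero insertion (1/alpha -
1 zeros between adjacent samples), low-pass filtered to interpolate the
zeros, and then block-averaged with segment length Q.  Integer tau is
computed directly on the raw channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import MultivariateSeries

logger = logging.getLogger(__name__)

#: minimum length of the upsampled series for stable zero-phase filtering
MIN_FILTER_LEN = 13
#: minimum coarse-grained length usable by the windowing stage
MIN_OUTPUT_LEN = 4


def _check_alpha(alpha: float) -> int:
    """Return the integer upsampling factor 1/alpha, or raise."""
    if alpha <= 0 or alpha > 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    up = 1.0 / alpha
    if abs(up - round(up)) > 1e-9:
        raise ValueError(f"1/alpha must be an integer, got alpha={alpha}")
    return int(round(up))


@dataclass(frozen=True)
class ScaleGrid:
    """The set of scale factors tau and their common step alpha.

    Every tau must be an integer multiple of alpha so the segment
    length Q = tau/alpha is a whole number.  The default grid is
    tau in {0.5, 1.0, ..., 5.0} with alpha = 0.5.
    """

    taus: tuple[float, ...] = tuple(np.arange(1, 11) * 0.5)
    alpha: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "taus", tuple(float(t) for t in self.taus))
        _check_alpha(self.alpha)
        for tau in self.taus:
            if tau <= 0:
                raise ValueError(f"scale factor must be positive, got {tau}")
            q = tau / self.alpha
            if abs(q - round(q)) > 1e-9:
                raise ValueError(
                    f"tau={tau} is not an integer multiple of alpha={self.alpha}"
                )

    @classmethod
    def from_string(cls, spec: str, alpha: float | None = None) -> "ScaleGrid":
        """Parse a ``start:stop:step`` grid string, e.g. ``"0.5:5:0.5"``."""
        start, stop, step = (float(tok) for tok in spec.split(":"))
        n = int(round((stop - start) / step)) + 1
        taus = tuple(start + i * step for i in range(n))
        return cls(taus=taus, alpha=step if alpha is None else alpha)


@dataclass(frozen=True)
class UpsampledSeries:
    """A zero-inserted (and possibly filtered) channel.

    ``values`` has length ``(N - 1)/alpha + 1`` for an original length
    ``N``; before filtering the original samples sit at positions
    ``(i - 1)/alpha + 1`` (1-based) and all other entries are zero.
    """

    values: np.ndarray
    original_length: int
    alpha: float


def upsample_zero_insert(channel: np.ndarray, alpha: float) -> UpsampledSeries:
    """Insert ``1/alpha - 1`` zeros between adjacent samples.

    The output keeps the original samples at stride ``1/alpha`` and has
    exact length ``(N - 1)/alpha + 1``; ``alpha = 1`` is the identity.
    """
    up = _check_alpha(alpha)
    channel = np.asarray(channel, dtype=float)
    n = channel.shape[0]
    if n < 2:
        raise ValueError(f"channel length {n} < 2")
    out = np.zeros((n - 1) * up + 1, dtype=float)
    out[::up] = channel
    return UpsampledSeries(out, original_length=n, alpha=alpha)


def butterworth_lowpass(
    upsampled: UpsampledSeries,
    order: int = 4,
    cutoff_fraction: float | None = None,
    gain: float | None = None,
) -> np.ndarray:
    """Interpolate a zero-inserted series with a Butterworth low-pass.

    The filter is order-``order`` (default 4) with normalized cutoff
    ``cutoff_fraction`` of the Nyquist frequency — by default ``alpha``,
    the anti-imaging cutoff matching the upsampling factor.  It is
    applied forward-backward (zero phase) and the output is multiplied
    by ``gain`` (default ``1/alpha``) to compensate the amplitude lost
    to zero insertion.
    """
    x = np.asarray(upsampled.values, dtype=float)
    if x.shape[0] < MIN_FILTER_LEN:
        raise ValueError(
            f"upsampled length {x.shape[0]} < {MIN_FILTER_LEN}: too short for "
            "stable zero-phase filtering; skip non-integer scales for this series"
        )
    if cutoff_fraction is None:
        cutoff_fraction = upsampled.alpha
    if gain is None:
        gain = 1.0 / upsampled.alpha
    sos = signal.butter(order, cutoff_fraction, btype="low", output="sos")
    padlen = min(3 * (2 * sos.shape[0]), x.shape[0] - 1)
    return gain * signal.sosfiltfilt(sos, x, padlen=padlen)


def coarse_grain(
    channel: np.ndarray,
    tau: float,
    alpha: float = 0.5,
    butter_order: int = 4,
    butter_cutoff_fraction: float | None = None,
) -> np.ndarray:
    """Coarse-grain one channel at scale factor ``tau``.

    Integer ``tau``: average non-overlapping blocks of ``tau`` raw
    points (length ``floor(N/tau)``); ``tau = 1`` returns the channel
    unchanged.  Non-integer ``tau``: zero-insert upsample by ``1/alpha``,
    low-pass filter, then average segments of length ``Q = tau/alpha``
    (length ``floor(L/Q)`` with ``L = (N-1)/alpha + 1``).

    Outputs shorter than the windowing minimum are allowed here; the
    minimum-length rule is enforced by :func:`multiscale_transform`,
    which drops such scales.
    """
    channel = np.asarray(channel, dtype=float)
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    q = tau / alpha
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"tau={tau} not an integer multiple of alpha={alpha}")
    if abs(tau - round(tau)) < 1e-9:
        itau = int(round(tau))
        if itau == 1:
            out = channel
        else:
            nblocks = channel.shape[0] // itau
            if nblocks == 0:
                raise ValueError(f"length {channel.shape[0]} < tau {itau}")
            out = channel[: nblocks * itau].reshape(nblocks, itau).mean(axis=1)
    else:
        qi = int(round(q))
        # remove the channel mean before zero insertion and restore it after
        # filtering: the DC offset would otherwise become an edge-rippled
        # filter response, and fractional scales would lose exact shift
        # equivariance
        mu = channel.mean()
        filtered = mu + butterworth_lowpass(
            upsample_zero_insert(channel - mu, alpha),
            order=butter_order,
            cutoff_fraction=butter_cutoff_fraction,
        )
        nblocks = filtered.shape[0] // qi
        out = filtered[: nblocks * qi].reshape(nblocks, qi).mean(axis=1)
    return out


def multiscale_transform(
    series: MultivariateSeries,
    grid: ScaleGrid | None = None,
    butter_order: int = 4,
    butter_cutoff_fraction: float | None = None,
) -> dict[float, MultivariateSeries]:
    """Coarse-grain every channel of a series at each grid scale.

    Returns a mapping tau -> coarse-grained series.  Scales whose output
    would be shorter than the windowing minimum (or whose upsampled
    input is too short to filter) are omitted with a warning; if no
    scale survives, a ``ValueError`` is raised.
    """
    if grid is None:
        grid = ScaleGrid()
    out: dict[float, MultivariateSeries] = {}
    for tau in grid.taus:
        try:
            channels = [
                coarse_grain(
                    series.values[:, j],
                    tau,
                    grid.alpha,
                    butter_order=butter_order,
                    butter_cutoff_fraction=butter_cutoff_fraction,
                )
                for j in range(series.m)
            ]
        except ValueError as exc:
            logger.warning(
                "instance %s: omitting tau=%g (%s)", series.instance_id, tau, exc
            )
            continue
        if channels[0].shape[0] < MIN_OUTPUT_LEN:
            logger.warning(
                "instance %s: omitting tau=%g (coarse-grained length %d < %d)",
                series.instance_id, tau, channels[0].shape[0], MIN_OUTPUT_LEN,
            )
            continue
        out[tau] = MultivariateSeries(
            np.column_stack(channels), series.channel_names, series.instance_id
        )
    if not out:
        raise ValueError(
            f"instance {series.instance_id!r}: every scale factor omitted "
            f"(series length {series.n} too short)"
        )
    return out
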