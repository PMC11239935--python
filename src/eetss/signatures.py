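"""Cumulative-moving-window eigen-entropy profiles and TSS features.

For a coarse-grained series of length N, a cumulative moving window
(CMW) schedule is the nested sequence of prefixes of lengths
SS, 2*SS, ..., N, where the sample size SS = max(2, floor(N/50)) yields
roughly fifty windows per series.  The eigen-entropy of each prefix
forms the EE profile; the change relative to the first window (CHEE)
divided by the window index k gives the time series signature
TSS_k = (EE_k - EE_first)/k, the features handed to classifiers.
Signatures are computed at every scale factor of a grid and
concatenated in grid order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .entropy import window_eigen_entropy
from .io import LabeledCollection, MultivariateSeries
from .multiscale import ScaleGrid, multiscale_transform

logger = logging.getLogger(__name__)

#: CMW count target: SS is the series length divided by this, floored
WINDOWS_PER_SERIES = 50


@dataclass(frozen=True)
class CMWSchedule:
    """Sample size SS and the increasing list of window end indices.

    ``window_ends`` are 1-based prefix lengths: SS, 2*SS, ... and, when
    SS does not divide N, a final window of size N so the schedule spans
    the whole series.
    """

    ss: int
    window_ends: tuple[int, ...]

    @property
    def k(self) -> int:
        """Number of cumulative windows."""
        return len(self.window_ends)


def window_schedule(n: int) -> CMWSchedule:
    """Build the CMW schedule for a series of length ``n``.

    ``SS = max(2, floor(n / 50))`` — for short series (n < 100) the
    window grows by 2 points per step; otherwise roughly fifty windows
    cover the series.  ``n`` below 4 is rejected (no meaningful
    schedule).
    """
    if n < 4:
        raise ValueError(f"series length {n} < 4: too short for windowing")
    ss = max(2, n // WINDOWS_PER_SERIES)
    ends = list(range(ss, (n // ss) * ss + 1, ss))
    if ends[-1] != n:
        ends.append(n)
    return CMWSchedule(ss=ss, window_ends=tuple(ends))


def ee_profile(series: MultivariateSeries, schedule: CMWSchedule | None = None) -> np.ndarray:
    """Eigen-entropy of each cumulative window of a series.

    Element ``k`` (0-based) is the EE of rows ``0 .. window_ends[k]``.
    """
    if schedule is None:
        schedule = window_schedule(series.n)
    if schedule.window_ends[-1] != series.n:
        raise ValueError(
            f"schedule spans {schedule.window_ends[-1]} points but series has {series.n}"
        )
    return np.array(
        [window_eigen_entropy(series.values[:end]).entropy for end in schedule.window_ends]
    )


def tss_from_profile(profile: np.ndarray) -> np.ndarray:
    """Convert an EE profile to TSS features.

    ``TSS_k = (EE_k - EE_first) / k`` for windows k = 2..K (1-based);
    the trivially-zero TSS_1 is not emitted.
    """
    profile = np.asarray(profile, dtype=float)
    k = profile.shape[0]
    if k < 2:
        raise ValueError(f"profile length {k} < 2")
    ks = np.arange(2, k + 1, dtype=float)
    return (profile[1:] - profile[0]) / ks


@dataclass(frozen=True)
class SignatureMatrix:
    """Instances-by-features TSS matrix with aligned labels.

    Columns are named ``tau{t}_k{k}``: the TSS of window ``k`` at scale
    factor ``t``, concatenated over the scale grid in grid order.
    """

    features: np.ndarray
    column_names: tuple[str, ...]
    labels: tuple[str, ...]
    positive_label: str

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", f)
        if f.ndim != 2:
            raise ValueError(f"features must be 2-D, got {f.shape}")
        if f.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")
        if f.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def _format_tau(tau: float) -> str:
    return f"{tau:g}"


def signature_vector(
    series: MultivariateSeries, grid: ScaleGrid | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """TSS features of one instance across all grid scales.

    SS is recomputed from each coarse-grained length, so every scale
    contributes a comparable number of windows.
    """
    if grid is None:
        grid = ScaleGrid()
    per_scale = multiscale_transform(series, grid)
    feats: list[float] = []
    names: list[str] = []
    for tau in grid.taus:
        if tau not in per_scale:
            continue
        coarse = per_scale[tau]
        schedule = window_schedule(coarse.n)
        tss = tss_from_profile(ee_profile(coarse, schedule))
        feats.extend(tss.tolist())
        names.extend(
            f"tau{_format_tau(tau)}_k{k}" for k in range(2, schedule.k + 1)
        )
    return np.array(feats), tuple(names)


def extract_signatures(
    collection: LabeledCollection, grid: ScaleGrid | None = None
) -> SignatureMatrix:
    """TSS signature matrix of a collection (instances x features).

    The collection must be padded to equal length beforehand so every
    instance yields the identical column schema; a schema mismatch is
    reported as an internal error since it signals an upstream length
    bug.
    """
    if grid is None:
        grid = ScaleGrid()
    lengths = {inst.n for inst in collection.instances}
    if len(lengths) > 1:
        raise ValueError(
            f"unequal instance lengths {sorted(lengths)}: pad the collection first"
        )
    rows = []
    schema: tuple[str, ...] | None = None
    for inst in collection.instances:
        vec, names = signature_vector(inst, grid)
        if schema is None:
            schema = names
            for tau in grid.taus:
                count = sum(1 for c in names if c.startswith(f"tau{_format_tau(tau)}_"))
                logger.info("tau=%g: %d signature features", tau, count)
        elif names != schema:
            raise RuntimeError(
                f"instance {inst.instance_id!r} produced a different feature schema "
                "(upstream length bug)"
            )
        rows.append(vec)
    return SignatureMatrix(
        features=np.vstack(rows),
        column_names=schema,
        labels=collection.labels,
        positive_label=collection.positive_label,
    )
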