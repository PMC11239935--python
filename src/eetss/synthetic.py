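"""Seeded generators of correlated Gaussian collections.

The premise being tested is that classes differ in how their channels
co-move over time.  The generator emits two-class collections of
zero-mean Gaussian channels with equicorrelated covariance: the control
class keeps a constant inter-channel correlation ``rho_base`` for the
whole series, while the case class switches to ``rho_shift`` at a
changepoint.  A null variant makes the classes distributionally
identical for calibration checks.

Seeding: one master seed spawns one child stream per instance, so
enlarging a collection never perturbs the instances already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabeledCollection, MultivariateSeries


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the correlation-shift generator.

    Defaults mirror a strong-effect two-class design: 40 instances per
    class, 400 time points, 4 channels, equicorrelation drifting from
    0.1 to 0.8 at the series midpoint, no added observation noise.
    """

    n_instances: int = 40
    n: int = 400
    m: int = 4
    rho_base: float = 0.1
    rho_shift: float = 0.8
    changepoint_fraction: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.rho_base, self.rho_shift):
            # equicorrelation matrix is PD iff -1/(m-1) < rho < 1
            if not (-1.0 / (self.m - 1) < rho < 1.0):
                raise ValueError(
                    f"rho={rho} gives a non-positive-definite {self.m}-channel "
                    f"equicorrelation matrix (need -1/(m-1) < rho < 1)"
                )
        if not (0.0 < self.changepoint_fraction < 1.0):
            raise ValueError("changepoint_fraction must be in (0, 1)")
        if self.n < 4 or self.m < 2 or self.n_instances < 1:
            raise ValueError("need n >= 4, m >= 2, n_instances >= 1")


def _equicorr_cholesky(m: int, rho: float) -> np.ndarray:
    c = np.full((m, m), rho)
    np.fill_diagonal(c, 1.0)
    return np.linalg.cholesky(c)


def _draw_instance(
    rng: np.random.Generator, cfg: GeneratorConfig, shifted: bool
) -> np.ndarray:
    z = rng.standard_normal((cfg.n, cfg.m))
    cut = int(round(cfg.changepoint_fraction * cfg.n))
    l_base = _equicorr_cholesky(cfg.m, cfg.rho_base)
    x = z @ l_base.T
    if shifted:
        l_shift = _equicorr_cholesky(cfg.m, cfg.rho_shift)
        x[cut:] = z[cut:] @ l_shift.T
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal((cfg.n, cfg.m))
    return x


def gen_correlation_shift(config: GeneratorConfig | None = None) -> LabeledCollection:
    """Two-class collection: stationary correlation vs a mid-series shift.

    Class ``"0"``: equicorrelation ``rho_base`` throughout.  Class
    ``"1"`` (positive): ``rho_base`` until the changepoint, then
    ``rho_shift``.  Fixed seed gives bit-identical output.
    """
    cfg = config or GeneratorConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(2 * cfg.n_instances)
    instances, labels = [], []
    for i in range(cfg.n_instances):
        rng = np.random.default_rng(streams[i])
        instances.append(MultivariateSeries(_draw_instance(rng, cfg, False),
                                            instance_id=f"ctl{i}"))
        labels.append("0")
    for i in range(cfg.n_instances):
        rng = np.random.default_rng(streams[cfg.n_instances + i])
        instances.append(MultivariateSeries(_draw_instance(rng, cfg, True),
                                            instance_id=f"shift{i}"))
        labels.append("1")
    return LabeledCollection(tuple(instances), tuple(labels), positive_label="1")


def gen_null(config: GeneratorConfig | None = None) -> LabeledCollection:
    """Calibration collection with no class signal.

    Both classes are drawn with ``rho_shift = rho_base``; the balanced
    labels are then shuffled (seeded), so any detected separation is a
    protocol artefact.
    """
    cfg = config or GeneratorConfig()
    base = GeneratorConfig(
        n_instances=cfg.n_instances, n=cfg.n, m=cfg.m,
        rho_base=cfg.rho_base, rho_shift=cfg.rho_base,
        changepoint_fraction=cfg.changepoint_fraction,
        noise_sd=cfg.noise_sd, seed=cfg.seed,
    )
    coll = gen_correlation_shift(base)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E756C6C]))
    labels = np.array(coll.labels)
    rng.shuffle(labels)
    return LabeledCollection(coll.instances, tuple(labels), coll.positive_label)


#: fixed 20 x 4 integer micro-fixture used throughout the unit tests;
#: values chosen once, small and varied enough that no window is degenerate
_MICRO = np.array([
    [3, 7, 2, 9],
    [5, 1, 8, 4],
    [2, 6, 3, 7],
    [8, 2, 5, 1],
    [4, 9, 1, 6],
    [7, 3, 6, 2],
    [1, 5, 9, 8],
    [6, 8, 4, 3],
    [9, 4, 7, 5],
    [2, 7, 1, 9],
    [5, 2, 8, 4],
    [3, 9, 2, 6],
    [8, 1, 6, 2],
    [4, 6, 9, 7],
    [7, 4, 3, 1],
    [1, 8, 5, 9],
    [6, 3, 7, 4],
    [9, 5, 2, 8],
    [2, 9, 6, 3],
    [5, 1, 4, 7],
], dtype=float)


def fixture_micro() -> MultivariateSeries:
    """The fixed 20-point, 4-channel integer fixture (deterministic)."""
    return MultivariateSeries(_MICRO.copy(), instance_id="micro")
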