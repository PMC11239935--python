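import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eetss import (
    correlation_magnitude,
    eigen_entropy,
    window_eigen_entropy,
    window_stats,
)
from oracles import cstar_exact, eigen_entropy_brute


def ee_2x2_closed_form(c: float) -> float:
    """EE of a 2x2 C* with off-diagonal c: eigenvalues are 1 +/- c."""
    terms = 0.0
    for lam in (1 + c, 1 - c):
        p = lam / 2.0
        if p > 0:
            terms -= p * math.log(p)
    return terms


class TestWindowStats:
    def test_population_divisor(self):
        stats = window_stats(np.array([[1.0, 1], [3.0, 2], [2.0, 3], [4.0, 4]]))
        np.testing.assert_allclose(stats.means, [2.5, 2.5])
        np.testing.assert_allclose(stats.stds[1], math.sqrt(1.25))

    def test_two_point_column(self):
        stats = window_stats(np.array([[1.0, 0.0], [3.0, 0.0]]))
        assert stats.means[0] == 2.0 and stats.stds[0] == 1.0

    def test_constant_column_has_zero_std(self):
        stats = window_stats(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert stats.stds[0] == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            window_stats(np.ones((1, 2)))


class TestCorrelationMagnitude:
    def test_affine_dependence_gives_unit_magnitude(self):
        x1 = np.array([1.0, 2, 5, 3, 8])
        window = np.column_stack([x1, 2 * x1 + 3])
        cm = correlation_magnitude(window)
        assert cm.cstar[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation_same_magnitude(self):
        x1 = np.array([1.0, 2, 5, 3, 8])
        cm = correlation_magnitude(np.column_stack([x1, -x1]))
        assert cm.cstar[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cm.corr[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_small_window_against_exact_oracle(self):
        window = np.array([[1.0, 1], [2, 3], [3, 2], [4, 4]])
        np.testing.assert_allclose(
            correlation_magnitude(window).cstar, cstar_exact(window), atol=1e-12
        )

    def test_zero_variance_channel_treated_as_uncorrelated(self):
        window = np.array([[5.0, 1, 2], [5.0, 3, 1], [5.0, 2, 4]])
        cm = correlation_magnitude(window)
        assert cm.cstar[0, 0] == 1.0
        np.testing.assert_array_equal(cm.cstar[0, 1:], [0.0, 0.0])
        assert np.trace(cm.cstar) == pytest.approx(3.0)
        assert np.linalg.eigvalsh(cm.cstar).min() > -1e-10

    @settings(deadline=None, max_examples=30)
    @given(window=hnp.arrays(np.float64, st.tuples(st.integers(3, 12), st.integers(2, 5)),
                             elements=st.floats(-100, 100)))
    def test_psd_unit_diagonal_and_trace(self, window):
        cm = correlation_magnitude(window)
        m = cm.m
        np.testing.assert_allclose(np.diag(cm.cstar), np.ones(m))
        np.testing.assert_allclose(cm.cstar, cm.cstar.T)
        assert np.linalg.eigvalsh(cm.cstar).min() > -1e-8 * m


class TestEigenEntropy:
    def test_identity_attains_maximum(self):
        spec = eigen_entropy(np.eye(3))
        assert spec.entropy == pytest.approx(math.log(3), abs=1e-10)

    def test_all_ones_gives_zero(self):
        for m in (2, 4, 6):
            spec = eigen_entropy(np.ones((m, m)))
            assert spec.entropy == pytest.approx(0.0, abs=1e-10)
            assert spec.lambdas[0] == pytest.approx(m)

    def test_2x2_half_correlation(self):
        spec = eigen_entropy(np.array([[1.0, 0.5], [0.5, 1.0]]))
        np.testing.assert_allclose(sorted(spec.lambdas), [0.5, 1.5])
        assert spec.entropy == pytest.approx(
            -(0.75 * math.log(0.75) + 0.25 * math.log(0.25)), abs=1e-12
        )

    def test_eigenvalue_and_proportion_sums(self):
        rng = np.random.default_rng(5)
        cm = correlation_magnitude(rng.standard_normal((60, 5)))
        spec = eigen_entropy(cm)
        assert spec.lambdas.sum() == pytest.approx(5.0, abs=1e-8)
        assert spec.proportions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_significantly_negative_eigenvalue_rejected(self):
        not_psd = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(FloatingPointError, match="not PSD"):
            eigen_entropy(not_psd)

    def test_log_base_rescaling(self):
        nats = eigen_entropy(np.eye(4)).entropy
        bits = eigen_entropy(np.eye(4), log_base=2).entropy
        assert bits == pytest.approx(nats / math.log(2), abs=1e-12)


class TestWindowEigenEntropy:
    def test_two_point_window_is_always_zero(self):
        # with n=2 every standardized absolute column is (1, 1), so C* is
        # the all-ones matrix regardless of the data
        rng = np.random.default_rng(6)
        for _ in range(5):
            window = rng.standard_normal((2, 4))
            assert window_eigen_entropy(window).entropy == pytest.approx(0.0, abs=1e-12)

    def test_independent_channels_converge_to_analytic_limit(self):
        # for independent Gaussians the off-diagonals of C* converge to
        # E|z_j| E|z_k| = 2/pi, not 0, so the limit entropy is that of the
        # 2/pi-equicorrelated matrix
        m = 3
        rng = np.random.default_rng(7)
        ee = window_eigen_entropy(rng.standard_normal((100_000, m))).entropy
        c = 2 / math.pi
        limit = np.full((m, m), c)
        np.fill_diagonal(limit, 1.0)
        assert ee == pytest.approx(eigen_entropy_brute(limit), abs=0.02)

    def test_micro_window_matches_exact_oracle(self):
        window = np.array([[1.0, 1], [2, 3], [3, 2], [4, 4]])
        expected = eigen_entropy_brute(cstar_exact(window))
        assert window_eigen_entropy(window).entropy == pytest.approx(expected, abs=1e-12)

    def test_entropy_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(3, 40))
            m = int(rng.integers(2, 6))
            ee = window_eigen_entropy(rng.standard_normal((n, m))).entropy
            assert 0.0 <= ee <= math.log(m) + 1e-12

    @settings(deadline=None, max_examples=20)
    @given(
        # two-decimal values keep in-window spreads well above the
        # cancellation scale of the affine shift
        window=hnp.arrays(np.float64, st.tuples(st.integers(4, 10), st.integers(2, 4)),
                          elements=st.floats(-20, 20).map(lambda v: round(v, 2))),
        seed=st.integers(0, 100),
    )
    def test_permutation_and_affine_invariance(self, window, seed):
        rng = np.random.default_rng(seed)
        base = window_eigen_entropy(window).entropy
        perm = rng.permutation(window.shape[1])
        assert window_eigen_entropy(window[:, perm]).entropy == pytest.approx(base, abs=1e-9)
        a = rng.uniform(0.5, 2.0, window.shape[1]) * rng.choice([-1, 1], window.shape[1])
        b = rng.uniform(-5, 5, window.shape[1])
        assert window_eigen_entropy(window * a + b).entropy == pytest.approx(base, abs=1e-9)

    def test_monotone_decreasing_in_correlation(self):
        # stronger co-movement concentrates the spectrum: EE falls as |rho| rises
        rng = np.random.default_rng(9)
        entropies = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            window = rng.standard_normal((10_000, 2)) @ np.linalg.cholesky(cov).T
            entropies.append(window_eigen_entropy(window).entropy)
        assert all(a > b for a, b in zip(entropies, entropies[1:]))

    def test_2x2_closed_form_matches_pipeline(self):
        rng = np.random.default_rng(10)
        window = rng.standard_normal((500, 2)) @ np.linalg.cholesky(
            np.array([[1.0, 0.7], [0.7, 1.0]])
        ).T
        realized_c = correlation_magnitude(window).cstar[0, 1]
        assert window_eigen_entropy(window).entropy == pytest.approx(
            ee_2x2_closed_form(realized_c), abs=1e-6
        )
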