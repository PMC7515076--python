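"""Delay embedding, recurrence quantification and dynamical invariants."""

import math

import numpy as np
import pytest

from hippogamma.nonlinear import (
    EmbeddingSpec,
    correlation_dimension,
    embed,
    false_nearest_neighbors,
    max_lyapunov,
    max_lyapunov_jacobian,
    radius_for_rate,
    recurrence_matrix,
    rqa_measures,
    select_delay,
    series_entropy,
)
from hippogamma.surrogates import gen_map_series


@pytest.fixture(scope="module")
def logistic():
    return gen_map_series("logistic", 5000, seed=11)


@pytest.fixture(scope="module")
def sine():
    return gen_map_series("sine", 3000, seed=11)


class TestSelectDelay:
    def test_sine_quarter_period(self, sine):
        delay = select_delay(sine.series)
        assert 3 <= delay <= 7  # about a quarter period

    def test_white_noise_short_delay(self, rng):
        x = rng.normal(size=3000)
        assert select_delay(x) <= 3

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_delay(np.ones(500))


class TestFNN:
    def test_logistic_low_dimensional(self, logistic):
        dim, saturated = false_nearest_neighbors(logistic.series, delay=1)
        assert not saturated
        assert dim <= 3

    def test_sine_low_dimensional(self, sine, rng):
        # a pinch of observational noise regularises the noise-free curve
        x = sine.series + rng.normal(0, 0.005, sine.series.size)
        dim, saturated = false_nearest_neighbors(x, delay=5)
        assert not saturated
        assert dim <= 3

    def test_noise_saturates(self, rng):
        x = rng.normal(size=1500)
        dim, saturated = false_nearest_neighbors(x, delay=1, max_dim=5)
        assert saturated and dim == 5


class TestRecurrence:
    def test_diagonal_and_symmetry(self, rng):
        x = rng.normal(size=300)
        spec = EmbeddingSpec(1, 2, theiler_window=0)
        m = recurrence_matrix(x, spec, radius=0.5)
        assert (np.diag(m) == 1).all()
        np.testing.assert_array_equal(m, m.T)

    def test_huge_radius_all_ones(self, rng):
        x = rng.normal(size=200)
        spec = EmbeddingSpec(1, 2, theiler_window=0)
        m = recurrence_matrix(x, spec, radius=1e9)
        assert m.all()

    def test_theiler_band_zeroed(self, rng):
        x = rng.normal(size=200)
        spec = EmbeddingSpec(1, 2, theiler_window=3)
        m = recurrence_matrix(x, spec, radius=1e9)
        ii, jj = np.indices(m.shape)
        assert not m[np.abs(ii - jj) <= 3].any()
        assert m[np.abs(ii - jj) > 3].all()

    def test_radius_for_rate_hits_target(self, rng):
        x = rng.normal(size=500)
        spec = EmbeddingSpec(1, 3)
        r = radius_for_rate(x, spec, 0.02)
        m = recurrence_matrix(x, spec, r)
        ii, jj = np.indices(m.shape)
        off = np.abs(ii - jj) > spec.theiler
        assert m[off].mean() == pytest.approx(0.02, abs=0.005)


class TestRQA:
    def test_single_line_length_zero_entropy(self):
        """A plot whose diagonal lines all share one length has zero entropy."""
        n = 60
        m = np.zeros((n, n), dtype=np.uint8)
        for off in (7, 14, 21):
            for i in range(0, n - off - 5, 10):
                m[i:i + 5, i + off:i + off + 5] |= np.eye(5, dtype=np.uint8)
        m |= m.T
        res = rqa_measures(m, theiler=0)
        assert res.entropy_bits == pytest.approx(0.0)
        assert res.l_max == 5
        assert res.determinism == pytest.approx(1.0)

    def test_uniform_length_histogram_max_entropy(self):
        """k equally common line lengths give entropy log2(k)."""
        n = 80
        m = np.zeros((n, n), dtype=np.uint8)
        row = 0
        lengths = (2, 3, 4, 5)
        for off, ln in zip((20, 30, 40, 50), lengths):
            m[row:row + ln, row + off:row + off + ln] |= np.eye(ln, dtype=np.uint8)
            row += ln + 2
        m |= m.T
        res = rqa_measures(m, theiler=0)
        assert res.entropy_bits == pytest.approx(np.log2(len(lengths)))

    def test_periodic_series_fully_deterministic(self, sine):
        spec = EmbeddingSpec(5, 2, theiler_window=10)
        m = recurrence_matrix(sine.series[:400], spec, radius=0.1)
        res = rqa_measures(m, theiler=10)
        assert res.determinism > 0.9
        assert res.l_max > 100

    def test_matches_brute_force_line_histogram(self, rng):
        n = 60
        m = (rng.random((n, n)) < 0.2).astype(np.uint8)
        m = np.triu(m) | np.triu(m).T  # symmetric
        res = rqa_measures(m, min_line=2, theiler=0)
        # oracle: explicit diagonal walk
        lengths = []
        for off in range(1, n):
            run = 0
            for i in range(n - off):
                if m[i, i + off]:
                    run += 1
                else:
                    if run:
                        lengths.append(run)
                    run = 0
            if run:
                lengths.append(run)
        long = [l for l in lengths if l >= 2]
        n_rec = int(m[np.abs(np.subtract.outer(range(n), range(n))) > 0].sum())
        assert res.l_max == max(long)
        assert res.determinism == pytest.approx(
            min(1.0, 2 * sum(long) / n_rec)
        )
        counts = np.bincount(long)[2:]
        p = counts[counts > 0] / counts.sum()
        assert res.entropy_bits == pytest.approx(float(-(p * np.log2(p)).sum()))

    def test_no_recurrences_flagged(self):
        m = np.eye(50, dtype=np.uint8)
        res = rqa_measures(m, theiler=0)
        assert "no-recurrences" in res.flags or res.recurrence_rate < 0.05


class TestLyapunov:
    def test_logistic_matches_jacobian_ground_truth(self, logistic):
        est = max_lyapunov(logistic.series, EmbeddingSpec(1, 2))
        assert est == pytest.approx(logistic.lyapunov_true, rel=0.10)

    def test_sine_non_positive(self, sine):
        est = max_lyapunov(sine.series, EmbeddingSpec(5, 2))
        assert est <= 0.01

    def test_jacobian_estimator_orders_stability(self, logistic, rng):
        """Chaotic maps sit clearly above noisy periodic observables."""
        chaotic = max_lyapunov_jacobian(logistic.series, EmbeddingSpec(1, 2))
        assert chaotic > 0.2
        from scipy.ndimage import gaussian_filter1d

        x = np.sin(2 * np.pi * np.arange(3000) / 19.7)
        x = x + gaussian_filter1d(rng.normal(0, 0.3, 3000), 2.0)
        stable = max_lyapunov_jacobian(x, EmbeddingSpec(5, 3))
        assert stable < chaotic - 0.2

    def test_deterministic(self, logistic):
        spec = EmbeddingSpec(1, 2)
        assert max_lyapunov(logistic.series, spec) == max_lyapunov(
            logistic.series, spec
        )


class TestCorrelationDimension:
    def test_uniform_noise_fills_embedding(self, rng):
        x = rng.uniform(size=4000)
        d2 = correlation_dimension(x, EmbeddingSpec(1, 3, theiler_window=1))
        assert d2 == pytest.approx(3.0, rel=0.15)

    def test_periodic_orbit_is_one_dimensional(self, sine, rng):
        x = sine.series + rng.normal(0, 0.005, sine.series.size)
        d2 = correlation_dimension(x, EmbeddingSpec(5, 3))
        assert d2 == pytest.approx(1.0, abs=0.3)

    def test_constant_series(self):
        assert correlation_dimension(np.zeros(2000), EmbeddingSpec(1, 3)) == 0.0


class TestInvariances:
    def test_affine_rescaling(self, rng):
        """Entropy and D2 unchanged when series and radius rescale together."""
        x = rng.normal(size=800)
        spec = EmbeddingSpec(2, 3, theiler_window=6)
        r = radius_for_rate(x, spec, 0.05)
        res_a = rqa_measures(recurrence_matrix(x, spec, r), theiler=6)
        y = 4.0 * x - 7.0
        res_b = rqa_measures(recurrence_matrix(y, spec, 4.0 * r), theiler=6)
        # borderline pairs may flip under floating-point rescaling
        assert res_a.entropy_bits == pytest.approx(res_b.entropy_bits, abs=0.1)
        assert res_a.determinism == pytest.approx(res_b.determinism, abs=0.02)
        d2_a = correlation_dimension(x, spec)
        d2_b = correlation_dimension(y, spec)
        assert d2_a == pytest.approx(d2_b, rel=0.05)


def test_series_entropy_uniform_bins():
    x = np.repeat(np.arange(32), 10).astype(float)
    assert series_entropy(x, bins=32) == pytest.approx(5.0)
    assert series_entropy(np.zeros(100)) == 0.0


def test_embed_shapes_and_errors():
    x = np.arange(10.0)
    e = embed(x, delay=2, dimension=3)
    assert e.shape == (6, 3)
    np.testing.assert_array_equal(e[0], [0, 2, 4])
    with pytest.raises(ValueError):
        embed(x, delay=5, dimension=4)
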