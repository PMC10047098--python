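"""The ten-measure feature bank and z-score normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apneawst.features import (FEATURE_NAMES, ZScoreStats, attention_entropy,
                               approximate_entropy,
                               cumulative_residual_entropy, feature_matrix,
                               feature_row, moment_features,
                               probability_entropy, sample_entropy,
                               shannon_entropy, spectral_entropy,
                               zscore_fit_transform)

# ---------------------------------------------------------------------------
# brute-force oracles (naive, loop-based; shared with the acceptance suite)
# ---------------------------------------------------------------------------

def apen_oracle(u, m, r):
    n = len(u)

    def phi(mm):
        t = [u[i:i + mm] for i in range(n - mm + 1)]
        return np.mean([np.log(sum(1 for b in t if np.max(np.abs(a - b)) <= r)
                               / (n - mm + 1)) for a in t])

    return phi(m) - phi(m + 1)


def sampen_oracle(u, m, r):
    n = len(u)
    tm = [u[i:i + m] for i in range(n - m)]
    tm1 = [u[i:i + m + 1] for i in range(n - m)]
    B = sum(1 for i, a in enumerate(tm) for j, b in enumerate(tm)
            if i != j and np.max(np.abs(a - b)) <= r)
    A = sum(1 for i, a in enumerate(tm1) for j, b in enumerate(tm1)
            if i != j and np.max(np.abs(a - b)) <= r)
    if B == 0:
        return float("nan")
    if A == 0:
        return float("inf")
    return -np.log(A / B)


def atten_oracle(x):
    keys = [i for i in range(1, len(x) - 1)
            if (x[i] > x[i - 1] and x[i] > x[i + 1])
            or (x[i] < x[i - 1] and x[i] < x[i + 1])]
    if len(keys) < 2:
        return 0.0
    intervals = [keys[k + 1] - keys[k] for k in range(len(keys) - 1)]
    counts = {}
    for iv in intervals:
        counts[iv] = counts.get(iv, 0) + 1
    p = np.array(list(counts.values())) / len(intervals)
    return float(-(p * np.log(p)).sum())


def cre_oracle(x):
    n = len(x)
    total = 0.0
    for xi in x:
        p = sum(1 for xj in x if xj > xi) / n
        if p > 0:
            total -= p * np.log(p)
    return total


class TestMoments:
    def test_constant_series(self):
        mu, std, skew, kurt = moment_features(np.ones(4))
        assert (mu, std) == (1.0, 0.0)
        assert np.isnan(skew) and np.isnan(kurt)

    def test_hand_example(self):
        mu, std, skew, kurt = moment_features(np.array([0.0, 0, 0, 1]))
        assert mu == pytest.approx(0.25)
        assert std == pytest.approx(np.sqrt(3) / 4)
        assert skew == pytest.approx(1.1547, abs=1e-4)
        assert kurt == pytest.approx(2.3333, abs=1e-4)

    def test_gaussian_limits(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        _, _, skew, kurt = moment_features(x)
        assert abs(skew) < 0.1
        assert abs(kurt - 3.0) < 0.1  # non-excess form


class TestShannon:
    def test_single_bin_zero(self):
        assert shannon_entropy(np.full(50, 2.5)) == 0.0

    def test_uniform_four_bins(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 10)
        assert shannon_entropy(x, n_bins=4) == pytest.approx(np.log(4))

    def test_half_quarter_quarter(self):
        x = np.array([0.0] * 2 + [1.0] + [2.0])
        assert shannon_entropy(x, n_bins=3) == pytest.approx(1.0397, abs=1e-4)

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.arange(4.0), n_bins=1)


class TestApEn:
    def test_constant_zero(self):
        assert approximate_entropy(np.full(30, 1.0)) == 0.0

    def test_alternating_matches_oracle(self):
        u = np.array([1.0, -1.0] * 15)
        r = 0.25 * u.std()
        assert approximate_entropy(u, m=2, r=r) == pytest.approx(
            apen_oracle(u, 2, r), abs=1e-12)

    def test_noise_more_irregular_than_sine(self, rng):
        t = np.arange(300) / 100.0
        sine = np.sin(2 * np.pi * 1.0 * t)
        noise = rng.standard_normal(300)
        noise *= sine.std() / noise.std()
        assert approximate_entropy(noise) > approximate_entropy(sine)

    def test_scale_invariance_with_relative_r(self, rng):
        u = rng.standard_normal(120)
        assert approximate_entropy(3.7 * u) == pytest.approx(
            approximate_entropy(u), abs=1e-12)


class TestSampEn:
    def test_constant_zero(self):
        assert sample_entropy(np.full(30, 2.0), r=0.0) == 0.0

    def test_periodic_matches_oracle(self):
        u = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3])
        assert sample_entropy(u, m=2, r=0.5) == pytest.approx(
            sampen_oracle(u, 2, 0.5), abs=1e-12)

    def test_ramp_infinite_flag(self):
        u = np.arange(30.0)
        assert np.isinf(sample_entropy(u, m=2, r=0.1))

    def test_scale_invariance_with_relative_r(self, rng):
        u = rng.standard_normal(120)
        assert sample_entropy(0.2 * u) == pytest.approx(sample_entropy(u),
                                                        abs=1e-12)


class TestSpectral:
    def test_pure_tone_concentrated(self):
        t = np.arange(1000) / 100.0  # 10 Hz lands on an exact FFT bin
        assert spectral_entropy(np.sin(2 * np.pi * 10 * t)) <= 0.2

    def test_white_noise_flat(self):
        x = np.random.default_rng(3).standard_normal(4096)
        assert spectral_entropy(x) >= 0.9

    def test_two_tone_closed_form(self):
        n = 1000  # both tones on exact FFT bins: a 2-atom spectrum
        t = np.arange(n) / 100.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t)
        n_freqs = n // 2 + 1
        expected = -(0.5 * np.log(0.5) * 2) / np.log(n_freqs)
        assert spectral_entropy(x) == pytest.approx(expected, abs=1e-3)

    def test_zero_signal(self):
        assert spectral_entropy(np.zeros(16)) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_unit_interval(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert 0.0 <= spectral_entropy(x) <= 1.0


class TestAttention:
    def test_monotone_zero(self):
        assert attention_entropy(np.arange(20.0)) == 0.0

    def test_alternating_degenerate_zero(self):
        assert attention_entropy(np.array([1.0, -1.0] * 10)) == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(100)
            assert attention_entropy(x) == pytest.approx(atten_oracle(x),
                                                         abs=1e-12)

    def test_pair_type_variant_runs(self, rng):
        x = rng.standard_normal(200)
        assert attention_entropy(x, pair_types=True) >= 0.0


class TestCre:
    def test_constant_zero(self):
        assert cumulative_residual_entropy(np.full(10, 3.3)) == 0.0

    def test_two_point_closed_form(self):
        assert cumulative_residual_entropy(np.array([0.0, 1.0])) == (
            pytest.approx(-0.5 * np.log(0.5), abs=1e-12))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_nonnegative(self, seed):
        x = np.random.default_rng(seed).standard_normal(30)
        assert cumulative_residual_entropy(x) >= 0.0

    def test_matches_oracle(self, rng):
        x = rng.standard_normal(80)
        assert cumulative_residual_entropy(x) == pytest.approx(cre_oracle(x),
                                                               abs=1e-12)


class TestFeatureRow:
    def test_zero_row(self):
        v = feature_row(np.zeros(20))
        named = dict(zip(FEATURE_NAMES, v))
        assert named["mean"] == 0.0 and named["std"] == 0.0
        for key in ("shannon", "apen", "sampen", "spen", "atten", "cre"):
            assert named[key] == 0.0
        assert np.isnan(named["skewness"]) and np.isnan(named["kurtosis"])

    def test_shift_equivariance(self, rng):
        x = rng.standard_normal(64)
        a = dict(zip(FEATURE_NAMES, feature_row(x)))
        b = dict(zip(FEATURE_NAMES, feature_row(x + 10.0)))
        assert b["mean"] == pytest.approx(a["mean"] + 10.0)
        for key in ("std", "skewness", "kurtosis"):
            assert b[key] == pytest.approx(a[key], abs=1e-9)

    def test_composition_matches_component_oracles(self, rng):
        x = rng.standard_normal(64)
        v = dict(zip(FEATURE_NAMES, feature_row(x)))
        r = 0.25 * x.std()
        mu, std, skew, kurt = moment_features(x)
        assert v["mean"] == mu and v["std"] == std
        assert v["apen"] == pytest.approx(apen_oracle(x, 2, r), abs=1e-12)
        assert v["sampen"] == pytest.approx(sampen_oracle(x, 2, r), abs=1e-12)
        assert v["atten"] == pytest.approx(atten_oracle(x), abs=1e-12)
        assert v["cre"] == pytest.approx(cre_oracle(x), abs=1e-12)
        assert v["shannon"] == pytest.approx(shannon_entropy(x), abs=1e-12)
        assert v["spen"] == pytest.approx(spectral_entropy(x), abs=1e-12)

    def test_too_short_row_rejected(self):
        with pytest.raises(ValueError):
            feature_row(np.arange(5.0))

    def test_feature_matrix_shape_and_names(self, rng):
        X = rng.standard_normal((7, 32))
        table = feature_matrix(X)
        assert list(table.columns) == FEATURE_NAMES
        assert len(table) == 7


class TestZScore:
    def test_column_example(self):
        Z, _ = zscore_fit_transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_transformed_moments(self, rng):
        X = rng.standard_normal((50, 4)) * 5 + 2
        Z, _ = zscore_fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_inverse_round_trip(self, rng):
        X = rng.standard_normal((20, 3))
        Z, stats = zscore_fit_transform(X)
        np.testing.assert_allclose(stats.inverse(Z), X, atol=1e-12)

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            ZScoreStats().transform(np.zeros((2, 2)))

    def test_zero_variance_column_passthrough(self, rng, caplog):
        X = np.column_stack([rng.standard_normal(10), np.full(10, 7.0)])
        with caplog.at_level("WARNING"):
            Z, _ = zscore_fit_transform(X)
        assert "zero-variance" in caplog.text
        np.testing.assert_allclose(Z[:, 1], 0.0)
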