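"""Ten statistical and entropy measures per scattering window, plus z-scoring.

Each row of the flattened scattering matrix (one 10-s time window, one value
per scattering path) is summarized by: mean, standard deviation, skewness,
kurtosis (all population, 1/N, forms; kurtosis non-excess so a Gaussian
scores 3), Shannon entropy of a histogram, approximate entropy, sample
entropy, spectral entropy, attention entropy and cumulative residual
entropy. Natural logarithms throughout. Measures that are undefined on a
degenerate input (zero variance, no extrema, no template matches) come back
as the documented degenerate value or as ``nan``/``inf`` flags — never a
silently clipped number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_NAMES = ["mean", "std", "skewness", "kurtosis", "shannon",
                 "apen", "sampen", "spen", "atten", "cre"]

DEFAULT_BINS = 32
DEFAULT_M = 2           # embedding dimension for ApEn / SampEn
DEFAULT_R_FACTOR = 0.25  # tolerance r = 0.25 * STD of the series


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def moment_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, std, skewness and non-excess kurtosis.

    Skewness and kurtosis are ``nan`` for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d ** 2)
    std = float(np.sqrt(m2))
    if m2 == 0:
        return float(mu), 0.0, float("nan"), float("nan")
    skew = float(np.mean(d ** 3) / m2 ** 1.5)
    kurt = float(np.mean(d ** 4) / m2 ** 2)
    return float(mu), std, skew, kurt


# ---------------------------------------------------------------------------
# Entropies
# ---------------------------------------------------------------------------

def shannon_entropy(x: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Shannon entropy (nats) of an equal-width histogram of ``x``."""
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(x, bins=n_bins)
    return probability_entropy(counts / counts.sum())


def probability_entropy(p: np.ndarray) -> float:
    """-sum p log p with 0 log 0 = 0, in nats."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _cheb_distance_matrices(u: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev distance matrices between all templates of lengths ``m``
    and ``m+1``.

    Built incrementally from the scalar distance matrix via running maxima
    along diagonals: ``d_{k+1}[i, j] = max(d_k[i, j], |u[i+k] - u[j+k]|)``,
    so both matrices come from one O(N^2) pass instead of two O(N^2 m)
    broadcasts.
    """
    pair = np.abs(u[:, None] - u[None, :])
    d = pair
    for k in range(1, m + 1):
        d = np.maximum(d[:-1, :-1], pair[k:, k:])
        if k == m - 1:
            d_m = d
    if m == 1:
        d_m = pair
    return d_m, d


def _apen_sampen(u: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """Shared-distance computation of (ApEn, SampEn)."""
    n = len(u)
    d_m, d_m1 = _cheb_distance_matrices(u, m)
    match_m = d_m <= r
    match_m1 = d_m1 <= r
    # ApEn: self-matches included, N-m+1 (resp. N-m) templates
    c_m = match_m.sum(axis=1) / (n - m + 1)
    c_m1 = match_m1.sum(axis=1) / (n - m)
    apen = float(np.log(c_m).mean() - np.log(c_m1).mean())
    # SampEn: self-matches excluded, both counts over the first N-m templates
    n_t = n - m
    B = int(match_m[:n_t, :n_t].sum()) - n_t
    A = int(match_m1.sum()) - n_t
    if A == 0:  # covers B == 0 too, since A <= B
        sampen = float("inf")
    else:
        sampen = float(-np.log(A / B))
    return apen, sampen


def approximate_entropy(u: np.ndarray, m: int = DEFAULT_M,
                        r: float | None = None) -> float:
    """Approximate entropy with self-matches included.

    ``C_i^m(r)`` is the fraction (out of ``N-m+1`` templates) of templates
    within Chebyshev distance ``r`` of template ``i``; ``Phi^m`` is the mean
    of ``ln C_i^m`` and ``ApEn = Phi^m - Phi^{m+1}``. The tolerance defaults
    to ``0.25 * STD(u)``, which makes the measure scale-invariant. A constant
    series (r = 0) is defined to have ApEn 0.
    """
    u = np.asarray(u, dtype=float)
    if len(u) < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples")
    if r is None:
        r = DEFAULT_R_FACTOR * u.std()
    if r <= 0:
        if np.ptp(u) == 0:
            return 0.0
        raise ValueError("tolerance r must be positive")
    return _apen_sampen(u, m, r)[0]


def sample_entropy(u: np.ndarray, m: int = DEFAULT_M,
                   r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with self-matches excluded.

    ``B`` counts ordered template pairs (i != j) matching at length ``m``,
    ``A`` at length ``m+1``, both over the first ``N-m`` templates so the
    two counts are comparable. No match at ``m+1`` yields ``inf`` (flagged,
    not capped). A constant series has A == B and SampEn 0.
    """
    u = np.asarray(u, dtype=float)
    if len(u) < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples")
    if r is None:
        r = DEFAULT_R_FACTOR * u.std()
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    return _apen_sampen(u, m, r)[1]


def spectral_entropy(x: np.ndarray) -> float:
    """Shannon entropy of the normalized periodogram, scaled to [0, 1].

    Power is taken from the one-sided FFT periodogram (all rfft bins);
    a zero signal is defined to have spectral entropy 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    p = np.abs(np.fft.rfft(x)) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    return probability_entropy(p / total) / np.log(len(p))


def _key_point_indices(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima and minima (interior points only)."""
    left, mid, right = x[:-2], x[1:-1], x[2:]
    is_max = (mid > left) & (mid > right)
    is_min = (mid < left) & (mid < right)
    return np.nonzero(is_max | is_min)[0] + 1


def attention_entropy(x: np.ndarray, pair_types: bool = False) -> float:
    """Shannon entropy of the intervals between successive local extrema.

    Key points are the strict local maxima and minima of the series; the
    sample-index gaps between successive key points form a count
    distribution whose Shannon entropy (nats) is returned. Fewer than two
    key points (e.g. a monotone series) gives 0.

    With ``pair_types=True`` the intervals are split into the four
    max/min transition streams and the four entropies averaged (the
    variant of the measure's original formulation).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    keys = _key_point_indices(x)
    if len(keys) < 2:
        return 0.0
    if not pair_types:
        intervals = np.diff(keys)
        _, counts = np.unique(intervals, return_counts=True)
        return probability_entropy(counts / counts.sum())

    left, mid, right = x[:-2], x[1:-1], x[2:]
    kinds = np.where((mid > left) & (mid > right), 1, 0)[keys - 1]  # 1=max
    ents = []
    for a in (0, 1):
        for b in (0, 1):
            sel = (kinds[:-1] == a) & (kinds[1:] == b)
            iv = np.diff(keys)[sel]
            if iv.size == 0:
                ents.append(0.0)
            else:
                _, counts = np.unique(iv, return_counts=True)
                ents.append(probability_entropy(counts / counts.sum()))
    return float(np.mean(ents))


def cumulative_residual_entropy(x: np.ndarray) -> float:
    """-sum p(X > x_i) log p(X > x_i) over the sample points, in nats.

    The survival probabilities are empirical; terms with p = 0 contribute
    nothing, so a constant sample scores 0. Always nonnegative.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least 1 sample")
    exceed = (x[None, :] > x[:, None]).sum(axis=1)  # count of X > x_i
    p = exceed / len(x)
    return probability_entropy(p) if np.any(p > 0) else 0.0


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def feature_row(row: np.ndarray, n_bins: int = DEFAULT_BINS,
                m: int = DEFAULT_M,
                r_factor: float = DEFAULT_R_FACTOR) -> np.ndarray:
    """All ten features of one scattering window row, in FEATURE_NAMES order."""
    row = np.asarray(row, dtype=float)
    if len(row) < 8:
        raise ValueError("feature extraction needs at least 8 coefficients")
    mu, std, skew, kurt = moment_features(row)
    r = r_factor * row.std()
    if r > 0:
        apen, sampen = _apen_sampen(row, m, r)
    else:
        apen, sampen = 0.0, 0.0  # constant row: defined regular
    return np.array([
        mu, std, skew, kurt,
        shannon_entropy(row, n_bins=n_bins),
        apen, sampen,
        spectral_entropy(row),
        attention_entropy(row),
        cumulative_residual_entropy(row),
    ])


def feature_matrix(X: np.ndarray, meta: pd.DataFrame | None = None,
                   **kwargs) -> pd.DataFrame:
    """Feature table for a flattened scattering matrix (one row per window).

    Provenance columns from ``meta`` (record, minute, window, label) are
    prepended when given.
    """
    rows = np.vstack([feature_row(r, **kwargs) for r in np.asarray(X, float)])
    feats = pd.DataFrame(rows, columns=FEATURE_NAMES)
    if meta is not None:
        feats = pd.concat([meta.reset_index(drop=True), feats], axis=1)
    return feats


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class ZScoreStats:
    """Per-column mean and population standard deviation fitted on training
    rows, reusable on held-out rows; invertible exactly."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, X: np.ndarray) -> "ZScoreStats":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit z-score statistics")
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)  # population (1/N)
        zero = self.std == 0
        if np.any(zero):
            logger.warning("%d zero-variance columns passed through unscaled",
                           int(zero.sum()))
            self.std = np.where(zero, 1.0, self.std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("z-score statistics not fitted")
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("z-score statistics not fitted")
        return np.asarray(Z, dtype=float) * self.std + self.mean


def zscore_fit_transform(X: np.ndarray) -> tuple[np.ndarray, ZScoreStats]:
    stats = ZScoreStats().fit(X)
    return stats.transform(X), stats
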