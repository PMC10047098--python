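"""Order-2 wavelet scattering transform for 60-s ECG segments.

The transform cascades analytic Morlet (Gabor-with-admissibility-correction)
band-pass filters, a modulus nonlinearity and a Gaussian low-pass ``phi``
whose time support is the invariance scale ``T``:

    S_0 f = f * phi
    S_1 f = |f * psi_{j1}| * phi
    S_2 f = ||f * psi_{j1}| * psi_{j2}| * phi

First-order wavelets are spaced at Q1 per octave (default 8), second order
at Q2 per octave (default 1); only frequency-decreasing paths
(center(psi_{j2}) < center(psi_{j1})) are kept. Every filter bank is
rescaled so that its Littlewood–Paley sum

    |phi^|^2 + sum_j |psi_j^|^2 <= 1

on the FFT grid, which makes each layer — and hence the whole transform —
non-expansive: the total scattering energy never exceeds the input energy.

Convolutions are circular via FFT; with the default ``boundary="periodic"``
a circular shift of the input rotates every intermediate signal exactly,
which is what makes the windowed coefficients stable to sub-``T``
translations. ``boundary="reflect"`` mirror-pads to twice the length first
and crops the central part, trading exact shift covariance for suppressed
wrap-around at the edges.

The averaged outputs are summarized into ``n_windows`` block means per
segment (default 6, i.e. a 10-s hop for 60-s epochs) — an oversampled
output grid, since at ``T = 60 s`` the critically sampled grid would hold a
single frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_T = 60.0
DEFAULT_Q1 = 8
DEFAULT_Q2 = 1
DEFAULT_N_WINDOWS = 6
#: highest wavelet center frequency as a fraction of fs
DEFAULT_F_MAX_FRACTION = 0.4
#: phi bandwidth in Hz is _SIGMA_PHI_FACTOR / T  (time support ~ T)
_SIGMA_PHI_FACTOR = 0.13


@dataclass(frozen=True)
class ScatteringPath:
    """Identifier of one scattering coefficient row."""

    order: int
    indices: tuple[int, ...]        # wavelet indices (j1[, j2[, j3]])
    center_freqs: tuple[float, ...]  # Hz, one per cascade level

    def __post_init__(self) -> None:
        if self.order != len(self.indices):
            raise ValueError("order must equal the number of wavelet indices")


def _geometric_centers(f_max: float, f_min: float, Q: int) -> np.ndarray:
    """Center frequencies from f_max down to f_min at Q per octave."""
    rho = 2.0 ** (1.0 / Q)
    n = int(np.floor(np.log(f_max / f_min) / np.log(rho))) + 1
    return f_max / rho ** np.arange(n)


@dataclass
class ScatteringFilterBank:
    """Morlet filter banks for a fixed sampling rate and segment length."""

    fs: float
    T: float
    Q1: int
    Q2: int
    signal_len: int
    f_max: float
    f_min: float
    centers1: np.ndarray
    sigmas1: np.ndarray
    centers2: np.ndarray
    sigmas2: np.ndarray
    sigma_phi: float
    scale1: float = 1.0
    scale2: float = 1.0
    _cache: dict = field(default_factory=dict, repr=False)

    def filters(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(phi_hat, psi1_hat, psi2_hat) sampled on the length-``n`` FFT grid."""
        if n not in self._cache:
            freqs = np.fft.fftfreq(n, d=1.0 / self.fs)
            phi = np.exp(-(freqs ** 2) / (2 * self.sigma_phi ** 2))
            p1 = _morlet_filters(freqs, self.centers1, self.sigmas1) * self.scale1
            p2 = _morlet_filters(freqs, self.centers2, self.sigmas2) * self.scale2
            self._cache[n] = (phi, p1, p2)
        return self._cache[n]

    def littlewood_paley(self, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Frame sums |phi^|^2 + sum |psi^|^2 for each bank on the grid."""
        phi, p1, p2 = self.filters(n or self.signal_len)
        return (phi ** 2 + (p1 ** 2).sum(axis=0),
                phi ** 2 + (p2 ** 2).sum(axis=0))


def _morlet_filters(freqs: np.ndarray, centers: np.ndarray,
                    sigmas: np.ndarray) -> np.ndarray:
    """Analytic Morlet wavelets in frequency: Gaussian bump at the center
    minus a zero-frequency correction so every wavelet has exactly zero mean."""
    out = np.empty((len(centers), len(freqs)))
    g0 = None
    for i, (c, s) in enumerate(zip(centers, sigmas)):
        g = np.exp(-((freqs - c) ** 2) / (2 * s ** 2))
        g0 = np.exp(-(freqs ** 2) / (2 * s ** 2))
        beta = np.exp(-(c ** 2) / (2 * s ** 2))
        out[i] = g - beta * g0
    return out


def build_filter_bank(fs: float = 100.0, T: float = DEFAULT_T,
                      Q1: int = DEFAULT_Q1, Q2: int = DEFAULT_Q2,
                      signal_len: int = 6000,
                      f_max: float | None = None,
                      f_min: float | None = None) -> ScatteringFilterBank:
    """Construct the two Morlet banks and the Gaussian low-pass.

    Wavelet centers run geometrically from ``f_max`` (default ``0.4 fs``)
    down to ``f_min`` (default ``1/T``); bandwidths are set so adjacent
    filters of a bank cross at half power, giving an effective quality
    factor of Q. Each bank is rescaled once so its Littlewood–Paley sum
    stays below 1.
    """
    if Q1 < 1 or Q2 < 1:
        raise ValueError("Q1 and Q2 must be >= 1")
    if T * fs > signal_len:
        raise ValueError(f"invariance scale T={T}s needs at least "
                         f"{T * fs:.0f} samples, got {signal_len}")
    f_max = DEFAULT_F_MAX_FRACTION * fs if f_max is None else f_max
    f_min = 1.0 / T if f_min is None else f_min
    if not 0 < f_min < f_max <= fs / 2:
        raise ValueError("need 0 < f_min < f_max <= fs/2")

    def _sigmas(centers: np.ndarray, Q: int) -> np.ndarray:
        rho = 2.0 ** (1.0 / Q)
        return centers * (np.sqrt(rho) - 1.0) / np.sqrt(np.log(2.0))

    c1 = _geometric_centers(f_max, f_min, Q1)
    c2 = _geometric_centers(f_max, f_min, Q2)
    bank = ScatteringFilterBank(
        fs=fs, T=T, Q1=Q1, Q2=Q2, signal_len=signal_len,
        f_max=f_max, f_min=f_min,
        centers1=c1, sigmas1=_sigmas(c1, Q1),
        centers2=c2, sigmas2=_sigmas(c2, Q2),
        sigma_phi=_SIGMA_PHI_FACTOR / T,
    )
    lp1, lp2 = bank.littlewood_paley(signal_len)
    bank.scale1 = 1.0 / np.sqrt(max(lp1.max(), 1.0))
    bank.scale2 = 1.0 / np.sqrt(max(lp2.max(), 1.0))
    bank._cache.clear()
    return bank


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

@dataclass
class ScatteringCoefficients:
    """Path-by-window coefficient matrix for one segment."""

    values: np.ndarray                  # [n_paths, n_windows], >= 0 up to fp error
    paths: list[ScatteringPath]
    window_hop: float                   # seconds between window centers
    parent_id: str = ""
    minute_index: int = -1
    label: str = "unlabeled"


def _scatter_full(x: np.ndarray, bank: ScatteringFilterBank, max_order: int,
                  boundary: str) -> tuple[list[ScatteringPath], np.ndarray]:
    """Full-resolution averaged coefficients S_p for every path.

    Returns the paths (order 0 first, then order 1 in decreasing frequency,
    then orders 2 and 3 lexicographically) and an ``[n_paths, len(x)]``
    matrix of phi-averaged outputs.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != bank.signal_len:
        raise ValueError(f"segment length {len(x)} != bank.signal_len "
                         f"{bank.signal_len}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains NaN or infinite samples")
    if max_order not in (0, 1, 2, 3):
        raise ValueError("max_order must be 0..3")
    if boundary not in ("periodic", "reflect"):
        raise ValueError(f"unknown boundary mode {boundary!r}")

    n0 = len(x)
    if boundary == "reflect":
        pad = n0 // 2
        x = np.pad(x, pad, mode="reflect")
        crop = slice(pad, pad + n0)
    else:
        crop = slice(0, n0)
    n = len(x)
    phi, p1, p2 = bank.filters(n)

    def lowpass(U: np.ndarray) -> np.ndarray:
        return np.fft.ifft(np.fft.fft(U, axis=-1) * phi, axis=-1).real

    paths: list[ScatteringPath] = [ScatteringPath(0, (), ())]
    rows: list[np.ndarray] = []

    X = np.fft.fft(x)
    rows.append(np.fft.ifft(X * phi).real[crop][None, :])

    if max_order >= 1:
        U1 = np.abs(np.fft.ifft(X[None, :] * p1, axis=-1))
        rows.append(lowpass(U1)[:, crop])
        paths.extend(ScatteringPath(1, (j,), (bank.centers1[j],))
                     for j in range(len(bank.centers1)))

    if max_order >= 2:
        U1f = np.fft.fft(U1, axis=-1)
        U2_list, meta2 = [], []
        for j1, fc1 in enumerate(bank.centers1):
            sel = np.nonzero(bank.centers2 < fc1)[0]
            if sel.size == 0:
                continue
            U2 = np.abs(np.fft.ifft(U1f[j1][None, :] * p2[sel], axis=-1))
            U2_list.append(U2)
            meta2.extend((j1, int(j2)) for j2 in sel)
        if U2_list:
            U2_all = np.vstack(U2_list)
            rows.append(lowpass(U2_all)[:, crop])
            paths.extend(
                ScatteringPath(2, (j1, j2),
                               (bank.centers1[j1], bank.centers2[j2]))
                for j1, j2 in meta2)

    if max_order >= 3 and U2_list:
        U2f = np.fft.fft(U2_all, axis=-1)
        U3_list, meta3 = [], []
        for idx, (j1, j2) in enumerate(meta2):
            sel = np.nonzero(bank.centers2 < bank.centers2[j2])[0]
            if sel.size == 0:
                continue
            U3 = np.abs(np.fft.ifft(U2f[idx][None, :] * p2[sel], axis=-1))
            U3_list.append(U3)
            meta3.extend((j1, j2, int(j3)) for j3 in sel)
        if U3_list:
            rows.append(lowpass(np.vstack(U3_list))[:, crop])
            paths.extend(
                ScatteringPath(3, (j1, j2, j3),
                               (bank.centers1[j1], bank.centers2[j2],
                                bank.centers2[j3]))
                for j1, j2, j3 in meta3)

    return paths, np.vstack(rows)


def scattering_transform(x: np.ndarray, bank: ScatteringFilterBank,
                         max_order: int = 2,
                         n_windows: int = DEFAULT_N_WINDOWS,
                         boundary: str = "periodic") -> ScatteringCoefficients:
    """Scattering coefficients of one segment, summarized per time window.

    The full-resolution averaged outputs are reduced to ``n_windows`` block
    means over equal contiguous blocks of the segment.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    paths, S = _scatter_full(x, bank, max_order, boundary)
    blocks = np.array_split(S, n_windows, axis=1)
    values = np.column_stack([b.mean(axis=1) for b in blocks])
    hop = bank.signal_len / bank.fs / n_windows
    return ScatteringCoefficients(values=values, paths=paths, window_hop=hop)


def scatter_segments(segments, bank: ScatteringFilterBank,
                     max_order: int = 2, n_windows: int = DEFAULT_N_WINDOWS,
                     boundary: str = "periodic") -> list[ScatteringCoefficients]:
    """Transform a list of :class:`~apneawst.preprocess.Segment` objects,
    carrying segment provenance onto the coefficients."""
    out = []
    for seg in segments:
        c = scattering_transform(seg.samples, bank, max_order=max_order,
                                 n_windows=n_windows, boundary=boundary)
        c.parent_id = seg.parent_id
        c.minute_index = seg.minute_index
        c.label = seg.label
        out.append(c)
    return out


def order_energies(x: np.ndarray, bank: ScatteringFilterBank,
                   max_order: int = 3,
                   boundary: str = "periodic") -> dict[int, float]:
    """Energy ``sum S_p^2`` of the full-resolution coefficients per order."""
    paths, S = _scatter_full(x, bank, max_order, boundary)
    energies = {m: 0.0 for m in range(max_order + 1)}
    sq = (S ** 2).sum(axis=1)
    for p, e in zip(paths, sq):
        energies[p.order] += float(e)
    return energies


def order_energy_ratio(segments: list[np.ndarray],
                       bank: ScatteringFilterBank,
                       boundary: str = "periodic") -> float:
    """Mean percentage of order-0..3 scattering energy held by orders 0..2."""
    ratios = []
    for x in segments:
        e = order_energies(x, bank, max_order=3, boundary=boundary)
        total = e[0] + e[1] + e[2] + e[3]
        ratios.append(100.0 * (e[0] + e[1] + e[2]) / total)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Tensor flattening
# ---------------------------------------------------------------------------

def flatten_windows(coeffs: list[ScatteringCoefficients]):
    """Stack many segments' coefficients into a window-per-row design matrix.

    Returns ``(X, meta)`` where ``X`` has ``n_segments * n_windows`` rows and
    ``n_paths`` columns, and ``meta`` is a DataFrame with one row per window
    (parent record, minute, window index, inherited label).
    """
    import pandas as pd

    if not coeffs:
        raise ValueError("no coefficient sets to flatten")
    ref = coeffs[0].paths
    for c in coeffs[1:]:
        if c.paths != ref:
            raise ValueError("heterogeneous scattering path sets cannot be "
                             "flattened together")
    X = np.vstack([c.values.T for c in coeffs])
    meta = pd.DataFrame({
        "record": np.repeat([c.parent_id for c in coeffs],
                            [c.values.shape[1] for c in coeffs]),
        "minute": np.repeat([c.minute_index for c in coeffs],
                            [c.values.shape[1] for c in coeffs]),
        "window": np.concatenate([np.arange(c.values.shape[1]) for c in coeffs]),
        "label": np.repeat([c.label for c in coeffs],
                           [c.values.shape[1] for c in coeffs]),
    })
    return X, meta


def unflatten_windows(X: np.ndarray, n_windows: int) -> list[np.ndarray]:
    """Inverse of :func:`flatten_windows` on the value matrix alone."""
    if X.shape[0] % n_windows:
        raise ValueError("row count is not a multiple of n_windows")
    return [X[i:i + n_windows].T for i in range(0, X.shape[0], n_windows)]
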