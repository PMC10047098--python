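"""Segmentation, band-pass filtering and autocorrelation-based quality weights.

A recording is cut into 60-s epochs, band-pass filtered (3–45 Hz FIR) and
each epoch receives a quality weight: the per-epoch autocorrelation
function (ACF) is compared to every other epoch of the same recording with
a centered cosine similarity

    w_st = (X_s - mean(X_s)) . (X_t - mean(X_t))
           / (||X_s - mean(X_s)|| ||X_t - mean(X_t)||),

algebraically the Pearson correlation of the two ACF vectors. A segment's
weight is its mean similarity to the other segments; segments whose weight
falls below a threshold ``lambda`` (default 0.8) are dropped as noisy.
Weights are computed per recording — artifacts disrupt the quasi-periodic
ACF signature shared by clean epochs of one patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin
from statsmodels.tsa.stattools import acf as _sm_acf

from .io import LABEL_UNLABELED, EcgRecord

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.8
DEFAULT_N_LAGS = 500  # 5 s at 100 Hz: several RR intervals
DEFAULT_LOW_HZ = 3.0
DEFAULT_HIGH_HZ = 45.0
DEFAULT_TAPS = 101


class DegenerateSegmentError(ValueError):
    """A segment with zero variance or non-finite values."""


@dataclass
class Segment:
    """One 60-s ECG window with its minute label and (optional) weight."""

    parent_id: str
    minute_index: int
    samples: np.ndarray
    label: str = LABEL_UNLABELED
    weight: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.weight is not None and not -1.0 <= self.weight <= 1.0 + 1e-12:
            raise ValueError(f"weight {self.weight} outside [-1, 1]")


@dataclass
class SegmentWeights:
    """Pairwise ACF similarities and the per-segment quality weights."""

    similarity: np.ndarray          # symmetric, unit diagonal
    weights: np.ndarray             # mean similarity per segment (NaN if degenerate)
    lambda_threshold: float
    dropped: list[int] = field(default_factory=list)
    degenerate: list[int] = field(default_factory=list)


def segment_record(record: EcgRecord) -> list[Segment]:
    """Split a record into whole-minute segments; a trailing partial minute
    is discarded. Each segment inherits the label of its minute."""
    spm = int(round(60 * record.fs))
    n_seg = len(record.samples) // spm
    if n_seg == 0:
        logger.warning("record %s shorter than one minute, no segments",
                       record.record_id)
        return []
    leftover = len(record.samples) - n_seg * spm
    if leftover:
        logger.info("record %s: dropping %d trailing samples",
                    record.record_id, leftover)
    segments = []
    for m in range(n_seg):
        label = record.labels[m] if record.labels else LABEL_UNLABELED
        segments.append(Segment(parent_id=record.record_id, minute_index=m,
                                samples=record.samples[m * spm:(m + 1) * spm],
                                label=label))
    return segments


def design_bandpass(fs: float, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    taps: int = DEFAULT_TAPS) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass (Hamming window)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(f"cutoffs ({low_hz}, {high_hz}) must satisfy "
                         f"0 < low < high < fs/2 = {fs / 2}")
    if taps % 2 == 0:
        raise ValueError("taps must be odd for integer group delay")
    h = firwin(taps, [low_hz, high_hz], fs=fs, pass_zero=False,
               window="hamming")
    return h - h.mean()  # exact DC null (window leaves ~-55 dB otherwise)


def bandpass_filter(x: np.ndarray, fs: float, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    taps: int = DEFAULT_TAPS) -> np.ndarray:
    """Apply the FIR band-pass with zero net phase and no length change.

    The filter is linear-phase; reflecting ``taps//2`` samples at each edge
    and keeping the 'valid' part of the convolution compensates the group
    delay exactly.
    """
    h = design_bandpass(fs, low_hz, high_hz, taps)
    half = len(h) // 2
    xe = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    return np.convolve(xe, h, mode="valid")


def bandpass_segment(segment: Segment, fs: float, **kwargs) -> Segment:
    """Band-pass filter one segment, preserving its metadata."""
    return Segment(parent_id=segment.parent_id,
                   minute_index=segment.minute_index,
                   samples=bandpass_filter(segment.samples, fs, **kwargs),
                   label=segment.label, weight=segment.weight)


def acf_vector(x: np.ndarray, n_lags: int = DEFAULT_N_LAGS) -> np.ndarray:
    """Normalized autocorrelation at lags 0..n_lags-1 (lag 0 equals 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.var(x) == 0:
        raise DegenerateSegmentError("zero-variance or non-finite segment")
    if n_lags > len(x):
        raise ValueError("n_lags cannot exceed the segment length")
    return _sm_acf(x, nlags=n_lags - 1, fft=True)


def pairwise_weight(acf_s: np.ndarray, acf_t: np.ndarray) -> float:
    """Centered cosine similarity of two ACF vectors (== their Pearson r)."""
    a = np.asarray(acf_s, dtype=float) - np.mean(acf_s)
    b = np.asarray(acf_t, dtype=float) - np.mean(acf_t)
    if len(a) != len(b):
        raise ValueError("ACF vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateSegmentError("zero centered norm in ACF vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def segment_weights(segments: list[Segment],
                    lambda_threshold: float = DEFAULT_LAMBDA,
                    n_lags: int = DEFAULT_N_LAGS,
                    include_self: bool = False) -> SegmentWeights:
    """Quality-weight all segments of one recording and mark the noisy ones.

    ``weights[s]`` is the mean of ``w_st`` over the other segments ``t``
    (``include_self=True`` adds the unit self-similarity to the mean).
    ``dropped`` collects degenerate segments and those with weight below
    ``lambda_threshold``. The weights are stored back on the segments.
    """
    n = len(segments)
    sim = np.full((n, n), np.nan)
    np.fill_diagonal(sim, 1.0)
    weights = np.full(n, np.nan)
    degenerate: list[int] = []

    acfs: list[np.ndarray | None] = []
    for i, seg in enumerate(segments):
        try:
            acfs.append(acf_vector(seg.samples, n_lags=n_lags))
        except DegenerateSegmentError:
            acfs.append(None)
            degenerate.append(i)

    valid = [i for i in range(n) if acfs[i] is not None]
    if len(valid) < 2:
        logger.warning("fewer than 2 usable segments: weights undefined, "
                       "nothing dropped by threshold")
        return SegmentWeights(similarity=sim, weights=weights,
                              lambda_threshold=lambda_threshold,
                              dropped=sorted(degenerate), degenerate=degenerate)

    acf_mat = np.vstack([acfs[i] for i in valid])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(acf_mat)
    corr = np.clip(corr, -1.0, 1.0)
    for a, i in enumerate(valid):
        for b, j in enumerate(valid):
            sim[i, j] = corr[a, b]
        off = np.delete(corr[a], a)
        if include_self:
            weights[i] = (off.sum() + 1.0) / len(valid)
        else:
            weights[i] = off.mean()
        segments[i].weight = float(weights[i])

    dropped = sorted(set(degenerate) |
                     {i for i in valid if weights[i] < lambda_threshold})
    logger.info("segment weights: %d segments, %d degenerate, %d dropped "
                "(lambda=%.3g)", n, len(degenerate), len(dropped),
                lambda_threshold)
    return SegmentWeights(similarity=sim, weights=weights,
                          lambda_threshold=lambda_threshold,
                          dropped=dropped, degenerate=degenerate)


def clean_segments(segments: list[Segment], sw: SegmentWeights) -> list[Segment]:
    """Segments that survived the quality threshold, in original order."""
    dropped = set(sw.dropped)
    return [s for i, s in enumerate(segments) if i not in dropped]
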