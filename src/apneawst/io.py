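"""Reading and writing single-lead ECG waveforms and per-minute apnea labels.

Two on-disk dialects are supported:

* a minimal subset of the PhysioNet WFDB format — format-16 (16-bit
  little-endian integer) signal files with a plain-text header, which is
  what the Apnea-ECG database uses;
* plain delimited text with one sample per line, plus a label sidecar with
  one ``<minute> <N|A>`` pair per line.

Labels are per-minute with minute ``m`` covering samples
``[m*60*fs, (m+1)*60*fs)`` (0-based, half-open).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

LABEL_NORMAL = "normal"
LABEL_APNEA = "apnea"
LABEL_UNLABELED = "unlabeled"

#: annotation codes accepted in label sidecars
_CODE_TO_LABEL = {"N": LABEL_NORMAL, "A": LABEL_APNEA}
_LABEL_TO_CODE = {LABEL_NORMAL: "N", LABEL_APNEA: "A"}


class EcgIoError(Exception):
    """Raised for malformed or unsupported ECG files."""


@dataclass
class EcgRecord:
    """A single-lead ECG waveform with optional per-minute apnea labels.

    Parameters
    ----------
    record_id : str
        Identifier of the recording (typically the file stem).
    samples : ndarray
        Waveform in physical units (mV).
    fs : float
        Sampling frequency in Hz (100 Hz for the Apnea-ECG recordings).
    labels : list of str
        One label per whole minute, each ``"normal"``, ``"apnea"`` or
        ``"unlabeled"``; may be empty when no annotations exist.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.labels and len(self.labels) != self.n_minutes:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n_minutes} whole minutes"
            )

    @property
    def n_minutes(self) -> int:
        """Number of whole minutes covered by the waveform."""
        return int(len(self.samples) // (60 * self.fs))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# WFDB (format 16) support
# ---------------------------------------------------------------------------

_DEFAULT_GAIN = 200.0  # WFDB convention: adu per physical unit when 0/absent


def _parse_gain_field(token: str) -> tuple[float, float]:
    """Split a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline)."""
    gain_part = token.split("/")[0]
    baseline = 0.0
    if "(" in gain_part:
        gain_str, base_str = gain_part.split("(")
        baseline = float(base_str.rstrip(")"))
    else:
        gain_str = gain_part
    gain = float(gain_str)
    if gain == 0:
        gain = _DEFAULT_GAIN
    return gain, baseline


def read_wfdb_record(header_path: str | Path, channel: int | None = None) -> EcgRecord:
    """Read a WFDB header/signal pair into an :class:`EcgRecord`.

    Only format-16 records with one or two channels sharing a single signal
    file are supported — sufficient for Apnea-ECG-style single-lead data.
    Stored integers are converted to physical units as
    ``(adc - baseline) / gain``.

    Parameters
    ----------
    header_path : path
        Path to the ``.hea`` file; the signal file it names must sit next
        to it.
    channel : int, optional
        Channel to extract when the record holds more than one.
    """
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise EcgIoError(f"{header_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise EcgIoError(f"{header_path}: header line needs name/nsig/fs/nsamp")
    record_id, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samp = int(head[3])
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise EcgIoError(f"{header_path}: expected {n_sig} signal lines")
    if n_sig > 2:
        raise EcgIoError(f"{header_path}: only 1- or 2-channel records supported")
    if n_sig > 1 and channel is None:
        raise EcgIoError(
            f"{header_path}: {n_sig} channels present; a channel index is required"
        )
    channel = 0 if channel is None else channel
    if not 0 <= channel < n_sig:
        raise EcgIoError(f"channel {channel} out of range for {n_sig} channels")

    sig_files, fmts, gains, baselines = [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        fields = ln.split()
        sig_files.append(fields[0])
        fmts.append(fields[1].split("x")[0].split(":")[0].split("+")[0])
        if len(fields) > 2:
            g, b = _parse_gain_field(fields[2])
        else:
            g, b = _DEFAULT_GAIN, 0.0
        # explicit baseline field (5th, adc zero) overrides when present
        if "(" not in (fields[2] if len(fields) > 2 else "") and len(fields) > 4:
            b = float(fields[4])
        gains.append(g)
        baselines.append(b)
    if any(f != "16" for f in fmts):
        raise EcgIoError(f"{header_path}: only format 16 supported, got {fmts}")
    if len(set(sig_files)) != 1:
        raise EcgIoError(f"{header_path}: channels must share one signal file")

    dat_path = header_path.parent / sig_files[0]
    if not dat_path.exists():
        raise FileNotFoundError(f"signal file {dat_path} missing for {header_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samp and len(raw) < n_samp * n_sig:
        raise EcgIoError(
            f"{dat_path}: {len(raw)} stored values < declared {n_samp * n_sig}"
        )
    if n_samp:
        raw = raw[: n_samp * n_sig]
    adc = raw.reshape(-1, n_sig)[:, channel].astype(float)
    physical = (adc - baselines[channel]) / gains[channel]
    return EcgRecord(record_id=record_id, samples=physical, fs=fs)


def write_wfdb_record(record: EcgRecord, directory: str | Path,
                      gain: float = _DEFAULT_GAIN) -> Path:
    """Write ``record`` as a format-16 WFDB header/signal pair.

    Samples are quantized to ``round(sample * gain)`` 16-bit integers, i.e.
    the resolution of the original Apnea-ECG recordings at the default gain.
    Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.samples * gain)
    if np.any(np.abs(adc) > 32767):
        raise EcgIoError("samples exceed 16-bit range at this gain")
    hea = directory / f"{record.record_id}.hea"
    dat_name = f"{record.record_id}.dat"
    hea.write_text(
        f"{record.record_id} 1 {record.fs:g} {len(record.samples)}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 ECG\n"
    )
    adc.astype("<i2").tofile(directory / dat_name)
    return hea


# ---------------------------------------------------------------------------
# Minute-label sidecars
# ---------------------------------------------------------------------------

def read_minute_annotations(path: str | Path, n_minutes: int) -> list[str]:
    """Read a ``<minute> <N|A>`` sidecar into a label list of ``n_minutes``.

    Minutes absent from the file come back ``"unlabeled"`` (reported via a
    warning), as do unknown codes. Minute indices must be strictly
    increasing.
    """
    if n_minutes < 0:
        raise ValueError("n_minutes must be >= 0")
    labels = [LABEL_UNLABELED] * n_minutes
    last = -1
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise EcgIoError(f"{path}:{lineno}: expected '<minute> <code>'")
        try:
            minute = int(parts[0])
        except ValueError as exc:
            raise EcgIoError(f"{path}:{lineno}: bad minute index {parts[0]!r}") from exc
        if minute <= last:
            raise EcgIoError(f"{path}:{lineno}: minute indices must increase")
        last = minute
        if minute >= n_minutes:
            logger.warning("%s:%d: minute %d beyond record end, ignored",
                           path, lineno, minute)
            continue
        code = parts[1].upper()
        if code not in _CODE_TO_LABEL:
            warnings.warn(f"{path}:{lineno}: unknown label code {parts[1]!r}, "
                          f"treating minute {minute} as unlabeled")
            continue
        labels[minute] = _CODE_TO_LABEL[code]
    n_missing = sum(1 for lb in labels if lb == LABEL_UNLABELED)
    if n_missing:
        logger.warning("%s: %d of %d minutes unlabeled", path, n_missing, n_minutes)
    return labels


def write_minute_annotations(labels: list[str], path: str | Path) -> None:
    """Write labeled minutes as a ``<minute> <N|A>`` sidecar (skips unlabeled)."""
    with open(path, "w") as fh:
        for minute, label in enumerate(labels):
            if label in _LABEL_TO_CODE:
                fh.write(f"{minute} {_LABEL_TO_CODE[label]}\n")


# ---------------------------------------------------------------------------
# Delimited text signals
# ---------------------------------------------------------------------------

def read_delimited_signal(path: str | Path, fs: float,
                          record_id: str | None = None) -> EcgRecord:
    """Read a one-sample-per-line text signal. Trailing blank lines are fine."""
    path = Path(path)
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError as exc:
            raise EcgIoError(f"{path}:{lineno}: non-numeric token {token!r}") from exc
    return EcgRecord(record_id=record_id or path.stem,
                     samples=np.asarray(values), fs=fs)


def write_delimited_signal(record: EcgRecord, path: str | Path,
                           precision: int = 9) -> None:
    np.savetxt(path, record.samples, fmt=f"%.{precision}f")
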