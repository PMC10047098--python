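"""Synthetic single-lead ECG with minute-by-minute apnea labels.

The generator is template-based: Ricker (Gaussian second-derivative) QRS
complexes are placed at beat times driven by an RR-interval process.

* Normal minutes: RR ~ 0.8 s modulated by respiratory sinus arrhythmia
  (a few-second sinusoid of small depth).
* Apnea minutes: RR and R-wave amplitude are modulated by a slow sinusoid
  with a 30–60-s period — the cyclical variation of heart rate
  (bradycardia during the event, tachycardia at its termination) that
  accompanies obstructive events.

On top of the beat train: white measurement noise, sub-Hz baseline wander,
50 Hz power-line interference, and optional broadband high-amplitude burst
artifacts on designated minutes (emulating electrode motion), which the
quality-weighting stage is expected to reject.

Everything is driven by one integer seed: identical config + seed gives a
bit-identical record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import LABEL_APNEA, LABEL_NORMAL, EcgRecord

#: benchmark base seeds per difficulty (offset by the caller's seed)
_BENCH_SEEDS = {"easy": 101, "hard": 202}


@dataclass
class SynthConfig:
    """Generator settings; defaults model a 100 Hz Apnea-ECG-like recording."""

    fs: float = 100.0
    n_minutes_normal: int = 10
    n_minutes_apnea: int = 10
    rr_base: float = 0.8                  # s, ~75 bpm
    resp_period: float = 4.0              # s, respiratory modulation of RR
    resp_rr_depth: float = 0.04           # fractional RSA depth (normal minutes)
    rr_jitter_sd: float = 0.02            # s, beat-to-beat HRV jitter (both classes)
    apnea_cycle_range: tuple[float, float] = (30.0, 60.0)  # s, CVHR period
    apnea_rr_depth: float = 0.25          # fractional RR swing during events
    apnea_amp_depth: float = 0.4          # fractional R-amplitude swing
    qrs_width: float = 0.025              # s, Ricker width parameter
    r_amplitude: float = 1.0              # mV
    white_sd: float = 0.03                # mV
    baseline_wander_amp: float = 0.1      # mV at baseline_wander_hz
    baseline_wander_hz: float = 0.3
    powerline_amp: float = 0.02           # mV at 50 Hz
    artifact_minutes: tuple[int, ...] = ()
    artifact_burst_sd: float = 1.0        # mV, broadband burst amplitude
    artifact_burst_s: tuple[float, float] = (5.0, 20.0)  # burst length range
    seed: int = 0
    record_id: str = "synth"

    def __post_init__(self) -> None:
        lo, hi = self.apnea_cycle_range
        if not 30.0 <= lo <= hi <= 60.0:
            raise ValueError("apnea cycle period range must lie in [30, 60] s")
        for name in ("white_sd", "baseline_wander_amp", "powerline_amp",
                     "artifact_burst_sd", "r_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _ricker(t: np.ndarray, width: float) -> np.ndarray:
    """Gaussian second-derivative pulse, peak-normalized to 1."""
    a = (t / width) ** 2
    return (1 - a) * np.exp(-a / 2)


def _minute_beats(rng: np.random.Generator, cfg: SynthConfig, label: str,
                  cycle_period: float) -> np.ndarray:
    """One minute of the QRS train (no noise), 60*fs samples."""
    spm = int(round(60 * cfg.fs))
    t = np.arange(spm) / cfg.fs
    x = np.zeros(spm)
    phase = rng.uniform(0, 2 * np.pi)
    resp_phase = rng.uniform(0, 2 * np.pi)
    tt = -rng.uniform(0, cfg.rr_base)  # random beat-grid offset
    width_n = int(6 * cfg.qrs_width * cfg.fs)
    tk = np.arange(-width_n, width_n + 1) / cfg.fs
    template = _ricker(tk, cfg.qrs_width)
    while tt < 60.0:
        if label == LABEL_APNEA:
            mod = np.sin(2 * np.pi * tt / cycle_period + phase)
            rr = cfg.rr_base * (1 + cfg.apnea_rr_depth * mod)
            amp = cfg.r_amplitude * (1 - cfg.apnea_amp_depth * mod)
        else:
            rr = cfg.rr_base * (1 + cfg.resp_rr_depth *
                                np.sin(2 * np.pi * tt / cfg.resp_period +
                                       resp_phase))
            amp = cfg.r_amplitude
        rr = max(rr + rng.normal(0.0, cfg.rr_jitter_sd), 0.3)
        center = int(round(tt * cfg.fs))
        lo = center - width_n
        hi = center + width_n + 1
        s_lo, s_hi = max(lo, 0), min(hi, spm)
        if s_lo < s_hi:
            x[s_lo:s_hi] += amp * template[s_lo - lo:s_hi - lo]
        tt += rr
    return x


def generate_record(cfg: SynthConfig) -> EcgRecord:
    """Generate one labeled record; minute order is a seeded shuffle of the
    requested normal/apnea counts."""
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_minutes_normal + cfg.n_minutes_apnea
    if n_total == 0:
        return EcgRecord(record_id=cfg.record_id, samples=np.empty(0),
                         fs=cfg.fs, labels=[])
    labels = ([LABEL_NORMAL] * cfg.n_minutes_normal +
              [LABEL_APNEA] * cfg.n_minutes_apnea)
    labels = [labels[i] for i in rng.permutation(n_total)]
    cycle_period = rng.uniform(*cfg.apnea_cycle_range)

    spm = int(round(60 * cfg.fs))
    minutes = [_minute_beats(rng, cfg, lb, cycle_period) for lb in labels]
    x = np.concatenate(minutes)

    t = np.arange(len(x)) / cfg.fs
    x = x + cfg.baseline_wander_amp * np.sin(
        2 * np.pi * cfg.baseline_wander_hz * t + rng.uniform(0, 2 * np.pi))
    x = x + cfg.powerline_amp * np.sin(
        2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    x = x + cfg.white_sd * rng.standard_normal(len(x))

    for m in cfg.artifact_minutes:
        if not 0 <= m < n_total:
            raise ValueError(f"artifact minute {m} outside record")
        dur = rng.uniform(*cfg.artifact_burst_s)
        n_burst = min(int(dur * cfg.fs), spm)
        start = m * spm + rng.integers(0, spm - n_burst + 1)
        x[start:start + n_burst] += (cfg.artifact_burst_sd *
                                     rng.standard_normal(n_burst))
    return EcgRecord(record_id=cfg.record_id, samples=x, fs=cfg.fs,
                     labels=labels)


def make_benchmark(n_per_class: int, difficulty: str = "easy",
                   seed: int | None = None,
                   minutes_per_record: int = 20) -> tuple[list[EcgRecord], list[str]]:
    """A multi-record labeled benchmark at a fixed difficulty.

    ``easy`` uses deep cyclical modulation and low noise, ``hard`` shallow
    modulation and more noise. Minutes are spread over records of
    ``minutes_per_record`` minutes (balanced classes per record) so
    subject-wise protocols have groups to work with. Returns the records
    and the concatenated per-minute labels.
    """
    if difficulty not in _BENCH_SEEDS:
        raise ValueError("difficulty must be 'easy' or 'hard'")
    base_seed = _BENCH_SEEDS[difficulty] + (0 if seed is None else 7919 * seed)
    base_seed %= 2 ** 31
    if difficulty == "easy":
        tweaks = dict(apnea_rr_depth=0.30, apnea_amp_depth=0.5,
                      white_sd=0.02)
    else:
        tweaks = dict(apnea_rr_depth=0.10, apnea_amp_depth=0.12,
                      white_sd=0.08)

    per_rec = minutes_per_record // 2
    n_records = int(np.ceil(n_per_class / per_rec))
    records, labels = [], []
    remaining = n_per_class
    for k in range(n_records):
        n_cls = min(per_rec, remaining)
        remaining -= n_cls
        cfg = SynthConfig(n_minutes_normal=n_cls, n_minutes_apnea=n_cls,
                          seed=(base_seed + k) % 2 ** 31,
                          record_id=f"{difficulty}{k:03d}", **tweaks)
        rec = generate_record(cfg)
        records.append(rec)
        labels.extend(rec.labels)
    return records, labels


def benchmark_with_artifacts(n_minutes: int, n_artifacts: int,
                             seed: int = 0) -> tuple[EcgRecord, list[int]]:
    """A single record with ``n_artifacts`` burst-corrupted minutes, for
    exercising the quality-weight filter. Returns the record and the
    artifact minute indices."""
    rng = np.random.default_rng(seed)
    artifact = sorted(rng.choice(n_minutes, size=n_artifacts, replace=False))
    cfg = SynthConfig(n_minutes_normal=n_minutes, n_minutes_apnea=0,
                      artifact_minutes=tuple(int(m) for m in artifact),
                      seed=seed, record_id=f"artifact{seed}")
    return generate_record(cfg), [int(m) for m in artifact]
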