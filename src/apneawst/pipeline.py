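"""End-to-end orchestration: read -> preprocess -> scatter -> featurize ->
classify -> report, behind a flat configuration with per-stage logging.

Every tunable of the method is a config key with the study defaults
(band-pass 3–45 Hz, quality threshold lambda = 0.8, invariance scale
T = 60 s, Q1 = 8, Q2 = 1, six windows per segment, r = 0.25 * STD,
10 CV repeats). Artifacts are persisted as delimited text / JSON with the
config hash and seed in a provenance header, so a rerun with the same
config reproduces them bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, features, preprocess, scattering, synthetic
from .io import (LABEL_APNEA, LABEL_NORMAL, EcgRecord, read_delimited_signal,
                 read_minute_annotations, read_wfdb_record)

logger = logging.getLogger(__name__)

_LABEL_CODE = {LABEL_NORMAL: 0, LABEL_APNEA: 1}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline."""

    # input: either paths to records or a synthetic benchmark
    input_records: list[str] = field(default_factory=list)  # .hea or .txt paths
    input_fs: float = 100.0
    synth_difficulty: str = "easy"
    synth_n_per_class: int = 100
    # preprocessing
    bandpass_low_hz: float = 3.0
    bandpass_high_hz: float = 45.0
    bandpass_taps: int = 101
    acf_n_lags: int = 500
    weight_lambda: float = 0.8
    weight_include_self: bool = False
    # scattering
    scattering_T: float = 60.0
    scattering_Q1: int = 8
    scattering_Q2: int = 1
    scattering_n_windows: int = 6
    scattering_max_order: int = 2
    scattering_boundary: str = "periodic"
    # features
    shannon_bins: int = 32
    embedding_m: int = 2
    tolerance_r_factor: float = 0.25
    # classification
    cv_scheme: str = "kfold_10"
    cv_repeats: int = 10
    cv_folds: int = 10
    classifiers: list[str] = field(default_factory=lambda: ["RF"])
    rf_n_estimators: int = 500
    pca_variance: float | None = None
    subject_wise: bool = False
    # misc
    seed: int = 0
    out_dir: str = "apneawst_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded)."""
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_header(cfg: PipelineConfig) -> str:
    return f"# apneawst config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def load_records(cfg: PipelineConfig) -> list[EcgRecord]:
    """Input stage: read configured record files or generate the synthetic
    benchmark when no inputs are listed."""
    if not cfg.input_records:
        records, _ = synthetic.make_benchmark(cfg.synth_n_per_class,
                                              cfg.synth_difficulty,
                                              seed=cfg.seed)
        logger.info("input: generated %d synthetic records (%s)",
                    len(records), cfg.synth_difficulty)
        return records
    records = []
    for p in cfg.input_records:
        p = Path(p)
        if p.suffix == ".hea":
            rec = read_wfdb_record(p)
        else:
            rec = read_delimited_signal(p, fs=cfg.input_fs)
        ann = p.with_suffix(".ann")
        if ann.exists():
            rec.labels = read_minute_annotations(ann, rec.n_minutes)
        records.append(rec)
    logger.info("input: read %d records", len(records))
    return records


def preprocess_records(records: list[EcgRecord], cfg: PipelineConfig):
    """Segment, filter and quality-weight each record; return the surviving
    labeled segments and a per-segment weight report."""
    kept, report_rows = [], []
    for rec in records:
        segs = preprocess.segment_record(rec)
        segs = [preprocess.bandpass_segment(s, rec.fs,
                                            low_hz=cfg.bandpass_low_hz,
                                            high_hz=cfg.bandpass_high_hz,
                                            taps=cfg.bandpass_taps)
                for s in segs]
        sw = preprocess.segment_weights(segs,
                                        lambda_threshold=cfg.weight_lambda,
                                        n_lags=cfg.acf_n_lags,
                                        include_self=cfg.weight_include_self)
        for i, s in enumerate(segs):
            report_rows.append({"record": s.parent_id, "minute": s.minute_index,
                                "label": s.label,
                                "weight": sw.weights[i],
                                "dropped": i in set(sw.dropped)})
        kept.extend(preprocess.clean_segments(segs, sw))
    report = pd.DataFrame(report_rows)
    n_drop = int(report["dropped"].sum()) if len(report) else 0
    logger.info("preprocess: %d segments in, %d noisy dropped, %d kept",
                len(report), n_drop, len(kept))
    labeled = [s for s in kept if s.label in _LABEL_CODE]
    if len(labeled) < len(kept):
        logger.info("preprocess: %d unlabeled segments excluded from "
                    "classification", len(kept) - len(labeled))
    return labeled, report


def scatter_stage(segments, cfg: PipelineConfig):
    if not segments:
        raise PipelineError("scatter", "no clean segments to transform")
    fs = 100.0 if not segments else None
    spm = len(segments[0].samples)
    fs = spm / 60.0
    bank = scattering.build_filter_bank(fs=fs, T=cfg.scattering_T,
                                        Q1=cfg.scattering_Q1,
                                        Q2=cfg.scattering_Q2,
                                        signal_len=spm)
    coeffs = scattering.scatter_segments(segments, bank,
                                         max_order=cfg.scattering_max_order,
                                         n_windows=cfg.scattering_n_windows,
                                         boundary=cfg.scattering_boundary)
    X, meta = scattering.flatten_windows(coeffs)
    logger.info("scatter: %d segments -> %d windows x %d paths",
                len(segments), X.shape[0], X.shape[1])
    return bank, coeffs, X, meta


def featurize_stage(X, meta, cfg: PipelineConfig) -> pd.DataFrame:
    table = features.feature_matrix(X, meta, n_bins=cfg.shannon_bins,
                                    m=cfg.embedding_m,
                                    r_factor=cfg.tolerance_r_factor)
    logger.info("featurize: %d rows x %d features", len(table),
                len(features.FEATURE_NAMES))
    return table


def classify_stage(table: pd.DataFrame, cfg: PipelineConfig):
    labeled = table[table["label"].isin(_LABEL_CODE)]
    if labeled.empty:
        raise PipelineError("classify", "no clean segments with labels")
    y = labeled["label"].map(_LABEL_CODE).to_numpy()
    X = labeled[features.FEATURE_NAMES].to_numpy()
    groups = labeled["record"].to_numpy()
    if len(np.unique(y)) < 2:
        raise PipelineError("classify", "both classes required for CV")
    reports = {}
    for name in cfg.classifiers:
        cc = classify.CvConfig(scheme=cfg.cv_scheme, repeats=cfg.cv_repeats,
                               seed=cfg.seed, classifier=name,
                               hyperparams=({"n_estimators": cfg.rf_n_estimators}
                                            if name in ("RF", "ExtraTrees")
                                            else {}),
                               n_folds=cfg.cv_folds,
                               pca_variance=cfg.pca_variance,
                               subject_wise=cfg.subject_wise)
        reports[name] = classify.run_cv(X, y, cc, groups=groups)
        logger.info("classify[%s]: acc %.4f +/- %.4f", name,
                    reports[name].mean("acc"), reports[name].std("acc"))
    return reports


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages and persist every intermediate under ``cfg.out_dir``.

    Returns the artifact paths. Any stage failure raises
    :class:`PipelineError` tagged with the stage; artifacts already written
    are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    cfg.to_yaml(out / "config.yaml")
    artifacts["config"] = out / "config.yaml"

    def stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        return result

    records = stage("input", load_records, cfg)
    segments, weight_report = stage("preprocess", preprocess_records,
                                    records, cfg)
    _write_table(weight_report, out / "segment_weights.tsv", cfg)
    artifacts["weights"] = out / "segment_weights.tsv"

    bank, coeffs, X, meta = stage("scatter", scatter_stage, segments, cfg)
    coef_df = pd.concat(
        [meta.reset_index(drop=True),
         pd.DataFrame(X, columns=[f"p{i}" for i in range(X.shape[1])])], axis=1)
    _write_table(coef_df, out / "scattering_coefficients.tsv", cfg)
    paths_df = pd.DataFrame(
        [{"row": i, "order": p.order,
          "indices": "-".join(map(str, p.indices)),
          "center_freqs_hz": "-".join(f"{f:.6g}" for f in p.center_freqs)}
         for i, p in enumerate(coeffs[0].paths)])
    _write_table(paths_df, out / "scattering_paths.tsv", cfg)
    artifacts["coefficients"] = out / "scattering_coefficients.tsv"
    artifacts["paths"] = out / "scattering_paths.tsv"

    table = stage("featurize", featurize_stage, X, meta, cfg)
    _write_table(table, out / "features.tsv", cfg)
    artifacts["features"] = out / "features.tsv"

    reports = stage("classify", classify_stage, table, cfg)
    metrics = {name: rep.to_dict() for name, rep in reports.items()}
    metrics["_provenance"] = {"config_hash": cfg.config_hash(),
                              "seed": cfg.seed}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    artifacts["metrics"] = out / "metrics.json"
    rows = [{"classifier": name, "metric": m, "mean": rep.mean(m),
             "std": rep.std(m)}
            for name, rep in reports.items() for m in classify.METRIC_NAMES]
    _write_table(pd.DataFrame(rows), out / "metrics.tsv", cfg)
    return artifacts


def complexity_probe(signal_lengths: list[int], fs: float = 100.0,
                     n_trials: int = 3, seed: int = 0) -> dict:
    """Empirical runtime scaling of the scattering transform.

    Fits the log–log slope of runtime against ``N log2 N`` over the given
    lengths. Purely diagnostic — machine dependent, never used as a gate.
    With fewer than 3 lengths no fit is attempted.
    """
    rng = np.random.default_rng(seed)
    times, sizes, n_paths = [], [], []
    for n in signal_lengths:
        bank = scattering.build_filter_bank(fs=fs, T=n / fs, signal_len=n)
        x = rng.standard_normal(n)
        scattering.scattering_transform(x, bank)  # warm-up
        t0 = time.perf_counter()
        for _ in range(n_trials):
            c = scattering.scattering_transform(x, bank)
        times.append((time.perf_counter() - t0) / n_trials)
        sizes.append(n * np.log2(n))
        n_paths.append(len(c.paths))
    result = {"lengths": list(signal_lengths), "seconds": times,
              "n_paths": n_paths, "slope": None}
    if len(signal_lengths) >= 3:
        slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
        result["slope"] = float(slope)
    else:
        logger.warning("complexity probe: need >= 3 lengths to fit a slope")
    return result
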