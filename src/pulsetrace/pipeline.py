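"""End-to-end analysis orchestration.

``run_analysis`` wires the full pipeline: orientation-checked reading of
one or more trace files -> missingness filter -> linear imputation ->
optional normalization -> adaptive smoothing -> data-derived peak
constraints (pooled over all loaded traces) -> peak detection ->
feature extraction -> optional downstream analyses -> provenance
record. The analysis path contains no randomness, so identical inputs
and configuration give identical outputs.

Multiple input files are treated as experimental conditions (labelled by
file stem) but share one pooled set of detection constraints, so the
"mean of the max of every trace" statistic spans the whole loaded set.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import downstream, io, qc
from .errors import DimensionError, ValidationError
from .features import (
    extract_features,
    features_to_frame,
    first_peak_metrics,
    peaks_to_frame,
    summaries_to_frame,
    summarize_condition,
)
from .peaks import derive_params, detect_peaks
from .smoothing import (
    DEFAULT_WINDOW_FRACTION,
    SmoothingConfig,
    adaptive_window,
    smooth_matrix,
)
from .traces import TraceMatrix

__all__ = [
    "AnalysisConfig",
    "ProcessResult",
    "load_config",
    "save_config",
    "process_matrix",
    "run_analysis",
]

_ORIENTATIONS = {"auto": None, "columns": io.COLUMNS_ARE_CELLS, "rows": io.ROWS_ARE_CELLS}

#: pandas float format used for every output CSV (replay byte-compares them)
CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class AnalysisConfig:
    """All user inputs of one analysis run."""

    duration_hours: float
    period_hours: float
    missing_threshold: float = 0.10
    normalization: str = "none"  # none | by_max | by_initial
    orientation: str = "auto"  # auto | columns | rows
    smoothing_method: str = "gaussian"
    window_fraction: float = DEFAULT_WINDOW_FRACTION
    savgol_order: int = 3
    peak_overrides: dict[str, float] = field(default_factory=dict)
    cluster: bool = False
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    cluster_k: int = 2
    averages: bool = False
    first_peak: bool = True
    seed: int = 0
    output_prefix: str = "pulsetrace"

    def validate(self) -> None:
        problems = []
        if not self.duration_hours > 0:
            problems.append("duration_hours must be positive")
        if not self.period_hours > 0:
            problems.append("period_hours must be positive")
        elif self.duration_hours > 0 and self.period_hours > self.duration_hours:
            problems.append("period_hours must not exceed duration_hours")
        if not 0.0 <= self.missing_threshold <= 1.0:
            problems.append("missing_threshold must be in [0, 1]")
        if self.normalization not in qc.NORMALIZATION_MODES:
            problems.append(f"unknown normalization {self.normalization!r}")
        if self.orientation not in _ORIENTATIONS:
            problems.append(f"unknown orientation {self.orientation!r}")
        if problems:
            raise ValidationError("; ".join(problems))


_REQUIRED_KEYS = ("duration_hours", "period_hours")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat YAML mapping."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown config keys: {', '.join(unknown)}")
    missing = sorted(k for k in _REQUIRED_KEYS if k not in raw)
    if missing:
        raise ValidationError(f"{path}: missing required keys: {', '.join(missing)}")
    cfg = AnalysisConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _concat(matrices: list[TraceMatrix]) -> TraceMatrix:
    first = matrices[0]
    if len(matrices) == 1:
        return first
    for m in matrices[1:]:
        if m.n_time != first.n_time:
            raise DimensionError(
                "input files disagree on the number of time points "
                f"({m.n_time} vs {first.n_time})"
            )
    return TraceMatrix(
        values=np.hstack([m.values for m in matrices]),
        time_hours=first.time_hours.copy(),
        missing_mask=np.hstack([m.missing_mask for m in matrices]),
        cell_ids=[cid for m in matrices for cid in m.cell_ids],
        condition_labels=[lab for m in matrices for lab in (m.condition_labels or [])],
    )


def _resolve_overrides(
    overrides: dict[str, float], sampling_rate: float
) -> dict[str, float]:
    """Translate hour-valued width/separation overrides (keys prefixed
    ``__hours__``) into samples using the matrix's sampling rate."""
    out: dict[str, float] = {}
    for key, val in (overrides or {}).items():
        if key.startswith("__hours__"):
            out[key.removeprefix("__hours__")] = val * sampling_rate
        else:
            out[key] = val
    return out


@dataclass
class ProcessResult:
    """In-memory result of the QC -> smoothing -> detection -> features chain."""

    smoothed: TraceMatrix
    features: list  # list[TraceFeatures], trace order = smoothed columns
    params: object  # effective DerivedPeakParams
    default_params: object
    qc_report: qc.QCReport
    smoothing_cfg: SmoothingConfig
    mean_max: float


def process_matrix(cfg: AnalysisConfig, tm: TraceMatrix) -> ProcessResult:
    """Run the analysis chain on an in-memory trace matrix.

    Applies the missingness filter, linear imputation, normalization,
    adaptive smoothing, pooled constraint derivation, peak detection and
    feature extraction; no files are touched.
    """
    filtered, qc_report = qc.filter_missing(tm, cfg.missing_threshold)
    imputed_tm, imputed_cells = qc.impute_matrix(filtered)
    qc_report.imputed_cells = imputed_cells
    qc_report.normalization_mode = cfg.normalization
    normalized = qc.normalize_matrix(imputed_tm, cfg.normalization)

    window = adaptive_window(
        cfg.period_hours,
        normalized.sampling_rate,
        cfg.window_fraction,
        n_time=normalized.n_time,
    )
    smoothing_cfg = SmoothingConfig(
        method=cfg.smoothing_method,
        window_samples=window,
        polynomial_order=cfg.savgol_order,
    )
    smoothed = TraceMatrix(
        values=smooth_matrix(normalized.values, smoothing_cfg),
        time_hours=normalized.time_hours.copy(),
        missing_mask=np.zeros_like(normalized.missing_mask),
        cell_ids=list(normalized.cell_ids),
        condition_labels=list(normalized.condition_labels or []),
    )

    overrides = _resolve_overrides(cfg.peak_overrides, smoothed.sampling_rate)
    params = derive_params(smoothed, cfg.period_hours, overrides or None)
    defaults = derive_params(smoothed, cfg.period_hours)
    mean_max = float(np.mean(np.max(smoothed.values, axis=0)))

    features_list = []
    conditions = smoothed.condition_labels or [""] * smoothed.n_cells
    for j in range(smoothed.n_cells):
        trace = smoothed.values[:, j]
        pk = detect_peaks(trace, params, smoothed.time_hours, smoothed.cell_ids[j])
        features_list.append(
            extract_features(
                trace,
                smoothed.time_hours,
                pk,
                cfg.duration_hours,
                trace_id=smoothed.cell_ids[j],
                condition=conditions[j],
            )
        )
    return ProcessResult(
        smoothed=smoothed,
        features=features_list,
        params=params,
        default_params=defaults,
        qc_report=qc_report,
        smoothing_cfg=smoothing_cfg,
        mean_max=mean_max,
    )


def run_analysis(
    cfg: AnalysisConfig,
    input_paths: list[str | Path],
    out_dir: str | Path = ".",
) -> dict[str, str]:
    """Run the full pipeline; returns a manifest of written output files."""
    from .provenance import build_record, write_record  # local: avoids cycle

    cfg.validate()
    if not input_paths:
        raise ValidationError("at least one input file is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hint = _ORIENTATIONS[cfg.orientation]

    matrices = []
    input_meta = []
    for path in input_paths:
        path = Path(path)
        tm, report = io.read_traces(path, hint, cfg.duration_hours)
        condition = path.stem
        # prefix cell ids by file stem so pooled ids stay unique
        tm.cell_ids = [f"{condition}:{cid}" for cid in tm.cell_ids]
        tm.condition_labels = [condition] * tm.n_cells
        matrices.append(tm)
        input_meta.append(
            {
                "path": str(path.resolve()),
                "n_time": tm.n_time,
                "n_cells": tm.n_cells,
                "condition": condition,
                "orientation": asdict(report),
            }
        )
    pooled = _concat(matrices)

    result = process_matrix(cfg, pooled)
    smoothed = result.smoothed
    features_list = result.features

    prefix = cfg.output_prefix
    manifest: dict[str, str] = {}

    def _write(df, name: str) -> None:
        fname = f"{prefix}.{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format=CSV_FLOAT_FORMAT)
        manifest[name] = fname

    _write(peaks_to_frame(features_list), "peaks")
    _write(features_to_frame(features_list), "traces")
    _write(summaries_to_frame(summarize_condition(features_list)), "summary")
    if cfg.first_peak:
        _write(first_peak_metrics(features_list), "first_peak")
    if cfg.cluster:
        result = downstream.cluster_traces(
            smoothed, cfg.cluster_metric, cfg.cluster_linkage, cfg.cluster_k
        )
        import pandas as pd

        _write(
            pd.DataFrame(
                {"trace_id": smoothed.cell_ids, "cluster": result.labels}
            ),
            "clusters",
        )
        _write(
            pd.DataFrame(
                smoothed.values[:, result.cophenetic_order].T,
                index=[smoothed.cell_ids[i] for i in result.cophenetic_order],
            ),
            "heatmap_matrix",
        )
    if cfg.averages:
        import pandas as pd

        avg = downstream.average_trace(smoothed)
        frames = {}
        for cond, (mean, sd) in avg.items():
            frames[f"{cond}_mean"] = mean
            frames[f"{cond}_sd"] = sd
        _write(
            pd.DataFrame({"time_hours": smoothed.time_hours, **frames}), "averages"
        )

    record = build_record(
        cfg=cfg,
        input_meta=input_meta,
        qc_report=result.qc_report,
        smoothing_cfg=result.smoothing_cfg,
        sampling_rate=smoothed.sampling_rate,
        params=result.params,
        default_params=result.default_params,
        mean_max=result.mean_max,
        manifest=manifest,
    )
    manifest.update(write_record(record, out_dir, prefix))
    return manifest
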