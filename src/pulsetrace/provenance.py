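"""Reproducibility records and replay.

Every analysis run emits two twin records: a structured JSON document
holding all inputs, derived parameters and data-handling decisions, and
a plain-language narrative rendered *from* that structure (never the
other way round). The structured record alone suffices to re-run the
analysis bit-identically given the same input files and tool version,
which is what :func:`replay` does.

Numbers in the narrative are printed to six significant digits; the
narrative is deterministic apart from its timestamp line.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

from .errors import ReplayError
from .qc import QCReport
from .smoothing import SmoothingConfig

__all__ = ["ProvenanceRecord", "build_record", "write_record", "render_record", "replay"]


def _version() -> str:
    from . import __version__

    return __version__


def _sig6(x: float) -> str:
    return f"{float(x):.6g}"


@dataclass
class ProvenanceRecord:
    """Structured account of one analysis run."""

    timestamp: str
    version: str
    environment: dict
    inputs: list[dict]
    config: dict
    qc: dict
    smoothing: dict
    derived_peak_params: dict
    outputs: dict


def build_record(
    cfg,
    input_meta: list[dict],
    qc_report: QCReport,
    smoothing_cfg: SmoothingConfig,
    sampling_rate: float,
    params,
    default_params,
    mean_max: float,
    manifest: dict[str, str],
) -> ProvenanceRecord:
    import numpy, pandas, scipy  # versions for the environment block

    window_derivation = (
        f"window_samples = round(period_hours x sampling_rate x fraction) = "
        f"round({_sig6(cfg.period_hours)} x {_sig6(sampling_rate)} x "
        f"{_sig6(cfg.window_fraction)}) forced odd, floored at 3 -> "
        f"{smoothing_cfg.window_samples}"
    )
    peak_block = {
        "mean_of_trace_maxima": mean_max,
        "sampling_rate_per_hour": sampling_rate,
        "defaults": {
            "min_height": default_params.min_height,
            "min_prominence": default_params.min_prominence,
            "min_separation_samples": default_params.min_separation_samples,
            "min_width_samples": default_params.min_width_samples,
            "max_width_samples": default_params.max_width_samples,
        },
        "effective": {
            "min_height": params.min_height,
            "min_prominence": params.min_prominence,
            "min_separation_samples": params.min_separation_samples,
            "min_width_samples": params.min_width_samples,
            "max_width_samples": params.max_width_samples,
        },
        "source": params.source,
        "formulas": {
            "min_height": f"mean(max(traces))/10 = {_sig6(mean_max)}/10 = "
            f"{_sig6(default_params.min_height)}",
            "min_prominence": f"mean(max(traces))/20 = {_sig6(mean_max)}/20 = "
            f"{_sig6(default_params.min_prominence)}",
            "min_width_and_separation": f"rate x period/10 = {_sig6(sampling_rate)} x "
            f"{_sig6(cfg.period_hours)}/10 = "
            f"{_sig6(default_params.min_separation_samples)} samples",
            "max_width": f"rate x period x 10 = {_sig6(sampling_rate)} x "
            f"{_sig6(cfg.period_hours)} x 10 = "
            f"{_sig6(default_params.max_width_samples)} samples",
        },
    }
    return ProvenanceRecord(
        timestamp=datetime.now(timezone.utc).isoformat(),
        version=_version(),
        environment={
            "python": platform.python_version(),
            "platform": platform.platform(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        inputs=input_meta,
        config=asdict(cfg),
        qc={
            "n_input_traces": qc_report.n_input_traces,
            "n_excluded": qc_report.n_excluded,
            "excluded_ids": qc_report.excluded_ids,
            "per_trace_missing_fraction": qc_report.per_trace_missing_fraction,
            "imputed_cells": [[cid, idx] for cid, idx in qc_report.imputed_cells],
            "normalization_mode": qc_report.normalization_mode,
        },
        smoothing={
            "method": smoothing_cfg.method,
            "window_samples": smoothing_cfg.window_samples,
            "polynomial_order": smoothing_cfg.polynomial_order,
            "derivation": window_derivation,
        },
        derived_peak_params=peak_block,
        outputs=dict(manifest),
    )


def render_record(rec: ProvenanceRecord) -> str:
    """Plain-language narrative of a run, generated from the structure."""
    lines: list[str] = []
    add = lines.append
    add(f"Analysis record (pulsetrace v{rec.version})")
    add(f"Timestamp: {rec.timestamp}")
    add(
        f"Environment: Python {rec.environment['python']} on "
        f"{rec.environment['platform']}; numpy {rec.environment['numpy']}, "
        f"scipy {rec.environment['scipy']}, pandas {rec.environment['pandas']}."
    )
    add("")
    add("Inputs:")
    for meta in rec.inputs:
        o = meta["orientation"]
        add(
            f"  {meta['path']} (condition '{meta['condition']}'): "
            f"{meta['n_time']} time points x {meta['n_cells']} traces."
        )
        add(
            f"    Orientation: used {o['used_orientation']} "
            f"(inferred {o['inferred_orientation']}; jaggedness as given "
            f"{_sig6(o['jaggedness_as_given'])}, transposed "
            f"{_sig6(o['jaggedness_transposed'])};"
            f" warning {'ISSUED' if o['warning_issued'] else 'not issued'})."
        )
    cfg = rec.config
    add("")
    add("User inputs:")
    add(f"  Experiment duration: {_sig6(cfg['duration_hours'])} h.")
    add(f"  Expected pulse period: {_sig6(cfg['period_hours'])} h.")
    add(
        f"  Missing-data threshold: traces with more than "
        f"{_sig6(100 * cfg['missing_threshold'])}% missing samples are excluded."
    )
    add(f"  Normalization: {cfg['normalization']}.")
    add(f"  Seed: {cfg['seed']}.")
    add("")
    q = rec.qc
    add("Quality control:")
    add(
        f"  {q['n_input_traces']} traces loaded; {q['n_excluded']} excluded for "
        f"excess missing data"
        + (f" ({', '.join(q['excluded_ids'])})" if q["excluded_ids"] else "")
        + "."
    )
    n_imp = len(q["imputed_cells"])
    imp_traces = sorted({cid for cid, _ in q["imputed_cells"]})
    add(
        f"  {n_imp} missing samples imputed by linear interpolation"
        + (f" across traces: {', '.join(imp_traces)}" if imp_traces else "")
        + "."
    )
    add("")
    s = rec.smoothing
    add("Smoothing:")
    add(f"  Method: {s['method']}; {s['derivation']}.")
    if s["method"] == "savitzky_golay":
        add(f"  Polynomial order: {s['polynomial_order']}.")
    add("")
    p = rec.derived_peak_params
    add("Peak detection constraints (derived from the data):")
    for name in sorted(p["formulas"]):
        add(f"  {name}: {p['formulas'][name]}")
    if p["source"] == "user_override":
        add("  USER OVERRIDE in effect; effective values:")
        for key in sorted(p["effective"]):
            val = p["effective"][key]
            marker = " (overridden)" if val != p["defaults"][key] else ""
            add(f"    {key} = {_sig6(val)}{marker}")
    add("")
    add("Outputs:")
    for name in sorted(rec.outputs):
        add(f"  {name}: {rec.outputs[name]}")
    add("")
    return "\n".join(lines)


def write_record(
    rec: ProvenanceRecord, out_dir: str | Path, prefix: str
) -> dict[str, str]:
    """Write the JSON twin and the text narrative; returns manifest entries."""
    out_dir = Path(out_dir)
    json_name = f"{prefix}.provenance.json"
    txt_name = f"{prefix}.provenance.txt"
    payload = asdict(rec)
    payload["outputs"] = {
        **payload["outputs"],
        "provenance_json": json_name,
        "provenance_text": txt_name,
    }
    rec.outputs = payload["outputs"]
    (out_dir / json_name).write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out_dir / txt_name).write_text(render_record(rec), encoding="utf-8")
    return {"provenance_json": json_name, "provenance_text": txt_name}


def load_record(path: str | Path) -> ProvenanceRecord:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        return ProvenanceRecord(**payload)
    except TypeError as exc:
        raise ReplayError(f"{path}: not a valid provenance record: {exc}") from exc


def replay(record_path: str | Path, out_dir: str | Path = ".") -> dict[str, str]:
    """Re-execute an archived run from its structured provenance record.

    The pipeline is deterministic, so outputs equal the original run's
    byte for byte (given the same input files and tool version).
    """
    from .pipeline import AnalysisConfig, run_analysis

    rec = load_record(record_path)
    if rec.version != _version():
        warnings.warn(
            f"record was written by version {rec.version}, this is {_version()}; "
            "outputs may differ",
            stacklevel=2,
        )
    inputs = [meta["path"] for meta in rec.inputs]
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise ReplayError(f"replay inputs not found: {', '.join(missing)}")
    cfg = AnalysisConfig(**rec.config)
    return run_analysis(cfg, inputs, out_dir)
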