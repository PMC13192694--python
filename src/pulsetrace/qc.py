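"""Trace quality control: missingness filtering, imputation, normalization.

Traces with more than a set fraction of missing samples (default 10%,
*strict* inequality, so a trace at exactly the threshold survives) are
excluded. Gaps in surviving traces are filled by linear interpolation
between the nearest observed neighbors; gaps touching either end of the
trace are filled by constant extension of the nearest observed value,
since a line needs two flanks. Observed samples are never altered.

Normalization divides each trace by its maximum (``by_max``) or its
first value (``by_initial``); ``none`` is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, EmptyResultError, NormalizationError
from .traces import TraceMatrix

__all__ = [
    "QCReport",
    "filter_missing",
    "impute_linear",
    "impute_matrix",
    "normalize",
    "normalize_matrix",
]

NORMALIZATION_MODES = ("none", "by_max", "by_initial")


@dataclass
class QCReport:
    """Record of what the QC stage did to a trace matrix."""

    n_input_traces: int
    n_excluded: int
    excluded_ids: list[str]
    per_trace_missing_fraction: dict[str, float]
    imputed_cells: list[tuple[str, int]] = field(default_factory=list)
    normalization_mode: str = "none"


def filter_missing(
    tm: TraceMatrix, threshold: float = 0.10
) -> tuple[TraceMatrix, QCReport]:
    """Drop traces whose missing fraction strictly exceeds ``threshold``.

    Order of surviving traces is preserved. Raises
    :class:`EmptyResultError` if nothing survives.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    frac = tm.missing_fraction()
    keep = np.flatnonzero(frac <= threshold)
    excluded = [tm.cell_ids[j] for j in np.flatnonzero(frac > threshold)]
    report = QCReport(
        n_input_traces=tm.n_cells,
        n_excluded=len(excluded),
        excluded_ids=excluded,
        per_trace_missing_fraction={
            cid: float(f) for cid, f in zip(tm.cell_ids, frac)
        },
    )
    if keep.size == 0:
        raise EmptyResultError(
            f"all {tm.n_cells} traces exceed missing-fraction threshold "
            f"{threshold}; raise --missing-threshold or inspect the input"
        )
    return tm.select_cells(keep), report


def impute_linear(trace: np.ndarray, missing_mask: np.ndarray) -> np.ndarray:
    """Fill missing samples of one trace by linear interpolation.

    Interior gaps take the straight line between the nearest observed
    neighbors; leading/trailing gaps take the nearest observed value.
    Observed entries are returned bit-identical. Needs at least two
    observed points.
    """
    trace = np.asarray(trace, dtype=float)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    obs_idx = np.flatnonzero(~missing_mask)
    if obs_idx.size < 2:
        raise DegenerateInputError(
            f"need >= 2 observed points to impute, got {obs_idx.size}"
        )
    out = trace.copy()
    gap_idx = np.flatnonzero(missing_mask)
    if gap_idx.size:
        # np.interp does linear interior interpolation and constant
        # extension outside the observed support, exactly the rule here
        out[gap_idx] = np.interp(gap_idx, obs_idx, trace[obs_idx])
    return out


def impute_matrix(tm: TraceMatrix) -> tuple[TraceMatrix, list[tuple[str, int]]]:
    """Impute every trace of a matrix; returns the filled matrix and the
    list of (cell id, time index) pairs that were imputed."""
    values = tm.values.copy()
    imputed: list[tuple[str, int]] = []
    for j in range(tm.n_cells):
        mask_j = tm.missing_mask[:, j]
        if mask_j.any():
            values[:, j] = impute_linear(tm.values[:, j], mask_j)
            imputed.extend((tm.cell_ids[j], int(i)) for i in np.flatnonzero(mask_j))
    filled = TraceMatrix(
        values=values,
        time_hours=tm.time_hours.copy(),
        missing_mask=np.zeros_like(tm.missing_mask),
        cell_ids=list(tm.cell_ids),
        condition_labels=list(tm.condition_labels)
        if tm.condition_labels is not None
        else None,
    )
    return filled, imputed


def normalize(trace: np.ndarray, mode: str, trace_id: str = "?") -> np.ndarray:
    """Normalize one fully observed trace by max, initial value, or not at all."""
    trace = np.asarray(trace, dtype=float)
    if mode == "none":
        return trace.copy()
    if mode == "by_max":
        m = trace.max()
        if m <= 0:
            raise NormalizationError(
                f"trace {trace_id!r}: maximum is {m}, cannot normalize by max"
            )
        return trace / m
    if mode == "by_initial":
        first = trace[0]
        if first == 0:
            raise NormalizationError(
                f"trace {trace_id!r}: initial value is 0, cannot normalize by it"
            )
        return trace / first
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_matrix(tm: TraceMatrix, mode: str) -> TraceMatrix:
    """Normalize every trace of a fully observed matrix."""
    if mode == "none":
        return tm
    values = np.column_stack(
        [normalize(tm.values[:, j], mode, tm.cell_ids[j]) for j in range(tm.n_cells)]
    )
    return TraceMatrix(
        values=values,
        time_hours=tm.time_hours.copy(),
        missing_mask=tm.missing_mask.copy(),
        cell_ids=list(tm.cell_ids),
        condition_labels=list(tm.condition_labels)
        if tm.condition_labels is not None
        else None,
    )
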