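"""Reading trace matrices and inferring their orientation.

Fluorescence trace tables arrive with no reliable convention for whether
rows or columns hold time. A matrix read in the wrong orientation
alternates between distinct cell traces at successive "time" points,
which shows up as strong artificial discontinuity. We quantify this with
a scale-free *jaggedness* metric — the mean absolute second difference of
each putative trace, normalized by that trace's range — and prefer the
orientation with the smaller score. A user-supplied orientation is never
overridden, but a warning is issued when it looks wrong.

CSV/TSV is the interchange format: rows = time points, columns = cells,
optional single header row of cell labels, empty/"NA"/"NaN" tokens for
missing samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, DimensionError, ParseError, PulseTraceError
from .traces import TraceMatrix, make_time_axis

__all__ = [
    "OrientationReport",
    "jaggedness",
    "check_orientation",
    "read_traces",
    "write_traces",
    "MISSING_TOKENS",
    "WARN_RATIO",
]

#: case-insensitive tokens treated as missing values in delimited files
MISSING_TOKENS = {"", "na", "nan"}

#: one-sided margin before an orientation warning fires
WARN_RATIO = 1.5

_EPS = 1e-12

COLUMNS_ARE_CELLS = "columns_are_cells"
ROWS_ARE_CELLS = "rows_are_cells"


@dataclass(frozen=True)
class OrientationReport:
    """Outcome of orientation inference for one input matrix."""

    jaggedness_as_given: float
    jaggedness_transposed: float
    inferred_orientation: str  # columns_are_cells | rows_are_cells
    warning_issued: bool
    used_orientation: str


def jaggedness(
    matrix: np.ndarray,
    missing_mask: np.ndarray | None = None,
    traces_axis: str = "columns",
) -> float:
    """Roughness score of a matrix under a putative trace orientation.

    For each putative trace, take its non-missing samples in time order,
    compute the mean absolute second difference, and divide by the
    trace's range (max - min) plus a tiny epsilon; return the mean over
    traces. Traces with fewer than three usable samples contribute 0.

    The score is invariant to adding a constant and to positive scaling,
    so it compares orientations, not signal magnitudes.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise DimensionError("jaggedness expects a 2-D matrix")
    if missing_mask is None:
        missing_mask = ~np.isfinite(values)
    else:
        missing_mask = np.asarray(missing_mask, dtype=bool) | ~np.isfinite(values)
    if traces_axis == "rows":
        values = values.T
        missing_mask = missing_mask.T
    elif traces_axis != "columns":
        raise ValueError(f"traces_axis must be 'columns' or 'rows', got {traces_axis!r}")
    if missing_mask.all():
        raise DegenerateInputError("cannot score an all-missing matrix")
    if values.shape[0] < 3:
        raise DegenerateInputError(
            "need at least 3 samples along the putative time axis"
        )
    scores = []
    for j in range(values.shape[1]):
        obs = values[~missing_mask[:, j], j]
        if obs.size < 3:
            scores.append(0.0)
            continue
        second = np.diff(obs, n=2)
        rng = obs.max() - obs.min()
        scores.append(float(np.mean(np.abs(second)) / (rng + _EPS)))
    return float(np.mean(scores))


def check_orientation(
    matrix: np.ndarray,
    missing_mask: np.ndarray | None = None,
    user_hint: str | None = None,
    warn_ratio: float = WARN_RATIO,
) -> OrientationReport:
    """Score both orientations of ``matrix`` and reconcile with a user hint.

    ``jaggedness_as_given`` treats the matrix as rows = time / columns =
    cells; ``jaggedness_transposed`` the reverse. The inferred
    orientation is the one with strictly smaller jaggedness (ties go to
    columns_are_cells). A user hint is always respected in
    ``used_orientation``; ``warning_issued`` is True iff the hinted
    orientation's jaggedness exceeds ``warn_ratio`` times the
    alternative's.
    """
    def _safe(axis: str) -> float:
        # an orientation with fewer than 3 putative time samples cannot
        # host traces at all: score it as infinitely jagged
        try:
            return jaggedness(matrix, missing_mask, traces_axis=axis)
        except DegenerateInputError:
            m = np.asarray(matrix)
            n_time = m.shape[0] if axis == "columns" else m.shape[1]
            if n_time < 3:
                return float("inf")
            raise

    j_given = _safe("columns")
    j_transposed = _safe("rows")
    if not (np.isfinite(j_given) or np.isfinite(j_transposed)):
        raise DegenerateInputError("matrix too small in both orientations")
    if j_transposed < j_given:
        inferred = ROWS_ARE_CELLS
    else:
        inferred = COLUMNS_ARE_CELLS
    if user_hint is None:
        used = inferred
        warning = False
    else:
        if user_hint not in (COLUMNS_ARE_CELLS, ROWS_ARE_CELLS):
            raise ValueError(f"unknown orientation hint {user_hint!r}")
        used = user_hint
        hinted = j_given if user_hint == COLUMNS_ARE_CELLS else j_transposed
        other = j_transposed if user_hint == COLUMNS_ARE_CELLS else j_given
        warning = hinted > warn_ratio * other
    return OrientationReport(
        jaggedness_as_given=j_given,
        jaggedness_transposed=j_transposed,
        inferred_orientation=inferred,
        warning_issued=warning,
        used_orientation=used,
    )


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def _parse_token(token: str) -> float | None:
    """Float value of a cell, or None if it is a missing token."""
    if _is_missing(token):
        return None
    return float(token)


def _sniff_delimiter(sample: str) -> str:
    # comma or tab only; prefer the one that actually appears
    first_line = sample.splitlines()[0] if sample else ""
    if "\t" in first_line and "," not in first_line:
        return "\t"
    return ","


def read_traces(
    path: str | Path,
    orientation_hint: str | None = None,
    duration_hours: float = 24.0,
    warn_ratio: float = WARN_RATIO,
) -> tuple[TraceMatrix, OrientationReport]:
    """Read a delimited trace table and return it in canonical orientation.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file. Optional single header row of cell labels;
        empty fields and "NA"/"NaN" (any case) mark missing samples.
    orientation_hint : str, optional
        ``"columns_are_cells"`` or ``"rows_are_cells"``; ``None`` lets the
        jaggedness metric decide.
    duration_hours : float
        Total experiment duration; the time axis is built from it (the
        file never carries a time column).

    Returns
    -------
    (TraceMatrix, OrientationReport)
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8-sig")
    except OSError as exc:
        raise PulseTraceError(f"cannot read input file {path}: {exc}") from exc
    delimiter = _sniff_delimiter(text)
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delimiter) if row]
    if not rows:
        raise ParseError(f"{path}: file is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ParseError(f"{path}: ragged rows — not a rectangular table")

    # header detection: first row is a header iff any cell is neither
    # numeric nor a missing token
    header: list[str] | None = None

    def _row_is_numeric(row: list[str]) -> bool:
        for tok in row:
            if _is_missing(tok):
                continue
            try:
                float(tok)
            except ValueError:
                return False
        return True

    body = rows
    if not _row_is_numeric(rows[0]):
        header = [tok.strip() for tok in rows[0]]
        body = rows[1:]

    n_rows, n_cols = len(body), width
    values = np.empty((n_rows, n_cols), dtype=float)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for i, row in enumerate(body):
        for j, tok in enumerate(row):
            try:
                val = _parse_token(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {i + 1}, column {j + 1}"
                ) from None
            if val is None:
                mask[i, j] = True
                values[i, j] = np.nan
            else:
                values[i, j] = val

    report = check_orientation(values, mask, orientation_hint, warn_ratio)
    if report.used_orientation == ROWS_ARE_CELLS:
        values = values.T
        mask = mask.T
        header = None  # header labelled time points, not cells
    if values.shape[0] < 3:
        raise DimensionError(
            f"{path}: only {values.shape[0]} time points after orientation; need >= 3"
        )
    cell_ids = header if header else [f"cell_{j}" for j in range(values.shape[1])]
    values = np.where(mask, 0.0, values)  # masked entries must stay finite
    tm = TraceMatrix(
        values=values,
        time_hours=make_time_axis(values.shape[0], duration_hours),
        missing_mask=mask,
        cell_ids=cell_ids,
    )
    return tm, report


def write_traces(tm: TraceMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a TraceMatrix as a delimited table (round-trips with read_traces)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(tm.cell_ids)
        for i in range(tm.n_time):
            row = [
                "" if tm.missing_mask[i, j] else repr(float(tm.values[i, j]))
                for j in range(tm.n_cells)
            ]
            writer.writerow(row)
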