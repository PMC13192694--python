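"""Canonical in-memory container for fluorescence trace matrices.

A :class:`TraceMatrix` always stores time along axis 0 (rows) and cells
along axis 1 (columns), with a uniform time axis in hours starting at 0.
Missing samples are carried in an explicit boolean mask rather than as
NaN so that downstream stages can distinguish "never observed" from
"computed to be NaN".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

__all__ = ["TraceMatrix"]


@dataclass
class TraceMatrix:
    """Time x cells matrix of fluorescence values with a missingness mask.

    Parameters
    ----------
    values : ndarray, shape (n_time, n_cells)
        Fluorescence values (arbitrary units or ratios). Entries flagged
        in ``missing_mask`` are ignored; all others must be finite.
    time_hours : ndarray, shape (n_time,)
        Uniformly spaced time axis starting at 0.
    missing_mask : ndarray of bool, same shape as ``values``
        True where the sample was not observed.
    cell_ids : list of str
        One label per column.
    condition_labels : list of str, optional
        Per-cell experimental condition tags.
    """

    values: np.ndarray
    time_hours: np.ndarray
    missing_mask: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    condition_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D matrix (time x cells)")
        n_time, n_cells = self.values.shape
        if n_time < 3:
            raise DimensionError(
                f"need at least 3 time points, got {n_time}"
            )
        if n_cells < 1:
            raise DimensionError("need at least 1 cell trace")
        self.time_hours = np.asarray(self.time_hours, dtype=float)
        if self.time_hours.shape != (n_time,):
            raise DimensionError("time_hours length must equal n_time")
        if self.time_hours[0] != 0.0:
            raise DimensionError("time axis must start at 0")
        steps = np.diff(self.time_hours)
        if np.any(steps <= 0):
            raise DimensionError("time axis must be strictly increasing")
        # uniform spacing to 1e-9 relative tolerance
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise DimensionError("time axis must be uniformly spaced")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise DimensionError("missing_mask shape must match values")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise DimensionError("observed values must be finite")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j}" for j in range(n_cells)]
        if len(self.cell_ids) != n_cells:
            raise DimensionError("cell_ids length must equal n_cells")
        if self.condition_labels is not None and len(self.condition_labels) != n_cells:
            raise DimensionError("condition_labels length must equal n_cells")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def duration_hours(self) -> float:
        return float(self.time_hours[-1])

    @property
    def spacing_hours(self) -> float:
        return float(self.time_hours[1] - self.time_hours[0])

    @property
    def sampling_rate(self) -> float:
        """Samples per hour."""
        return 1.0 / self.spacing_hours

    def missing_fraction(self) -> np.ndarray:
        """Per-trace fraction of missing samples, shape (n_cells,)."""
        return self.missing_mask.mean(axis=0)

    def select_cells(self, index: np.ndarray | list[int]) -> "TraceMatrix":
        """Return a new matrix restricted to the given cell columns (order kept)."""
        idx = np.asarray(index, dtype=int)
        return TraceMatrix(
            values=self.values[:, idx],
            time_hours=self.time_hours.copy(),
            missing_mask=self.missing_mask[:, idx],
            cell_ids=[self.cell_ids[j] for j in idx],
            condition_labels=(
                [self.condition_labels[j] for j in idx]
                if self.condition_labels is not None
                else None
            ),
        )


def make_time_axis(n_time: int, duration_hours: float) -> np.ndarray:
    """Uniform time axis 0..duration with n_time samples."""
    if duration_hours <= 0:
        raise DimensionError("duration_hours must be positive")
    return np.linspace(0.0, float(duration_hours), n_time)
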