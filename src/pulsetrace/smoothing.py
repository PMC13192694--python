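"""Adaptive noise smoothing of fluorescence traces.

The default filter is a Gaussian window whose width is one third of the
expected pulse period, converted to samples from the experiment's
sampling rate — so the same configuration adapts across experiments of
different durations and temporal resolutions. A Savitzky-Golay filter
(local polynomial least squares, better at preserving peak height) and a
plain moving average are available as alternatives.

Boundary handling for the kernel methods renormalizes the truncated
kernel instead of padding: no data are invented and the local mean is
preserved at the edges. Constant traces are exact fixed points of every
method and the operation is exactly linear.

Smoothing reshapes the frequency content of a trace; spectral analyses
should use raw, unsmoothed data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ParameterError

__all__ = ["SmoothingConfig", "adaptive_window", "smooth", "gaussian_kernel"]

METHODS = ("gaussian", "savitzky_golay", "moving_average", "none")

#: window fraction of the expected pulse period
DEFAULT_WINDOW_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing method plus its window, in samples.

    ``window_samples`` must be odd and at least 3; ``polynomial_order``
    applies to Savitzky-Golay only and must be smaller than the window.
    """

    method: str = "gaussian"
    window_samples: int = 11
    polynomial_order: int = 3

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown smoothing method {self.method!r}")
        if self.method != "none":
            if self.window_samples < 3 or self.window_samples % 2 == 0:
                raise ParameterError(
                    f"window_samples must be odd and >= 3, got {self.window_samples}"
                )
            if self.method == "savitzky_golay" and not (
                0 <= self.polynomial_order < self.window_samples
            ):
                raise ParameterError(
                    f"polynomial_order {self.polynomial_order} must be < "
                    f"window_samples {self.window_samples}"
                )


def adaptive_window(
    period_hours: float,
    sampling_rate: float,
    fraction: float = DEFAULT_WINDOW_FRACTION,
    n_time: int | None = None,
) -> int:
    """Smoothing window, in samples, scaled to the expected pulse period.

    window = round(period_hours * sampling_rate * fraction), forced odd
    (by adding one when even), floored at 3, and capped at the largest
    odd value not exceeding ``n_time`` when given.
    """
    if period_hours <= 0 or sampling_rate <= 0:
        raise ParameterError("period_hours and sampling_rate must be positive")
    w = int(math.floor(period_hours * sampling_rate * fraction + 0.5))
    if w % 2 == 0:
        w += 1
    w = max(w, 3)
    if n_time is not None:
        cap = n_time if n_time % 2 == 1 else n_time - 1
        w = min(w, cap)
    return w


def gaussian_kernel(window_samples: int) -> np.ndarray:
    """Discrete Gaussian kernel of odd length L with sigma = (L - 1) / 5,
    normalized to unit sum. The window edge sits at ~2.5 sigma."""
    length = window_samples
    sigma = (length - 1) / 5.0
    x = np.arange(length) - (length - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _renormalized_convolve(trace: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-length convolution; near the boundaries the truncated part of
    the kernel is renormalized to unit mass."""
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def smooth(trace: np.ndarray, cfg: SmoothingConfig) -> np.ndarray:
    """Smooth one fully observed trace; output has the input's length."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ParameterError("smooth expects a 1-D trace")
    if not np.all(np.isfinite(trace)):
        raise ParameterError("trace contains NaN/inf; impute before smoothing")
    if cfg.method == "none":
        return trace.copy()
    window = min(
        cfg.window_samples,
        trace.size if trace.size % 2 == 1 else trace.size - 1,
    )
    if cfg.method == "gaussian":
        return _renormalized_convolve(trace, gaussian_kernel(window))
    if cfg.method == "moving_average":
        kernel = np.full(window, 1.0 / window)
        return _renormalized_convolve(trace, kernel)
    if cfg.method == "savitzky_golay":
        order = min(cfg.polynomial_order, window - 1)
        return savgol_filter(trace, window_length=window, polyorder=order, mode="interp")
    raise ParameterError(f"unknown smoothing method {cfg.method!r}")


def smooth_matrix(values: np.ndarray, cfg: SmoothingConfig) -> np.ndarray:
    """Smooth each column of a (time x cells) matrix."""
    return np.column_stack([smooth(values[:, j], cfg) for j in range(values.shape[1])])
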