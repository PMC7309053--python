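"""ECG preprocessing: derivative filter, moving-average filter, normalization.

The stages run in that fixed order. The derivative filter removes baseline
wander and emphasises the fast QRS deflection; the moving average smooths
high-frequency noise; the final step rescales the whole record to

    y[n] = 2 * (x[n] - median(x)) / (max(x) - min(x))

so the amplitude span is exactly 2 and the median maps to 0. Normalization
statistics are computed over the full record, before any segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import DegenerateInputError, ECGRecord

__all__ = [
    "PreprocessConfig",
    "derivative_filter",
    "moving_average_filter",
    "normalize",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing chain.

    ma_window_s
        Moving-average span in seconds; converted to the nearest odd sample
        count (minimum 1) at the record's rate. Default 0.05 s: shorter than
        a QRS complex, so smoothing suppresses noise without flattening
        the R deflection the peak detector relies on.
    derivative_kind
        ``"first_difference"`` (y[n] = x[n] - x[n-1], first sample zero) or
        ``"central_difference"`` (y[n] = (x[n+1] - x[n-1]) / 2, both edges
        zero-padded).
    """

    ma_window_s: float = 0.05
    derivative_kind: str = "first_difference"

    def __post_init__(self) -> None:
        if self.ma_window_s <= 0:
            raise ValueError("ma_window_s must be positive")
        if self.derivative_kind not in ("first_difference", "central_difference"):
            raise ValueError(f"unknown derivative_kind {self.derivative_kind!r}")

    def ma_window_samples(self, sampling_rate_hz: float) -> int:
        """Odd window length in samples at the given rate (>= 1)."""
        n = int(round(self.ma_window_s * sampling_rate_hz))
        if n < 1:
            n = 1
        if n % 2 == 0:
            n += 1
        return n


def derivative_filter(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Discrete time-derivative of the record, same length as the input.

    Edge samples that lack a neighbour are zero-padded so downstream
    segment arithmetic stays exact.
    """
    config = config or PreprocessConfig()
    x = record.samples
    if x.size < 2:
        raise DegenerateInputError("derivative_filter needs at least 2 samples")
    y = np.zeros_like(x)
    if config.derivative_kind == "first_difference":
        y[1:] = np.diff(x)
    else:  # central_difference
        y[1:-1] = (x[2:] - x[:-2]) / 2.0
    return record.with_samples(y)


def moving_average_filter(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Centered moving mean with an odd window; edges use shrinking windows."""
    config = config or PreprocessConfig()
    x = record.samples
    w = config.ma_window_samples(record.sampling_rate_hz)
    if w > x.size:
        raise DegenerateInputError(
            f"moving-average window ({w} samples) longer than record ({x.size})"
        )
    if w == 1:
        return record.with_samples(x.copy())
    half = w // 2
    # cumulative-sum trick with shrinking edge windows: window at i is
    # x[max(0, i-half) : min(n, i+half+1)] averaged over its true length
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    y = (csum[hi] - csum[lo]) / (hi - lo)
    return record.with_samples(y)


def normalize(record: ECGRecord) -> ECGRecord:
    """Median-centered min-max normalization; output span is exactly 2.

    Raises
    ------
    DegenerateInputError
        If the signal is flat (max == min), which would divide by zero.
    """
    x = record.samples
    x_min, x_max = float(np.min(x)), float(np.max(x))
    if x_max == x_min:
        raise DegenerateInputError("cannot normalize a flat signal (max == min)")
    x_med = float(np.median(x))
    y = 2.0 * (x - x_med) / (x_max - x_min)
    return record.with_samples(y)


def preprocess(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Full chain: derivative filter -> moving-average filter -> normalize."""
    config = config or PreprocessConfig()
    return normalize(moving_average_filter(derivative_filter(record, config), config))
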