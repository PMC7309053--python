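"""Cutting a preprocessed record into fixed-length labelled windows.

Two modes are supported:

* ``fixed_window`` — non-overlapping consecutive slices of a fixed sample
  count (e.g. 288 samples at 128 Hz = 2.25 s, 444 samples at 360 Hz = 1.23 s);
  any trailing remainder is dropped.
* ``rpeak_grouped`` — each detected heartbeat is trimmed to a fixed window
  around its R peak and consecutive runs of ``group_n`` beats are
  concatenated into one model-input window.

R-peak detection follows a Pan-Tompkins-style chain (differentiate, square,
moving-window integrate, threshold) and enforces the clinical refractory
bound: no two peaks closer than 200 ms (equivalently, nothing above 300 bpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .records import DegenerateInputError, ECGRecord

__all__ = [
    "SegmentationConfig",
    "SegmentSet",
    "RPeakList",
    "detect_r_peaks",
    "enforce_refractory",
    "segment_fixed",
    "segment_rpeak_grouped",
    "window_duration_s",
    "max_heart_rate_bpm",
    "concat_segment_sets",
]


def window_duration_s(window_samples: int, sampling_rate_hz: float) -> float:
    """Duration in seconds of a window of `window_samples` at the given rate."""
    return window_samples / sampling_rate_hz


def max_heart_rate_bpm(refractory_s: float) -> float:
    """Maximum heart rate admissible under a minimum R-R interval."""
    return 60.0 / refractory_s


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of both segmentation modes.

    mode
        ``"fixed_window"`` or ``"rpeak_grouped"``.
    window_samples
        Slice length for fixed mode (288 for a 128 Hz record, 444 for 360 Hz
        in the reference datasets).
    group_n
        Number of consecutive beats concatenated per window in rpeak mode.
    beat_window_samples
        Per-beat trim length in rpeak mode.
    refractory_s
        Minimum admissible R-R interval in seconds; 0.2 s corresponds to the
        300 bpm clinical ceiling.
    pre_peak_fraction
        Fraction of the beat window placed before the R peak (default 1/3,
        so the P wave and the T wave both fit).
    """

    mode: str = "fixed_window"
    window_samples: int = 288
    group_n: int = 3
    beat_window_samples: int = 444
    refractory_s: float = 0.2
    pre_peak_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_window", "rpeak_grouped"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if self.group_n < 1:
            raise ValueError("group_n must be positive")
        if self.beat_window_samples < 1:
            raise ValueError("beat_window_samples must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if not 0.0 < self.pre_peak_fraction < 1.0:
            raise ValueError("pre_peak_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RPeakList:
    """Strictly increasing sample positions of detected (or true) R peaks."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SegmentSet:
    """Equal-length labelled windows ready for the classifier.

    windows : (n_windows, window_len) float array
    labels : list of subject ids, one per window
    """

    windows: np.ndarray
    labels: list[str]
    source_rate_hz: float
    mode: str

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 2:
            self.windows = self.windows.reshape(len(self.labels), -1)
        if self.windows.shape[0] != len(self.labels):
            raise ValueError("labels and windows must have equal count")

    def __len__(self) -> int:
        return int(self.windows.shape[0])

    @property
    def window_length(self) -> int:
        return int(self.windows.shape[1]) if len(self) else 0


def empty_segment_set(rate_hz: float, mode: str, window_len: int = 0) -> SegmentSet:
    return SegmentSet(np.empty((0, window_len)), [], rate_hz, mode)


def concat_segment_sets(sets: list[SegmentSet]) -> SegmentSet:
    """Stack several compatible SegmentSets into one."""
    nonempty = [s for s in sets if len(s)]
    if not nonempty:
        return sets[0] if sets else empty_segment_set(0.0, "fixed_window")
    lengths = {s.window_length for s in nonempty}
    if len(lengths) != 1:
        raise ValueError(f"incompatible window lengths: {sorted(lengths)}")
    rates = {s.source_rate_hz for s in nonempty}
    if len(rates) != 1:
        raise ValueError("cannot mix sampling rates in one SegmentSet")
    windows = np.vstack([s.windows for s in nonempty])
    labels = [lab for s in nonempty for lab in s.labels]
    return SegmentSet(windows, labels, nonempty[0].source_rate_hz, nonempty[0].mode)


def enforce_refractory(
    indices: np.ndarray, amplitudes: np.ndarray, min_gap_samples: int
) -> np.ndarray:
    """Drop peaks violating the minimum gap, keeping the taller of each pair.

    Greedy left-to-right pass: a candidate closer than `min_gap_samples` to
    the last kept peak replaces it if its amplitude is larger, else it is
    dropped.
    """
    indices = np.asarray(indices, dtype=np.int64)
    amplitudes = np.asarray(amplitudes, dtype=float)
    kept: list[int] = []
    for pos, amp in zip(indices, amplitudes):
        if kept and pos - kept[-1] < min_gap_samples:
            if amp > amplitudes[indices.searchsorted(kept[-1])]:
                kept[-1] = int(pos)
        else:
            kept.append(int(pos))
    return np.asarray(kept, dtype=np.int64)


def _integrated_envelope(x: np.ndarray, fs: float, span_s: float = 0.15) -> np.ndarray:
    """Squared signal smoothed by a moving-window integrator."""
    w = max(1, int(round(span_s * fs)))
    sq = x * x
    kernel = np.ones(w) / w
    return np.convolve(sq, kernel, mode="same")


def detect_r_peaks(record: ECGRecord, config: SegmentationConfig | None = None) -> RPeakList:
    """Locate R peaks in a preprocessed (amplitude-normalized) record.

    Pipeline: square the signal, integrate over a 150 ms moving window,
    mark regions where the envelope exceeds an adaptive threshold, merge
    regions separated by less than the refractory span, take the envelope
    argmax of each region as the beat position, then enforce the
    refractory bound by keeping the larger-amplitude peak of any violating
    pair. The centered integrator puts each envelope maximum at the QRS
    energy centroid, i.e. at the R peak up to a few samples.

    Returns an empty list (not an error) when the record is shorter than
    one refractory span or contains nothing above threshold.
    """
    config = config or SegmentationConfig()
    x = record.samples
    fs = record.sampling_rate_hz
    refractory = max(1, int(round(config.refractory_s * fs)))
    if x.size < refractory:
        return RPeakList(np.empty(0, dtype=np.int64))

    env = _integrated_envelope(x, fs)
    env_max = float(env.max())
    if env_max <= 0.0:
        return RPeakList(np.empty(0, dtype=np.int64))
    # adaptive threshold: a fraction of a robust high quantile, floored by
    # the median so broad low-energy waves (P/T) do not trigger
    thr = max(0.3 * float(np.quantile(env, 0.99)), 1.5 * float(np.median(env)))
    mask = env > thr
    if not mask.any():
        return RPeakList(np.empty(0, dtype=np.int64))
    # region boundaries: contiguous True runs of the mask
    idx = np.flatnonzero(mask)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], gaps + 1))
    run_ends = np.concatenate((gaps, [idx.size - 1]))
    regions = [(int(idx[a]), int(idx[b])) for a, b in zip(run_starts, run_ends)]
    # merge regions separated by less than the refractory span
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        if lo - merged[-1][1] < refractory:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    # energy centroid of each region: stable against the envelope's lobes
    candidates = np.asarray(
        [
            int(round(np.average(np.arange(lo, hi + 1), weights=env[lo : hi + 1])))
            for lo, hi in merged
        ],
        dtype=np.int64,
    )
    kept = enforce_refractory(candidates, env[candidates], refractory)
    return RPeakList(kept)


def segment_fixed(record: ECGRecord, config: SegmentationConfig) -> SegmentSet:
    """Non-overlapping consecutive windows of exactly `window_samples`.

    The trailing remainder shorter than one window is dropped; a record
    shorter than one window yields an empty SegmentSet.
    """
    x = record.samples
    w = config.window_samples
    count = x.size // w
    if count == 0:
        return empty_segment_set(record.sampling_rate_hz, "fixed_window", w)
    windows = x[: count * w].reshape(count, w).copy()
    labels = [record.subject_id] * count
    return SegmentSet(windows, labels, record.sampling_rate_hz, "fixed_window")


def segment_rpeak_grouped(
    record: ECGRecord, peaks: RPeakList, config: SegmentationConfig
) -> SegmentSet:
    """Trim each beat around its R peak and concatenate runs of `group_n`.

    Each usable beat contributes `beat_window_samples` samples with
    `pre_peak_fraction` of the window before the R peak. Beats whose
    window would run off the record are discarded. Groups are
    non-overlapping, in temporal order; leftover beats (< group_n) are
    dropped.
    """
    x = record.samples
    w = config.beat_window_samples
    pre = int(round(config.pre_peak_fraction * w))
    post = w - pre
    beats = []
    for r in peaks.indices:
        lo, hi = int(r) - pre, int(r) + post
        if lo < 0 or hi > x.size:
            continue
        beats.append(x[lo:hi])
    n_groups = len(beats) // config.group_n
    if n_groups == 0:
        return empty_segment_set(
            record.sampling_rate_hz, "rpeak_grouped", w * config.group_n
        )
    windows = np.stack(
        [
            np.concatenate(beats[g * config.group_n : (g + 1) * config.group_n])
            for g in range(n_groups)
        ]
    )
    labels = [record.subject_id] * n_groups
    return SegmentSet(windows, labels, record.sampling_rate_hz, "rpeak_grouped")
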