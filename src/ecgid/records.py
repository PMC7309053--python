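"""Core container for a single-channel ECG trace."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is too short/flat for the requested operation."""


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class ECGRecord:
    """A single-channel ECG trace with its sampling rate and subject label.

    Parameters
    ----------
    samples : np.ndarray
        1-D array of amplitudes (mV or arbitrary units). Must be non-empty
        and finite.
    sampling_rate_hz : float
        Sampling rate in Hz, strictly positive.
    subject_id : str
        Opaque identity label carried through the pipeline.
    channel_index : int
        Which channel of a multi-channel source this trace was taken from.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str = ""
    channel_index: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise DegenerateInputError("ECGRecord.samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECGRecord.samples must be finite")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.channel_index < 0:
            raise ValueError("channel_index must be non-negative")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of this record with new sample values (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))
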