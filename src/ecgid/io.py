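"""Record and dataset I/O: WFDB header/signal pairs, HDF5 segment
containers, JSON reports, and layered YAML/flag configuration.

WFDB support targets the two dialects used by the MIT-BIH databases:
format 212 (two 12-bit samples packed into 3 bytes, read-only here beyond
round-trip tests) and plain little-endian 16-bit (format 16), which the
writer emits. Samples are converted to physical units at read time:
``physical = (digital - baseline) / gain``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .records import ConfigurationError, ECGRecord
from .segmentation import SegmentSet

__all__ = [
    "RecordHeader",
    "read_wfdb_record",
    "write_wfdb_record",
    "save_segments",
    "load_segments",
    "load_config",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class RecordHeader:
    record_name: str
    num_channels: int
    sampling_rate_hz: float
    num_samples: int
    signal_files: list[str]
    formats: list[int]
    gains: list[float]  # ADC units per physical unit
    baselines: list[int]
    adc_resolutions: list[int]

    def __post_init__(self) -> None:
        if self.num_channels < 1 or self.num_samples < 1:
            raise ValueError("num_channels and num_samples must be positive")
        if any(g == 0 for g in self.gains):
            raise ValueError("gain must be nonzero")


def _parse_gain_field(field: str) -> tuple[float, int]:
    """Parse the WFDB 'gain(baseline)/units' field; defaults gain 200."""
    gain_part = field.split("/")[0]
    baseline = 0
    if "(" in gain_part:
        gain_str, base_str = gain_part.split("(")
        baseline = int(base_str.rstrip(")"))
    else:
        gain_str = gain_part
    gain = float(gain_str) if gain_str else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def read_wfdb_header(header_path: Path) -> RecordHeader:
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"missing WFDB header: {header_path}")
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    num_channels = int(first[1])
    fs = float(first[2]) if len(first) > 2 else 250.0
    num_samples = int(first[3]) if len(first) > 3 else 0
    files, formats, gains, baselines, resolutions = [], [], [], [], []
    for ln in lines[1 : 1 + num_channels]:
        parts = ln.split()
        files.append(parts[0])
        formats.append(int(parts[1].split("x")[0].split(":")[0].split("+")[0]))
        gain, baseline = _parse_gain_field(parts[2]) if len(parts) > 2 else (200.0, 0)
        gains.append(gain)
        resolutions.append(int(parts[3]) if len(parts) > 3 else 12)
        # explicit baseline field (5th token) overrides the (baseline) suffix
        if len(parts) > 4:
            baseline = int(parts[4])
        baselines.append(baseline)
    return RecordHeader(
        record_name, num_channels, fs, num_samples, files, formats, gains,
        baselines, resolutions,
    )


def _read_format_212(raw: bytes, num_channels: int, num_samples: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = b.size // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s0 = b[:, 0] + ((b[:, 1] & 0x0F) << 8)
    s1 = b[:, 2] + ((b[:, 1] & 0xF0) << 4)
    s0[s0 > 2047] -= 4096
    s1[s1 > 2047] -= 4096
    flat = np.empty(2 * n_pairs, dtype=np.int32)
    flat[0::2] = s0
    flat[1::2] = s1
    total = num_channels * num_samples
    return flat[:total].reshape(num_samples, num_channels)


def _read_format_16(raw: bytes, num_channels: int, num_samples: int) -> np.ndarray:
    flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    total = num_channels * num_samples
    return flat[:total].reshape(num_samples, num_channels)


def read_wfdb_record(path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record in physical units.

    `path` is the record path with or without the ``.hea`` extension.
    """
    path = Path(path)
    header_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    header = read_wfdb_header(header_path)
    if not 0 <= channel < header.num_channels:
        raise ConfigurationError(
            f"channel {channel} out of range for {header.num_channels}-channel record"
        )
    sig_path = header_path.parent / header.signal_files[channel]
    if not sig_path.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {sig_path}")
    raw = sig_path.read_bytes()
    fmt = header.formats[channel]
    if fmt == 212:
        digital = _read_format_212(raw, header.num_channels, header.num_samples)
    elif fmt == 16:
        digital = _read_format_16(raw, header.num_channels, header.num_samples)
    else:
        raise ConfigurationError(f"unsupported WFDB signal format {fmt}")
    physical = (digital[:, channel] - header.baselines[channel]) / header.gains[channel]
    return ECGRecord(
        physical,
        header.sampling_rate_hz,
        subject_id=header.record_name,
        channel_index=channel,
    )


def write_wfdb_record(
    record: ECGRecord, directory, record_name: str | None = None, gain: float = 1000.0
) -> Path:
    """Write a record as a format-16 WFDB header/signal pair; returns the
    header path. Quantization error is at most 1/(2*gain)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record_name or (record.subject_id or "record")
    digital = np.clip(
        np.round(record.samples * gain), -32768, 32767
    ).astype("<i2")
    (directory / f"{name}.dat").write_bytes(digital.tobytes())
    fs = record.sampling_rate_hz
    fs_str = f"{fs:g}"
    header = (
        f"{name} 1 {fs_str} {len(record)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0\n"
    )
    header_path = directory / f"{name}.hea"
    header_path.write_text(header)
    return header_path


# --------------------------------------------------------------------------
# native containers
# --------------------------------------------------------------------------


def save_segments(segments: SegmentSet, path) -> None:
    """Persist a SegmentSet to HDF5 with labels and provenance metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=segments.windows)
        f.create_dataset(
            "labels", data=np.array(segments.labels, dtype=h5py.string_dtype())
        )
        f.attrs["source_rate_hz"] = segments.source_rate_hz
        f.attrs["mode"] = segments.mode
        f.attrs["format_version"] = 1


def load_segments(path) -> SegmentSet:
    with h5py.File(path, "r") as f:
        windows = f["windows"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
        return SegmentSet(windows, labels, float(f.attrs["source_rate_hz"]), str(f.attrs["mode"]))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: default run configuration (training defaults match the standard recipe:
#: cross-entropy, Adam, learning rate 0.001, 80/20 split)
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "channel": 0,
    "ma_window_s": 0.05,
    "derivative": "first_difference",
    "mode": "fixed_window",
    "window_samples": 288,
    "group_n": 3,
    "beat_window_samples": 444,
    "refractory_s": 0.2,
    "arch": 6,
    "hidden_dim": 128,
    "learning_rate": 0.001,
    "batch_size": 100,
    "epochs": 50,
    "split_fraction": 0.8,
    "keep_prob": 1.0,
    "num_subjects": 6,
    "duration_s": 60.0,
    "sampling_rate_hz": 360.0,
    "noise_sd": 0.05,
    "baseline_wander_amp": 0.1,
    "baseline_wander_hz": 0.3,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Layered configuration: defaults < YAML file < explicit overrides.

    Unknown keys in the file or overrides are rejected by name.
    """
    config = dict(DEFAULT_CONFIG)
    layers = []
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        layers.append(loaded or {})
    if overrides:
        layers.append({k: v for k, v in overrides.items() if v is not None})
    for layer in layers:
        unknown = sorted(set(layer) - set(DEFAULT_CONFIG))
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {unknown}")
        config.update(layer)
    return config


def echo_config(config: dict, out_dir) -> Path:
    """Write the fully resolved configuration next to the run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True))
    return path
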