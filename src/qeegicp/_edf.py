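"""Minimal single-channel EDF writing, plus reading through MNE.

Only the subset of the European Data Format needed here is implemented on the
write side: one signal, 16-bit samples, 1-second data records, symmetric
physical range. Reading goes through :func:`mne.io.read_raw_edf` so the
writer is exercised against an independent parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} (max {width})")
    return b.ljust(width)


def write_edf(path, samples: np.ndarray, fs: float, label: str = "EEG",
              physical_dim: str = "uV") -> None:
    """Write a one-channel EDF file with 1-s records; pads the tail with zeros."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")

    n_records = int(np.ceil(samples.size / spr))
    padded = np.zeros(n_records * spr)
    padded[: samples.size] = samples

    phys_max = float(np.max(np.abs(padded)))
    phys_max = max(np.ceil(phys_max), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.clip(np.round((padded + phys_max) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),                       # patient id
            _field("Startdate X qeegicp synthetic", 80), # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * 2), 8),
            _field("EDF", 44),
            _field(str(n_records), 8),
            _field("1", 8),                              # record duration, s
            _field("1", 4),                              # number of signals
            _field(label, 16),
            _field("synthetic", 80),                     # transducer
            _field(physical_dim, 8),
            _field(f"{-phys_max:.1f}", 8),
            _field(f"{phys_max:.1f}", 8),
            _field(str(dig_min), 8),
            _field(str(dig_max), 8),
            _field("BP:0.5-47Hz", 80),
            _field(str(spr), 8),
            _field("", 32),
        ]
    )
    Path(path).write_bytes(header + digital.tobytes())


def read_edf(path) -> tuple[np.ndarray, float]:
    """Read the first channel of an EDF file; returns (samples in uV, fs)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0]
    # MNE rescales recognized channel kinds to SI volts; undo for uV output.
    if raw.get_channel_types()[0] in ("eeg", "eog", "ecg", "emg"):
        data = data * 1e6
    return data, float(raw.info["sfreq"])
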