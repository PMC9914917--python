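"""EEG preprocessing: band-pass filtering, epoch segmentation, hemodynamic
synchronization, stabilization-period exclusion, and IICP labelling.

Conventions: time is seconds from record start; epoch windows are half-open
``[start, start + epoch_length)``; the whole record is filtered before
epoching so windows share one filter transient; an epoch crossing a phase
boundary takes the phase of its start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocol_sim import SubjectRecord

__all__ = [
    "FilterSpec",
    "EpochSpec",
    "EpochTable",
    "IICP_THRESHOLD_MMHG",
    "bandpass_filter",
    "segment_epochs",
    "synchronize_and_label",
    "apply_exclusions",
    "preprocess_subject",
]

#: Operational threshold for increased intracranial pressure (inclusive).
IICP_THRESHOLD_MMHG = 25.0


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""

    low_cut: float = 0.5
    high_cut: float = 47.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut < fs / 2:
            raise ValueError(f"need 0 < low_cut < high_cut < fs/2; got {self} at fs={fs}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, [self.low_cut, self.high_cut],
                          btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class EpochSpec:
    epoch_length: float = 2.0
    overlap: float = 1.5
    stabilization_exclusion: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.epoch_length:
            raise ValueError("need 0 <= overlap < epoch_length")
        if self.stabilization_exclusion < 0:
            raise ValueError("stabilization_exclusion must be >= 0")

    @property
    def stride(self) -> float:
        return self.epoch_length - self.overlap


@dataclass
class EpochTable:
    """Overlapping EEG epochs with synchronized hemodynamics and labels.

    ``frame`` has one row per epoch (subject_id, start_s, mean_icp, mean_map,
    mean_hr, phase, iicp_label); ``samples[i]`` is the filtered uV window for
    row ``i``.
    """

    frame: pd.DataFrame
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.samples):
            raise ValueError("frame and samples row counts differ")

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def concat(tables: "list[EpochTable]") -> "EpochTable":
        fs = tables[0].fs
        if any(t.fs != fs for t in tables):
            raise ValueError("cannot concatenate tables with different sampling rates")
        return EpochTable(
            frame=pd.concat([t.frame for t in tables], ignore_index=True),
            samples=np.concatenate([t.samples for t in tables]),
            fs=fs,
        )


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase band-pass; same length as the input, no group delay."""
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    min_len = 3 * (2 * spec.order + 1)  # sosfiltfilt default pad length
    if x.shape[-1] <= min_len:
        raise ValueError(f"signal too short to filter: {x.shape[-1]} <= {min_len} samples")
    return sps.sosfiltfilt(sos, x, axis=-1)


def segment_epochs(
    x: np.ndarray, fs: float, spec: EpochSpec = EpochSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a signal into overlapping fixed-length windows.

    Returns ``(starts_s, windows)`` where windows is ``(n, epoch_length*fs)``.
    Epochs start at 0, stride, 2*stride, ...; a trailing partial window is
    dropped. A record shorter than one epoch yields zero epochs.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(spec.epoch_length * fs))
    step = int(round(spec.stride * fs))
    if step <= 0:
        raise ValueError("stride too small for this sampling rate")
    if x.size < win:
        return np.empty(0), np.empty((0, win))
    n = (x.size - win) // step + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, win)[::step][:n]
    starts = np.arange(n) * step / fs
    return starts, np.ascontiguousarray(windows)


def _window_means(trace: np.ndarray, trace_fs: float, starts: np.ndarray,
                  length: float) -> np.ndarray:
    """Mean of trace samples whose times fall in [start, start+length)."""
    trace = np.asarray(trace, dtype=float)
    out = np.empty(starts.size)
    for i, s in enumerate(starts):
        lo = int(np.ceil(s * trace_fs - 1e-9))
        hi = int(np.ceil((s + length) * trace_fs - 1e-9))
        if lo < 0 or hi > trace.size or hi <= lo:
            raise ValueError(
                f"epoch [{s}, {s + length}) s not covered by trace of "
                f"{trace.size / trace_fs} s"
            )
        out[i] = trace[lo:hi].mean()
    return out


def synchronize_and_label(
    starts: np.ndarray,
    windows: np.ndarray,
    fs: float,
    icp_trace: np.ndarray,
    map_trace: np.ndarray,
    hr_trace: np.ndarray,
    hemo_fs: float,
    phase_annotations: list[tuple[str, float, float]],
    subject_id: str = "",
    threshold: float = IICP_THRESHOLD_MMHG,
    epoch_length: float | None = None,
) -> EpochTable:
    """Attach epoch-mean hemodynamics, phase labels and the IICP label.

    An epoch is IICP-positive iff its mean ICP is >= ``threshold`` (inclusive).
    """
    starts = np.asarray(starts, dtype=float)
    if epoch_length is None:
        epoch_length = windows.shape[1] / fs
    mean_icp = _window_means(icp_trace, hemo_fs, starts, epoch_length)
    mean_map = _window_means(map_trace, hemo_fs, starts, epoch_length)
    mean_hr = _window_means(hr_trace, hemo_fs, starts, epoch_length)

    phase = np.empty(starts.size, dtype=object)
    for label, p_start, p_end in phase_annotations:
        phase[(starts >= p_start - 1e-9) & (starts < p_end - 1e-9)] = label

    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "start_s": starts,
            "mean_icp": mean_icp,
            "mean_map": mean_map,
            "mean_hr": mean_hr,
            "phase": phase,
            "iicp_label": (mean_icp >= threshold).astype(int),
        }
    )
    return EpochTable(frame=frame, samples=np.asarray(windows, dtype=float), fs=fs)


def apply_exclusions(
    table: EpochTable,
    spec: EpochSpec,
    phase_annotations: list[tuple[str, float, float]],
) -> EpochTable:
    """Drop epochs overlapping the stabilization window of each injury phase.

    An epoch is removed when ``[start, start+epoch_length)`` intersects
    ``[phase_start, phase_start + stabilization_exclusion)`` of any phase
    whose label is not ``baseline``. The baseline phase is kept in full.
    """
    if spec.stabilization_exclusion == 0:
        return table
    starts = table.frame["start_s"].to_numpy()
    ends = starts + spec.epoch_length
    keep = np.ones(starts.size, dtype=bool)
    for label, p_start, p_end in phase_annotations:
        if label == "baseline":
            continue
        excl_end = min(p_start + spec.stabilization_exclusion, p_end)
        keep &= ~((starts < excl_end) & (ends > p_start))
    return EpochTable(
        frame=table.frame.loc[keep].reset_index(drop=True),
        samples=table.samples[keep],
        fs=table.fs,
    )


def preprocess_subject(
    record: SubjectRecord,
    filter_spec: FilterSpec = FilterSpec(),
    epoch_spec: EpochSpec = EpochSpec(),
    threshold: float = IICP_THRESHOLD_MMHG,
) -> EpochTable:
    """Filter -> segment -> synchronize/label -> exclude, for one subject."""
    filtered = bandpass_filter(record.eeg, record.eeg_fs, filter_spec)
    starts, windows = segment_epochs(filtered, record.eeg_fs, epoch_spec)
    table = synchronize_and_label(
        starts, windows, record.eeg_fs,
        record.icp_trace, record.map_trace, record.hr_trace, record.hemo_fs,
        record.phase_annotations, subject_id=record.subject_id, threshold=threshold,
        epoch_length=epoch_spec.epoch_length,
    )
    return apply_exclusions(table, epoch_spec, record.phase_annotations)
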