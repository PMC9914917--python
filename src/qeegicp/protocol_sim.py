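"""Synthetic porcine TBI cohort generator.

Emulates a stepped intracranial-hypertension protocol: a baseline phase
followed by four balloon-inflation steps holding intracranial pressure (ICP)
near 20/30/40/50 mmHg, with single-channel scalp EEG whose spectral
composition shifts toward high-frequency (>= 13 Hz) components as ICP rises,
plus mean arterial pressure (MAP) and heart rate (HR) traces that climb with
ICP (Cushing-type response).

The EEG model is a pink-noise background plus five band-limited Gaussian
oscillators (delta/theta/alpha/beta/gamma) whose relative weights and overall
RMS amplitude are looked up per ICP bin from a :class:`SpectralProfile`.
The profile is a *directional* calibration: it reproduces the direction and
rough size of the band-power shifts observed across ICP bins in the animal
data this package emulates, not a fitted biophysical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "BAND_EDGES",
    "BAND_NAMES",
    "ICP_BIN_EDGES",
    "ProtocolConfig",
    "SpectralProfile",
    "SubjectRecord",
    "icp_bin_index",
    "generate_icp_trace",
    "generate_eeg",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

#: Conventional qEEG band edges (Hz); beta starts at 13 Hz, the high-frequency
#: boundary relevant for intracranial hypertension, and gamma is capped by the
#: 47 Hz acquisition band-pass.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 47.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BAND_EDGES)

#: ICP bin edges (mmHg) defining the five analysis bins:
#: <20, 20-30, 30-40, 40-50, >=50.
ICP_BIN_EDGES: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)


def icp_bin_index(icp: np.ndarray | float) -> np.ndarray:
    """Map ICP values (mmHg) to bin indices 0..4 (right-open bins)."""
    return np.digitize(np.asarray(icp, dtype=float), ICP_BIN_EDGES)


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and sampling parameters of the simulated protocol.

    Durations are seconds, pressures mmHg, rates Hz. ``hemo_sampling_rate``
    is deliberately 10 Hz rather than the 1 kHz of a bedside acquisition
    platform: downstream synchronization only needs epoch-mean values.
    """

    baseline_duration: float = 300.0
    injury_step_duration: float = 360.0
    icp_targets: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    baseline_icp_mean: float = 12.4
    eeg_sampling_rate: float = 250.0
    hemo_sampling_rate: float = 10.0
    n_subjects: int = 30
    ramp_duration: float = 30.0
    icp_jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0 or self.injury_step_duration <= 0:
            raise ValueError("durations must be positive")
        targets = tuple(float(t) for t in self.icp_targets)
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("icp_targets must be strictly increasing")
        gamma_high = BAND_EDGES["gamma"][1]
        if self.eeg_sampling_rate < 2.0 * gamma_high:
            raise ValueError(
                f"eeg_sampling_rate must be >= {2 * gamma_high} Hz to resolve the gamma band"
            )
        if self.ramp_duration < 0 or self.ramp_duration >= self.injury_step_duration:
            raise ValueError("ramp_duration must lie in [0, injury_step_duration)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + len(self.icp_targets) * self.injury_step_duration


def _default_band_weights() -> np.ndarray:
    # Rows: ICP bins <20, 20-30, 30-40, 40-50, >=50. Columns: delta..gamma.
    # Monotone trends: gamma/beta weight up, theta/delta weight down with ICP.
    return np.array(
        [
            [0.38, 0.22, 0.20, 0.14, 0.06],
            [0.37, 0.19, 0.20, 0.16, 0.08],
            [0.36, 0.16, 0.20, 0.18, 0.10],
            [0.35, 0.13, 0.20, 0.20, 0.12],
            [0.30, 0.08, 0.20, 0.26, 0.16],
        ]
    )


@dataclass(frozen=True)
class SpectralProfile:
    """ICP-bin-conditional spectral recipe for the EEG generator.

    ``band_weights[b, k]`` is the relative variance of band ``k`` in ICP bin
    ``b`` (each row sums to 1); ``amplitude_scale[b]`` is the target RMS in
    uV for bin ``b``; ``pink_noise_fraction`` is the variance fraction of the
    1/f background shared by all bins.
    """

    band_weights: np.ndarray = field(default_factory=_default_band_weights)
    amplitude_scale: tuple[float, ...] = (32.5, 33.5, 37.5, 38.5, 41.5)
    pink_noise_fraction: float = 0.3

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (len(ICP_BIN_EDGES) + 1, len(BAND_NAMES)):
            raise ValueError(f"band_weights must have shape {(len(ICP_BIN_EDGES) + 1, len(BAND_NAMES))}")
        if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("band_weights rows must be non-negative and sum to 1")
        object.__setattr__(self, "band_weights", w)
        amp = tuple(float(a) for a in self.amplitude_scale)
        if len(amp) != w.shape[0] or any(a <= 0 for a in amp):
            raise ValueError("amplitude_scale must be positive, one value per ICP bin")
        object.__setattr__(self, "amplitude_scale", amp)
        if not 0.0 <= self.pink_noise_fraction <= 1.0:
            raise ValueError("pink_noise_fraction must be in [0, 1]")

    @classmethod
    def flat(cls, amplitude: float = 35.0) -> "SpectralProfile":
        """Null profile: identical spectrum and amplitude in every ICP bin.

        Removes every ICP-dependent EEG signature, so downstream classifiers
        should perform at chance.
        """
        w = np.tile(_default_band_weights()[0], (len(ICP_BIN_EDGES) + 1, 1))
        return cls(band_weights=w, amplitude_scale=(amplitude,) * (len(ICP_BIN_EDGES) + 1))


@dataclass
class SubjectRecord:
    """One simulated animal: raw EEG plus time-aligned hemodynamic traces."""

    subject_id: str
    eeg: np.ndarray  # uV at eeg_fs
    eeg_fs: float
    icp_trace: np.ndarray  # mmHg at hemo_fs
    map_trace: np.ndarray  # mmHg
    hr_trace: np.ndarray  # beats/min
    hemo_fs: float
    phase_annotations: list[tuple[str, float, float]]  # (label, start_s, end_s)

    def __post_init__(self) -> None:
        n = len(self.icp_trace)
        if len(self.map_trace) != n or len(self.hr_trace) != n:
            raise ValueError("hemodynamic traces must have equal length")
        # EEG and hemo durations must agree within one hemo sample
        if abs(len(self.eeg) / self.eeg_fs - n / self.hemo_fs) > 1.0 / self.hemo_fs + 1e-9:
            raise ValueError("EEG and hemodynamic trace durations are inconsistent")
        t = 0.0
        for label, start, end in self.phase_annotations:
            if abs(start - t) > 1e-9 or end <= start:
                raise ValueError("phase annotations must tile the record without overlap")
            t = end

    @property
    def duration(self) -> float:
        return len(self.eeg) / self.eeg_fs


# ---------------------------------------------------------------------------
# ICP / hemodynamics
# ---------------------------------------------------------------------------

def generate_icp_trace(
    config: ProtocolConfig, rng_seed: int
) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """Piecewise ICP trace (mmHg, at ``hemo_sampling_rate``) with annotations.

    Baseline fluctuates about ``baseline_icp_mean``; each injury step opens
    with a linear ramp (``ramp_duration`` s) from the previous level to the
    step target, then a plateau. Gaussian jitter (SD ``icp_jitter_sd``) is
    added throughout.
    """
    rng = np.random.default_rng(rng_seed)
    fs = config.hemo_sampling_rate
    segments: list[np.ndarray] = []
    phases: list[tuple[str, float, float]] = []

    n_base = int(round(config.baseline_duration * fs))
    segments.append(np.full(n_base, config.baseline_icp_mean))
    phases.append(("baseline", 0.0, config.baseline_duration))

    level = config.baseline_icp_mean
    t = config.baseline_duration
    n_step = int(round(config.injury_step_duration * fs))
    n_ramp = int(round(config.ramp_duration * fs))
    for i, target in enumerate(config.icp_targets, start=1):
        ramp = np.linspace(level, target, n_ramp, endpoint=False) if n_ramp else np.empty(0)
        plateau = np.full(n_step - n_ramp, float(target))
        segments.append(np.concatenate([ramp, plateau]))
        phases.append((f"injury_{i}", t, t + config.injury_step_duration))
        level = float(target)
        t += config.injury_step_duration

    icp = np.concatenate(segments)
    icp = icp + rng.normal(0.0, config.icp_jitter_sd, size=icp.size)
    return icp, phases


_HEMO_ANCHORS = {
    # Per-ICP-bin means the hemodynamic traces trend through (Cushing response).
    "map": (90.2, 91.6, 101.1, 103.0, 120.1),
    "hr": (96.1, 103.2, 104.9, 114.8, 134.8),
}


def _hemo_trace(icp: np.ndarray, anchors: tuple[float, ...], noise_sd: float,
                subject_offset: float, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(anchors)[icp_bin_index(icp)]
    return base + subject_offset + rng.normal(0.0, noise_sd, size=icp.size)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _band_sos(lo: float, hi: float, fs: float, order: int = 8):
    # steep skirts so an oscillator's power stays inside its nominal band
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _unit_band_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    x = sps.sosfiltfilt(_band_sos(lo, hi, fs), rng.standard_normal(n))
    return x / x.std()


def _unit_pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, band-limited to the 0.5-47 Hz acquisition band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    pink = np.fft.irfft(spec * scale, n=n)
    lo, hi = BAND_EDGES["delta"][0], BAND_EDGES["gamma"][1]
    pink = sps.sosfiltfilt(_band_sos(lo, hi, fs), pink)
    return pink / pink.std()


def generate_eeg(
    icp_trace: np.ndarray,
    profile: SpectralProfile,
    fs: float,
    rng_seed: int,
    hemo_fs: float = 10.0,
) -> np.ndarray:
    """Synthesize a uV EEG record whose spectrum tracks the concurrent ICP bin.

    The signal is ``A(t) * (sqrt(1-p) * sum_b sqrt(w_b(t)) * o_b(t)
    + sqrt(p) * pink(t))`` with unit-variance band oscillators ``o_b``, pink
    background fraction ``p``, and per-sample amplitude/weights looked up from
    the ICP bin active at that instant.
    """
    icp_trace = np.asarray(icp_trace, dtype=float)
    if icp_trace.size == 0:
        raise ValueError("icp_trace must be non-empty")
    if fs < 2.0 * BAND_EDGES["gamma"][1]:
        raise ValueError("fs too low to represent the gamma band")

    rng = np.random.default_rng(rng_seed)
    n = int(round(icp_trace.size / hemo_fs * fs))
    # ICP bin active at each EEG sample (zero-order hold of the hemo trace)
    hemo_idx = np.minimum((np.arange(n) / fs * hemo_fs).astype(np.intp), icp_trace.size - 1)
    bins = icp_bin_index(icp_trace)[hemo_idx]

    w = profile.band_weights[bins, :]  # (n, 5)
    amp = np.asarray(profile.amplitude_scale)[bins]
    p = profile.pink_noise_fraction

    mix = np.zeros(n)
    for k, name in enumerate(BAND_NAMES):
        lo, hi = BAND_EDGES[name]
        mix += np.sqrt(w[:, k]) * _unit_band_noise(n, lo, hi, fs, rng)
    mix *= np.sqrt(1.0 - p)
    if p > 0:
        mix += np.sqrt(p) * _unit_pink_noise(n, fs, rng)
    return amp * mix


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_subject(
    config: ProtocolConfig,
    profile: SpectralProfile,
    subject_id: str,
    rng_seed: int,
    amp_factor_sd: float = 0.15,
    weight_jitter_sd: float = 0.02,
) -> SubjectRecord:
    """One subject with log-normal amplitude and band-weight random effects."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(4) % (2**31)
    rng = np.random.default_rng(int(seeds[0]))

    # per-subject random effects
    amp_factor = float(np.exp(rng.normal(0.0, amp_factor_sd)))
    w = profile.band_weights + rng.normal(0.0, weight_jitter_sd, size=profile.band_weights.shape)
    w = np.clip(w, 0.01, None)
    w = w / w.sum(axis=1, keepdims=True)
    subj_profile = replace(
        profile,
        band_weights=w,
        amplitude_scale=tuple(a * amp_factor for a in profile.amplitude_scale),
    )

    icp, phases = generate_icp_trace(config, int(seeds[1]))
    eeg = generate_eeg(icp, subj_profile, config.eeg_sampling_rate, int(seeds[2]),
                       hemo_fs=config.hemo_sampling_rate)
    hemo_rng = np.random.default_rng(int(seeds[3]))
    map_trace = _hemo_trace(icp, _HEMO_ANCHORS["map"], 5.0, hemo_rng.normal(0.0, 5.0), hemo_rng)
    hr_trace = _hemo_trace(icp, _HEMO_ANCHORS["hr"], 5.0, hemo_rng.normal(0.0, 6.0), hemo_rng)
    return SubjectRecord(
        subject_id=subject_id,
        eeg=eeg,
        eeg_fs=config.eeg_sampling_rate,
        icp_trace=icp,
        map_trace=map_trace,
        hr_trace=hr_trace,
        hemo_fs=config.hemo_sampling_rate,
        phase_annotations=phases,
    )


def generate_cohort(
    config: ProtocolConfig,
    profile: SpectralProfile | None = None,
    rng_seed: int | None = None,
) -> list[SubjectRecord]:
    """Generate ``config.n_subjects`` subjects with independent child seeds."""
    if profile is None:
        profile = SpectralProfile()
    master = config.seed if rng_seed is None else rng_seed
    child_seeds = np.random.SeedSequence(master).generate_state(config.n_subjects) % (2**31)
    return [
        generate_subject(config, profile, f"pig{i + 1:02d}", int(child_seeds[i]))
        for i in range(config.n_subjects)
    ]


def write_cohort(cohort: list[SubjectRecord], outdir) -> "pd.DataFrame":
    """Write per-subject EDF + trace CSV files and a cohort manifest CSV.

    Returns the manifest frame (subject_id, edf_path, trace_path).
    """
    import pandas as pd
    from pathlib import Path

    from ._edf import write_edf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        edf_path = outdir / f"{rec.subject_id}.edf"
        trace_path = outdir / f"{rec.subject_id}_traces.csv"
        write_edf(edf_path, rec.eeg, rec.eeg_fs, label="EEG", physical_dim="uV")
        t = np.arange(len(rec.icp_trace)) / rec.hemo_fs
        phase = np.empty(t.size, dtype=object)
        for label, start, end in rec.phase_annotations:
            phase[(t >= start) & (t < end)] = label
        pd.DataFrame(
            {
                "time_s": t,
                "icp_mmhg": rec.icp_trace,
                "map_mmhg": rec.map_trace,
                "hr_bpm": rec.hr_trace,
                "phase": phase,
            }
        ).to_csv(trace_path, index=False)
        rows.append({"subject_id": rec.subject_id, "edf_path": edf_path.name,
                     "trace_path": trace_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
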