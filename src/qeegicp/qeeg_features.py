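"""Quantitative EEG feature bank: time, frequency and entropy domain indices.

Every operation accepts a single epoch (1-D) or a stack of epochs (2-D,
epochs in rows) and is vectorised over the leading axis. The ten indices
retained by the selection stage downstream are: EEG magnitude (RMS), DELTAR,
DTABR, THETAPR, GAMMAPR, log energy entropy, and the band-limited standard
deviations SD_theta/alpha/beta/gamma. A wider candidate bank (relative band
powers, spectral entropy, line length, zero-crossing rate, Hjorth mobility
and complexity) gives the selection stage a realistic pool to rank.

Definitions of the ratio indices (the source nomenclature does not pin them
down; these forms reproduce the observed signs and magnitudes):

- THETAPR = P_theta / P_total,  GAMMAPR = P_gamma / P_total
- DTABR   = log10((P_delta + P_theta) / (P_alpha + P_beta))
- DELTAR  = log10(P_delta / (P_theta + P_alpha + P_beta + P_gamma))

with P_total the 0.5-47 Hz power and all band powers floored at
``1e-12 * P_total`` before ratios are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EpochTable

__all__ = [
    "BandDefinition",
    "FEATURE_REGISTRY",
    "SELECTED_TEN",
    "power_spectrum",
    "band_powers",
    "ratio_features",
    "time_domain_features",
    "log_energy_entropy",
    "spectral_entropy",
    "extract_feature_table",
]

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """Contiguous, non-overlapping frequency bands within the filter passband."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 47.0),
    )

    def __post_init__(self) -> None:
        for (_, lo, hi), (_, lo2, _hi2) in zip(self.bands, self.bands[1:]):
            if hi != lo2 or lo >= hi:
                raise ValueError("bands must be contiguous and increasing")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def total_range(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][2]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


def power_spectrum(
    x: np.ndarray, fs: float, method: str = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density of an epoch (Welch: 1-s Hann segments, 50% overlap).

    Satisfies Parseval within the leakage of the window: the integral of the
    density approximates the signal variance.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty epoch")
    if x.shape[-1] < fs:
        raise ValueError("need at least 1 s of samples for the spectrum")
    if method == "welch":
        nperseg = int(round(fs))
        return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2, detrend="constant", axis=-1)
    if method == "periodogram":
        return sps.periodogram(x, fs=fs, window="hann", detrend="constant", axis=-1)
    raise ValueError(f"unknown spectral method {method!r}")


def band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: BandDefinition = BandDefinition(),
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Absolute and relative power per band.

    Bands are integrated over half-open frequency intervals ``[lo, hi)``;
    total power is the full band span (0.5-47 Hz by default), so the five
    relative powers sum to exactly 1.
    """
    freqs = np.asarray(freqs)
    psd = np.asarray(psd, dtype=float)
    lo_all, hi_all = bands.total_range
    if freqs[0] > lo_all or freqs[-1] < hi_all - 1e-9:
        raise ValueError("spectrum does not cover the requested band range")
    df = freqs[1] - freqs[0]
    power: dict[str, np.ndarray] = {}
    for name, lo, hi in bands.bands:
        mask = (freqs >= lo) & (freqs < hi)
        power[name] = psd[..., mask].sum(axis=-1) * df
    total = sum(power.values())
    total = np.where(total > 0, total, np.nan)
    relative = {name: p / total for name, p in power.items()}
    return power, relative


def ratio_features(power: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """DELTAR, DTABR, THETAPR, GAMMAPR from absolute band powers."""
    total = sum(np.asarray(power[n], dtype=float) for n in power)
    if np.any(total <= 0):
        raise ValueError("all-zero epoch: band powers are zero")
    floor = _LOG_EPS * total
    p = {n: np.maximum(np.asarray(power[n], dtype=float), floor) for n in power}
    return {
        "deltar": np.log10(p["delta"] / (p["theta"] + p["alpha"] + p["beta"] + p["gamma"])),
        "dtabr": np.log10((p["delta"] + p["theta"]) / (p["alpha"] + p["beta"])),
        "thetapr": p["theta"] / total,
        "gammapr": p["gamma"] / total,
    }


def _band_sd(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1).std(axis=-1)


def time_domain_features(
    x: np.ndarray, fs: float, bands: BandDefinition = BandDefinition()
) -> dict[str, np.ndarray]:
    """RMS magnitude and per-band standard deviations (uV).

    ``sd_<band>`` is the standard deviation of the epoch after a zero-phase
    band-pass restricted to that band.
    """
    x = np.asarray(x, dtype=float)
    out = {"magnitude": np.sqrt(np.mean(x**2, axis=-1))}
    for name in bands.names:
        lo, hi = bands.edges(name)
        out[f"sd_{name}"] = _band_sd(x, fs, lo, hi)
    return out


def log_energy_entropy(x: np.ndarray) -> np.ndarray:
    """Log energy entropy: sum_i ln(x_i^2 + 1e-12) over the epoch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty epoch")
    return np.sum(np.log(x**2 + _LOG_EPS), axis=-1)


def spectral_entropy(relative: dict[str, np.ndarray]) -> np.ndarray:
    """Shannon entropy (nats) of the five-band relative power distribution."""
    ps = np.stack([np.asarray(relative[n], dtype=float) for n in relative])
    ps = np.clip(ps, _LOG_EPS, None)
    return -(ps * np.log(ps)).sum(axis=0)


def _line_length(x: np.ndarray) -> np.ndarray:
    return np.abs(np.diff(x, axis=-1)).sum(axis=-1)


def _zero_crossing_rate(x: np.ndarray) -> np.ndarray:
    signs = np.signbit(x)
    return (signs[..., 1:] != signs[..., :-1]).mean(axis=-1)


def _hjorth(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(x, axis=-1)
    ddx = np.diff(dx, axis=-1)
    var = x.var(axis=-1)
    var_d = dx.var(axis=-1)
    var_dd = ddx.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.sqrt(np.where(var > 0, var_d / np.maximum(var, _LOG_EPS), 0.0))
        mob_d = np.sqrt(np.where(var_d > 0, var_dd / np.maximum(var_d, _LOG_EPS), 0.0))
        complexity = np.where(mobility > 0, mob_d / np.maximum(mobility, _LOG_EPS), 0.0)
    return mobility, complexity


#: The ten indices reported across ICP bins, in registry order, followed by
#: the wider candidate bank.
SELECTED_TEN: tuple[str, ...] = (
    "magnitude", "deltar", "dtabr", "thetapr", "gammapr",
    "log_energy_entropy", "sd_theta", "sd_alpha", "sd_beta", "sd_gamma",
)
FEATURE_REGISTRY: tuple[str, ...] = SELECTED_TEN + (
    "sd_delta",
    "relpow_delta", "relpow_theta", "relpow_alpha", "relpow_beta", "relpow_gamma",
    "spectral_entropy", "line_length", "zero_crossing_rate",
    "hjorth_mobility", "hjorth_complexity",
)

_META_COLUMNS = ("subject_id", "start_s", "phase", "mean_icp", "mean_map",
                 "mean_hr", "iicp_label")


def _compute_bank(x: np.ndarray, fs: float, bands: BandDefinition,
                  method: str) -> dict[str, np.ndarray]:
    freqs, psd = power_spectrum(x, fs, method=method)
    power, relative = band_powers(freqs, psd, bands)
    feats: dict[str, np.ndarray] = {}
    feats.update(ratio_features(power))
    feats.update(time_domain_features(x, fs, bands))
    feats["log_energy_entropy"] = log_energy_entropy(x)
    for name in bands.names:
        feats[f"relpow_{name}"] = np.asarray(relative[name], dtype=float)
    feats["spectral_entropy"] = spectral_entropy(relative)
    feats["line_length"] = _line_length(x)
    feats["zero_crossing_rate"] = _zero_crossing_rate(x)
    feats["hjorth_mobility"], feats["hjorth_complexity"] = _hjorth(x)
    return feats


def extract_feature_table(
    table: EpochTable,
    bands: BandDefinition = BandDefinition(),
    bank: tuple[str, ...] = FEATURE_REGISTRY,
    spectral_method: str = "welch",
) -> pd.DataFrame:
    """One row per epoch: metadata columns then feature columns in bank order."""
    unknown = [f for f in bank if f not in FEATURE_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown features {unknown}; known features: {list(FEATURE_REGISTRY)}"
        )
    feats = _compute_bank(np.atleast_2d(table.samples), table.fs, bands, spectral_method)
    out = table.frame.loc[:, [c for c in _META_COLUMNS if c in table.frame.columns]].copy()
    for name in bank:
        out[name] = feats[name]
    return out
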