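"""Filtering, bad-channel detection, and burst rejection.

The cleaning chain mirrors a standard resting/auditory EEG pipeline:

1. zero-phase band-pass (Butterworth order 6, 0.1-30 Hz by default);
2. channel rejection on three criteria — flat for more than 5 s,
   high-frequency noise z-score above 4, maximum correlation with the
   other channels below 0.8;
3. rejection of bad data periods whose amplitude exceeds 20 times the
   standard deviation of the calibration (quietest) data.

Step 3 is a window-RMS thresholder sharing Artifact Subspace
Reconstruction's calibration idea and its 20-SD cutoff, not a subspace
reconstruction: windows are masked, never repaired.  Independent-component
rejection is intentionally out of scope; the pipeline accepts pre-cleaned
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import RawRecording

__all__ = [
    "ChannelQualityReport",
    "BurstMask",
    "bandpass_filter",
    "detect_bad_channels",
    "reject_burst_segments",
]


@dataclass
class ChannelQualityReport:
    """Per-channel quality flags with the statistics behind them."""

    table: pd.DataFrame  # channel, flat, hf_noise, low_correlation, flagged + stats

    @property
    def flagged_channels(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "channel"])


@dataclass
class BurstMask:
    """Boolean per-sample mask of rejected periods (True = rejected)."""

    mask: np.ndarray
    calibration_sd: np.ndarray  # per channel
    threshold_k: float

    @property
    def fraction_rejected(self) -> float:
        return float(self.mask.mean())


def bandpass_filter(
    rec: RawRecording, low: float = 0.1, high: float = 30.0, order: int = 6
) -> RawRecording:
    """Zero-phase Butterworth band-pass; output length equals input length.

    The filter is applied forward and backward (``filtfilt``), so the
    effective magnitude response is the squared Butterworth response and
    phase distortion cancels.  Edge transients are handled by ``filtfilt``'s
    reflective padding (3 x filter order worth of samples).
    """
    nyq = rec.fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < fs/2; got ({low}, {high}) at fs={rec.fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=1, padtype="even", padlen=3 * order)
    return RawRecording(filtered, rec.fs, list(rec.channel_names), rec.events.copy())


def _flat_run_seconds(x: np.ndarray, fs: float, tol: float = 1e-12) -> float:
    """Longest constant run, in seconds."""
    dx = np.abs(np.diff(x)) <= tol
    if not dx.any():
        return 1.0 / fs
    # runs of True in dx of length L mean L+1 equal samples
    padded = np.concatenate([[False], dx, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    run_lengths = edges[1::2] - edges[0::2]
    return float((run_lengths.max() + 1) / fs)


def detect_bad_channels(
    rec: RawRecording,
    flat_seconds: float = 5.0,
    hf_sd_threshold: float = 4.0,
    min_correlation: float = 0.8,
    hf_band: tuple[float, float] = (15.0, 30.0),
) -> ChannelQualityReport:
    """Flag channels that are flat, noisy at high frequency, or uncorrelated.

    High-frequency noise is operationalized as the standard deviation of the
    channel's ``hf_band`` component, expressed as a robust z-score
    (median/MAD) against the other channels, flagged above
    ``hf_sd_threshold``.  The correlation criterion compares each channel's
    best Pearson correlation with any other channel against
    ``min_correlation`` ("nearby" defaults to all channels; pass a montage
    subset by slicing the recording first).
    """
    if rec.n_channels < 2:
        raise ValueError("correlation criterion needs at least 2 channels")
    x = rec.samples
    fs = rec.fs

    flat_runs = np.array([_flat_run_seconds(ch, fs) for ch in x])
    flat = flat_runs > flat_seconds

    lo, hi = hf_band
    hi = min(hi, 0.99 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    hf_sd = sps.sosfiltfilt(sos, x, axis=1).std(axis=1)
    med = np.median(hf_sd)
    mad = np.median(np.abs(hf_sd - med)) * 1.4826  # normal-consistent MAD
    if mad == 0:
        mad = med if med > 0 else 1.0
    hf_z = (hf_sd - med) / mad
    hf_noise = hf_z > hf_sd_threshold

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    np.fill_diagonal(corr, -np.inf)
    corr = np.nan_to_num(corr, nan=0.0, neginf=-np.inf)
    max_corr = corr.max(axis=1)
    low_corr = max_corr < min_correlation

    flagged = flat | hf_noise | low_corr
    table = pd.DataFrame(
        {
            "channel": rec.channel_names,
            "flat": flat,
            "hf_noise": hf_noise,
            "low_correlation": low_corr,
            "flagged": flagged,
            "flat_run_s": flat_runs,
            "hf_noise_z": hf_z,
            "max_neighbor_corr": max_corr,
        }
    )
    return ChannelQualityReport(table=table)


def reject_burst_segments(
    rec: RawRecording, k: float = 20.0, window_s: float = 0.5
) -> tuple[RawRecording, BurstMask]:
    """Mask windows whose RMS strictly exceeds ``k`` x the calibration SD.

    Calibration SD is computed per channel over the quietest quartile of
    windows (by RMS), emulating artifact-subspace calibration on clean data.
    The recording itself is returned unmodified (masking, not repair); the
    mask marks samples to exclude from epoching.
    """
    win = int(round(window_s * rec.fs))
    if win < 1 or rec.n_times < win:
        raise ValueError("recording shorter than one rejection window")
    n_win = rec.n_times // win
    x = rec.samples[:, : n_win * win].reshape(rec.n_channels, n_win, win)
    rms = np.sqrt((x**2).mean(axis=2))  # channels x windows

    # quietest quartile of windows per channel -> calibration SD
    n_calib = max(1, n_win // 4)
    order = np.argsort(rms, axis=1)[:, :n_calib]
    calib_sd = np.empty(rec.n_channels)
    for c in range(rec.n_channels):
        calib = x[c, order[c]].ravel()
        calib_sd[c] = calib.std()
    if np.all(calib_sd == 0):
        raise ValueError("no calibratable data: all calibration windows are constant")

    exceeded = rms > k * calib_sd[:, None]  # strict: 'exceeded' k x SD
    bad_windows = exceeded.any(axis=0)
    mask = np.zeros(rec.n_times, dtype=bool)
    for w in np.flatnonzero(bad_windows):
        mask[w * win : (w + 1) * win] = True
    if bad_windows.all():
        raise ValueError("no calibratable data: every window exceeds threshold")
    return rec, BurstMask(mask=mask, calibration_sd=calib_sd, threshold_k=k)
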