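"""Event-locked time-frequency (ERD/ERS) mapping.

Epochs are cut around keypress events (500 ms before to 1 s after), each
epoch is transformed with a continuous wavelet transform using the complex
Gaussian family

    f(x) = C_p d^p/dx^p [ exp(-i x) exp(-x^2) ],

with C_p chosen so the p-th derivative has unit L2 norm.  Being built on a
complex exponential the family is analytic, so |coefficients| are
shift-invariant power estimates.  Per-epoch coefficient matrices are
averaged and rectified into a time x frequency power map P(t, f), and
baseline-corrected by subtracting the per-frequency mean over the
pre-event window (-400 to -100 ms):

    BC(t, f) = P(t, f) - R̄(f).

Positive corrected values are event-related synchronization (ERS),
negative ones desynchronization (ERD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .io import RawRecording
from .preprocess import BurstMask

__all__ = [
    "EpochSet",
    "CGauWavelet",
    "TFMap",
    "extract_epochs",
    "make_cgau_wavelet",
    "cwt_epoch",
    "average_and_rectify",
    "baseline_correct",
    "default_freq_grid",
    "render_scalogram",
    "band_mean",
]


# ---------------------------------------------------------------------------
# epoching


@dataclass
class EpochSet:
    """Fixed-length single-channel windows time-locked to keypress events."""

    epochs: np.ndarray  # (n_epochs, n_times)
    fs: float
    t_axis: np.ndarray  # seconds relative to the event, t=0 at the keypress
    labels: list[str]
    n_dropped: int = 0
    channel: str = "Fz"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def extract_epochs(
    rec: RawRecording,
    channel: str = "Fz",
    tmin: float = -0.5,
    tmax: float = 1.0,
    burst_mask: BurstMask | None = None,
) -> EpochSet:
    """Cut [tmin, tmax) windows around each event on one channel.

    The window in samples is half-open:
    ``[round(onset*fs) - round(|tmin|*fs), round(onset*fs) + round(tmax*fs))``.
    Events whose window leaves the recording or touches a masked burst
    period are dropped and counted in ``n_dropped``.
    """
    if len(rec.events) == 0:
        raise ValueError("recording has no events to epoch")
    ci = rec.channel_index(channel)
    x = rec.samples[ci]
    fs = rec.fs
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    n_len = n_pre + n_post
    t_axis = (np.arange(n_len) - n_pre) / fs

    mask = burst_mask.mask if burst_mask is not None else None
    epochs, labels, dropped = [], [], 0
    for onset, label in zip(rec.events["onset_s"], rec.events["label"]):
        center = int(round(onset * fs))
        start, stop = center - n_pre, center + n_post
        if start < 0 or stop > x.size:
            dropped += 1
            continue
        if mask is not None and mask[start:stop].any():
            dropped += 1
            continue
        epochs.append(x[start:stop])
        labels.append(str(label))
    if not epochs:
        raise ValueError("zero usable events after boundary/burst exclusion")
    return EpochSet(
        epochs=np.asarray(epochs),
        fs=fs,
        t_axis=t_axis,
        labels=labels,
        n_dropped=dropped,
        channel=channel,
    )


# ---------------------------------------------------------------------------
# complex Gaussian wavelet


def _cgau_poly(p: int) -> np.ndarray:
    """Coefficients (ascending) of the complex polynomial P_p with
    d^p/dx^p [e^{-ix-x^2}] = P_p(x) e^{-ix-x^2}.

    Recurrence: P_{p+1} = P_p' + (-i - 2x) P_p.
    """
    poly = np.array([1.0 + 0.0j])
    for _ in range(p):
        deriv = poly[1:] * np.arange(1, poly.size)
        term = np.zeros(poly.size + 1, dtype=complex)
        term[:-1] += -1j * poly
        term[1:] += -2.0 * poly
        nxt = term
        nxt[: deriv.size] += deriv
        poly = nxt
    return poly


@dataclass
class CGauWavelet:
    """Sampled p-th derivative complex Gaussian mother wavelet, unit energy."""

    p: int
    x: np.ndarray
    values: np.ndarray
    norm_constant: float  # C_p
    center_frequency: float = field(init=False)  # cycles per unit x

    def __post_init__(self) -> None:
        dx = self.x[1] - self.x[0]
        spectrum = np.abs(np.fft.fft(self.values))
        freqs = np.fft.fftfreq(self.x.size, d=dx)
        self.center_frequency = float(abs(freqs[int(np.argmax(spectrum))]))

    def l2_norm(self) -> float:
        """Numerically integrated L2 norm (trapezoid) of the sampled wavelet."""
        return float(np.sqrt(np.trapezoid(np.abs(self.values) ** 2, self.x)))

    def sample(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the normalized wavelet on an arbitrary grid."""
        return _cgau_eval(self.p, x) * self.norm_constant


def _cgau_eval(p: int, x: np.ndarray) -> np.ndarray:
    poly = _cgau_poly(p)
    # Horner with ascending coefficients, evaluated highest-first
    px = np.zeros(x.shape, dtype=complex)
    for c in poly[::-1]:
        px = px * x + c
    return px * np.exp(-1j * x - x**2)


def make_cgau_wavelet(
    p: int, support: tuple[float, float] = (-8.0, 8.0), n_points: int = 2**14
) -> CGauWavelet:
    """Build the order-``p`` complex Gaussian wavelet, normalized to unit energy.

    The derivative is taken in closed form via the polynomial recurrence for
    Gaussian-times-complex-exponential products, then C_p is fixed so the
    numerically integrated L2 norm over ``support`` equals 1.
    """
    if not (isinstance(p, (int, np.integer)) and p >= 1):
        raise ValueError(f"derivative order p must be an integer >= 1, got {p!r}")
    x = np.linspace(support[0], support[1], n_points)
    raw = _cgau_eval(p, x)
    norm = np.sqrt(np.trapezoid(np.abs(raw) ** 2, x))
    c_p = 1.0 / norm
    return CGauWavelet(p=int(p), x=x, values=raw * c_p, norm_constant=float(c_p))


# ---------------------------------------------------------------------------
# CWT


def default_freq_grid(
    n: int = 60, f_min: float = 0.5, f_max: float = 30.0, spacing: str = "log"
) -> np.ndarray:
    """Analysis frequency grid.

    Defaults to 60 log-spaced frequencies in [0.5, 30] Hz.  ``spacing="linear"``
    reaches arbitrarily low frequencies (e.g. 0.1 Hz), but with 1.5 s epochs
    anything below ~0.7 Hz is under-resolved — the maps show it anyway.
    """
    if spacing == "log":
        return np.geomspace(f_min, f_max, n)
    if spacing == "linear":
        return np.linspace(f_min, f_max, n)
    raise ValueError(f"unknown spacing {spacing!r}")


def cwt_epoch(
    epoch: np.ndarray,
    freqs: np.ndarray,
    wavelet: CGauWavelet,
    fs: float,
    support_halfwidth: float = 6.0,
) -> np.ndarray:
    """Continuous wavelet transform of one epoch.

    W(b, f) = (1/sqrt(s)) Σ_t x(t) conj(ψ((t-b)/s)) Δt with s = f_c / f,
    where f_c is the wavelet's spectral-peak frequency measured from its
    FFT.  The epoch is reflect-padded by one wavelet support per scale so
    edge samples see a full kernel.  Returns complex (n_times, n_freqs).
    """
    epoch = np.asarray(epoch, dtype=float).ravel()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if (freqs <= 0).any() or (freqs > fs / 2).any():
        raise ValueError(f"frequencies must lie in (0, fs/2] = (0, {fs / 2}]")
    dt = 1.0 / fs
    n = epoch.size
    out = np.empty((n, freqs.size), dtype=complex)
    for j, f in enumerate(freqs):
        s = wavelet.center_frequency / f
        half = int(np.ceil(support_halfwidth * s / dt))
        k = np.arange(-half, half + 1)
        kernel = np.conj(wavelet.sample(k * dt / s)) * (dt / np.sqrt(s))
        pad = min(half, n - 1)
        padded = np.pad(epoch, pad, mode="reflect")
        # correlation with the kernel == convolution with its reverse
        conv = fftconvolve(padded, kernel[::-1], mode="same")
        out[:, j] = conv[pad : pad + n]
    return out


# ---------------------------------------------------------------------------
# averaging, rectification, baseline correction


@dataclass
class TFMap:
    """Time x frequency power map with optional baseline correction."""

    P: np.ndarray  # (n_times, n_freqs), real
    freqs: np.ndarray
    t_axis: np.ndarray
    baseline: np.ndarray | None = None  # R̄(f), set by baseline_correct
    corrected: bool = False
    mode: str = "average_then_abs"

    def __post_init__(self) -> None:
        if not np.isfinite(self.P).all():
            raise ValueError("TFMap contains non-finite values")


def average_and_rectify(
    coeffs: list[np.ndarray] | np.ndarray,
    t_axis: np.ndarray,
    freqs: np.ndarray,
    mode: str = "average_then_abs",
) -> TFMap:
    """Collapse per-epoch CWT coefficient matrices into one power map.

    ``average_then_abs`` (default) averages the complex coefficients across
    epochs then rectifies — phase-inconsistent (induced) activity partially
    cancels.  ``abs_then_average`` rectifies each epoch first, keeping
    induced power.  With a single epoch or identical epochs the two agree.
    """
    stack = np.asarray(coeffs)
    if stack.ndim != 3:
        raise ValueError("need a stack of per-epoch coefficient matrices")
    if stack.shape[0] < 1:
        raise ValueError("need at least one epoch")
    if mode == "average_then_abs":
        P = np.abs(stack.mean(axis=0))
    elif mode == "abs_then_average":
        P = np.abs(stack).mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TFMap(P=P, freqs=np.asarray(freqs), t_axis=np.asarray(t_axis), mode=mode)


def baseline_correct(tfmap: TFMap, window: tuple[float, float] = (-0.4, -0.1)) -> TFMap:
    """Subtract the per-frequency mean power over the pre-event window.

    Window endpoints are converted to the nearest time samples and included.
    Correcting an already-corrected map raises.
    """
    if tfmap.corrected:
        raise ValueError("map is already baseline-corrected")
    t = tfmap.t_axis
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"baseline window {window} outside epoch [{t[0]}, {t[-1]}]")
    i0 = int(np.argmin(np.abs(t - lo)))
    i1 = int(np.argmin(np.abs(t - hi)))
    baseline = tfmap.P[i0 : i1 + 1].mean(axis=0)
    return TFMap(
        P=tfmap.P - baseline[None, :],
        freqs=tfmap.freqs,
        t_axis=tfmap.t_axis,
        baseline=baseline,
        corrected=True,
        mode=tfmap.mode,
    )


def compute_tfmap(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    p: int = 4,
    mode: str = "average_then_abs",
    baseline_window: tuple[float, float] | None = (-0.4, -0.1),
) -> TFMap:
    """Epochs -> (optionally baseline-corrected) ERD/ERS map, in one call."""
    if freqs is None:
        freqs = default_freq_grid()
    wavelet = make_cgau_wavelet(p)
    coeffs = [cwt_epoch(e, freqs, wavelet, epochs.fs) for e in epochs.epochs]
    tfm = average_and_rectify(coeffs, epochs.t_axis, freqs, mode=mode)
    if baseline_window is not None:
        tfm = baseline_correct(tfm, baseline_window)
    return tfm


def band_mean(
    tfmap: TFMap, f_band: tuple[float, float], t_window: tuple[float, float]
) -> float:
    """Mean map value over a frequency band x time window (ERS if > 0)."""
    fsel = (tfmap.freqs >= f_band[0]) & (tfmap.freqs <= f_band[1])
    tsel = (tfmap.t_axis >= t_window[0]) & (tfmap.t_axis < t_window[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band or window selection")
    return float(tfmap.P[np.ix_(tsel, fsel)].mean())


# ---------------------------------------------------------------------------
# scalogram rendering


def render_scalogram(
    tfmap: TFMap,
    out_path: str | Path | None = None,
    canvas_size: tuple[int, int] = (1200, 900),
    out_size: tuple[int, int] = (160, 160),
    colormap: str = "viridis",
) -> np.ndarray:
    """Render a map as a color scalogram image.

    The map (frequency on the vertical axis, low at the bottom; time on the
    horizontal) is min-max normalized, colored with a fixed colormap, drawn
    at ``canvas_size`` (width x height) and bilinearly resized to
    ``out_size``.  If ``out_path`` is given, both PNGs plus a JSON metadata
    sidecar (vmin/vmax/colormap) are written; returns the resized
    uint8 RGB array.  Same map in, byte-identical PNG out.
    """
    from matplotlib import colormaps
    from PIL import Image

    P = tfmap.P
    if not np.isfinite(P).all():
        raise ValueError("cannot render non-finite map")
    vmin, vmax = float(P.min()), float(P.max())
    span = vmax - vmin if vmax > vmin else 1.0
    normed = (P - vmin) / span
    # rows = frequency (descending so low freq sits at the bottom), cols = time
    grid = normed.T[::-1]
    rgba = colormaps[colormap](grid)
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    canvas = Image.fromarray(rgb).resize(canvas_size, Image.BILINEAR)
    resized = canvas.resize(out_size, Image.BILINEAR)
    out = np.asarray(resized)
    if out_path is not None:
        out_path = Path(out_path)
        canvas.save(out_path.with_suffix(".full.png"))
        resized.save(out_path)
        meta = {
            "vmin": vmin,
            "vmax": vmax,
            "colormap": colormap,
            "canvas_size": list(canvas_size),
            "out_size": list(out_size),
            "corrected": bool(tfmap.corrected),
        }
        import json

        out_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return out


def write_tfmap_csv(tfmap: TFMap, path: str | Path) -> Path:
    """Serialize a map as CSV (frequency rows x time columns) + sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        tfmap.P.T, index=np.round(tfmap.freqs, 6), columns=np.round(tfmap.t_axis, 6)
    )
    df.index.name = "freq_hz"
    df.to_csv(path)
    return path
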