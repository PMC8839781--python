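"""Synthetic EEG cohorts and labeled scalogram-image fixtures.

The generator emulates the structure of a two-group (tinnitus / control),
two-session (S1 before / S2 after an 8-week sound therapy) auditory
recognition study: 16-channel, 256 Hz recordings in which a participant
hears 5 stimuli x 50 repetitions of 1 s sounds and presses a key on each
recognition.  Each keypress event is followed, on every channel, by
band-limited oscillatory bursts (Hann-windowed sinusoids) riding on 1/f
background noise — the event-related synchronization (ERS) the downstream
time-frequency mapping is meant to recover.

The default effect profile follows the qualitative group pattern such a
study reports: controls show alpha-band ERS in both sessions; the tinnitus
group lacks it before treatment (showing instead late 25-30 Hz activity)
and gains it after treatment.  Reaction times are broad (0-1 s) in S1 and
narrow (0-0.5 s) in S2 for both groups.

Everything is deterministic given the master seed: each recording draws
from its own RNG stream spawned from (group, session, subject), so
regenerating one cell never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RawRecording

__all__ = [
    "ErsBurst",
    "ReactionTimeModel",
    "CohortConfig",
    "SyntheticTruth",
    "generate_recording",
    "generate_cohort",
    "generate_scalogram_fixtures",
    "write_scalogram_fixtures",
    "DEFAULT_CHANNELS",
    "GROUPS",
    "SESSIONS",
]

GROUPS = ("tinnitus", "control")
SESSIONS = ("S1", "S2")

# 10-20 montage actually used: 16 channels referenced at Cz
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "T4", "T5", "T6", "C3", "C4", "Pz", "O1", "O2",
]

# default scalogram-image class sizes: tinnitus S1/S2, control S1/S2
DEFAULT_CLASS_SIZES = (801, 667, 500, 500)
FIXTURE_CLASSES = (
    ("tinnitus", "S1"),
    ("tinnitus", "S2"),
    ("control", "S1"),
    ("control", "S2"),
)


@dataclass(frozen=True)
class ErsBurst:
    """One injected event-locked oscillatory response.

    Hann-windowed sinusoid at ``f_center`` Hz (uniform in
    [f_low, f_high] would smear the band; a fixed center with the Hann
    envelope's spectral width keeps the burst inside the nominal band),
    starting ``onset_s`` after the keypress and lasting ``duration_s``.
    """

    f_low: float
    f_high: float
    amplitude_uv: float
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"need 0 < f_low < f_high, got {self.f_low}, {self.f_high}")
        if self.amplitude_uv < 0:
            raise ValueError("burst amplitude must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("burst duration must be positive")

    @property
    def f_center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


@dataclass(frozen=True)
class ReactionTimeModel:
    """Uniform reaction-time distribution with hard bounds (seconds)."""

    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError("reaction-time bounds need 0 <= low < high")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


def _default_ers_profile() -> dict[tuple[str, str], list[ErsBurst]]:
    alpha = ErsBurst(f_low=8.0, f_high=13.0, amplitude_uv=4.0, onset_s=0.0, duration_s=0.5)
    late_beta = ErsBurst(f_low=25.0, f_high=30.0, amplitude_uv=3.0, onset_s=0.5, duration_s=0.4)
    return {
        ("tinnitus", "S1"): [late_beta],
        ("tinnitus", "S2"): [alpha],
        ("control", "S1"): [alpha],
        ("control", "S2"): [alpha],
    }


def _default_rt_models() -> dict[tuple[str, str], ReactionTimeModel]:
    # S1: dispersed responses over the full stimulus second;
    # S2: practice narrows the range to the first half second.
    return {
        (g, s): ReactionTimeModel(0.0, 1.0 if s == "S1" else 0.5)
        for g in GROUPS
        for s in SESSIONS
    }


@dataclass
class CohortConfig:
    """Study-level generator configuration (defaults mirror the protocol)."""

    n_subjects_per_group: int = 5
    fs: float = 256.0
    n_channels: int = 16
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    n_stimuli: int = 5
    reps_per_stimulus: int = 50
    stimulus_duration: float = 1.0
    isi_range: tuple[float, float] = (2.0, 3.0)
    reaction_time_model: dict[tuple[str, str], ReactionTimeModel] = field(
        default_factory=_default_rt_models
    )
    ers_bands: dict[tuple[str, str], list[ErsBurst]] = field(
        default_factory=_default_ers_profile
    )
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    line_noise_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.reps_per_stimulus < 1:
            raise ValueError("reps_per_stimulus must be >= 1")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if not 0 < self.isi_range[0] <= self.isi_range[1]:
            raise ValueError("isi_range must satisfy 0 < min <= max")
        nyquist = self.fs / 2
        for bursts in self.ers_bands.values():
            for b in bursts:
                if b.f_high > nyquist:
                    raise ValueError(
                        f"burst band [{b.f_low}, {b.f_high}] exceeds Nyquist {nyquist} Hz"
                    )

    @property
    def n_events(self) -> int:
        return self.n_stimuli * self.reps_per_stimulus

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth for one recording: what was injected, where."""

    group: str
    session: str
    subject: int
    event_times: np.ndarray  # keypress times, s, strictly increasing
    bursts: pd.DataFrame  # columns: event_s, f_low, f_high, f_center, amplitude_uv, onset_s, duration_s


def _recording_rng(config: CohortConfig, group: str, session: str, subject: int) -> np.random.Generator:
    """One independent stream per (group, session, subject) cell member."""
    key = (GROUPS.index(group), SESSIONS.index(session), subject)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int, fs: float,
                exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shape, n=n_times, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * shaped / sd


def _hann_burst(fs: float, f_center: float, amplitude: float, duration: float,
                phase: float) -> np.ndarray:
    n = max(int(round(duration * fs)), 2)
    t = np.arange(n) / fs
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))
    return amplitude * envelope * np.sin(2.0 * np.pi * f_center * t + phase)


def generate_recording(
    config: CohortConfig, group: str, session: str, subject: int = 0
) -> tuple[RawRecording, SyntheticTruth]:
    """Simulate one subject's session.

    The event table holds one keypress per stimulus repetition, at stimulus
    onset plus a sampled reaction time.  Every injected burst is recorded in
    the returned :class:`SyntheticTruth`.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}, got {session!r}")
    rng = _recording_rng(config, group, session, subject)
    fs = config.fs
    n_events = config.n_events

    rt_model = config.reaction_time_model.get((group, session), ReactionTimeModel())
    bursts_cfg = config.ers_bands.get((group, session), [])
    max_burst_end = max((b.onset_s + b.duration_s for b in bursts_cfg), default=0.0)

    # stimulus onsets: lead-in, then stimulus + ISI gaps
    lead_in = 2.0
    isis = rng.uniform(config.isi_range[0], config.isi_range[1], size=n_events)
    stim_onsets = lead_in + np.cumsum(np.concatenate([[0.0], isis[:-1]])) + np.arange(
        n_events
    ) * config.stimulus_duration
    reaction_times = rt_model.sample(rng, n_events)
    event_times = stim_onsets + reaction_times

    tail = 2.0 + max(max_burst_end, rt_model.high)
    duration = event_times[-1] + tail
    n_times = int(np.ceil(duration * fs))
    if event_times[-1] + max_burst_end >= n_times / fs:
        raise ValueError("recording too short to host all requested events")

    signal = _pink_noise(
        rng, config.n_channels, n_times, fs, config.noise_exponent, config.noise_scale
    )
    if config.line_noise_hz:
        t = np.arange(n_times) / fs
        signal += 0.5 * config.noise_scale * np.sin(2 * np.pi * config.line_noise_hz * t)

    truth_rows = []
    for ev in event_times:
        for b in bursts_cfg:
            phase = rng.uniform(0, 2 * np.pi)
            burst = _hann_burst(fs, b.f_center, b.amplitude_uv, b.duration_s, phase)
            start = int(round((ev + b.onset_s) * fs))
            stop = min(start + burst.size, n_times)
            if b.amplitude_uv > 0:
                signal[:, start:stop] += burst[: stop - start]
            truth_rows.append(
                {
                    "event_s": ev,
                    "f_low": b.f_low,
                    "f_high": b.f_high,
                    "f_center": b.f_center,
                    "amplitude_uv": b.amplitude_uv,
                    "onset_s": b.onset_s,
                    "duration_s": b.duration_s,
                }
            )

    stim_labels = np.tile(np.arange(config.n_stimuli), config.reps_per_stimulus)[:n_events]
    events = pd.DataFrame(
        {"onset_s": event_times, "label": [f"stim{i + 1}" for i in stim_labels]}
    )
    rec = RawRecording(signal, fs, list(config.channel_names), events)
    truth = SyntheticTruth(
        group=group,
        session=session,
        subject=subject,
        event_times=event_times,
        bursts=pd.DataFrame(
            truth_rows,
            columns=[
                "event_s", "f_low", "f_high", "f_center",
                "amplitude_uv", "onset_s", "duration_s",
            ],
        ),
    )
    return rec, truth


def generate_cohort(
    config: CohortConfig,
) -> dict[tuple[str, str, int], tuple[RawRecording, SyntheticTruth]]:
    """All recordings for {tinnitus, control} x {S1, S2} x subjects.

    Keys are (group, session, subject); deterministic given ``config.seed``.
    """
    cohort: dict[tuple[str, str, int], tuple[RawRecording, SyntheticTruth]] = {}
    for group in GROUPS:
        for session in SESSIONS:
            for subject in range(config.n_subjects_per_group):
                cohort[(group, session, subject)] = generate_recording(
                    config, group, session, subject
                )
    return cohort


# ---------------------------------------------------------------------------
# scalogram-image fixtures


def _class_pattern(class_idx: int, size: int) -> np.ndarray:
    """Distinct horizontal-band template per class, values in [0, 1]."""
    y = np.linspace(0.0, 1.0, size)[:, None]
    x = np.linspace(0.0, 1.0, size)[None, :]
    centers = (0.2, 0.4, 0.6, 0.8)
    c = centers[class_idx]
    band = np.exp(-(((y - c) / 0.08) ** 2))
    ripple = 0.5 + 0.5 * np.sin(2 * np.pi * (2 + class_idx) * x)
    return band * ripple


def generate_scalogram_fixtures(
    n_per_class: tuple[int, int, int, int] | None = None,
    image_size: int = 160,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Class-conditional noisy scalogram-like images.

    Returns ``(images, labels)`` with images uint8 of shape
    (n, image_size, image_size, 3).  Classes are the four study cells
    (tinnitus/control x S1/S2); class sizes default to 801/667/500/500.
    ``separation`` scales the between-class pattern contrast: 0 makes the
    classes statistically indistinguishable.
    """
    sizes = tuple(n_per_class) if n_per_class is not None else DEFAULT_CLASS_SIZES
    if len(sizes) != 4 or any(n < 1 for n in sizes):
        raise ValueError("n_per_class must give four positive counts")
    if image_size < 8:
        raise ValueError("image_size too small")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    images = []
    rows = []
    for class_idx, ((group, session), n) in enumerate(zip(FIXTURE_CLASSES, sizes)):
        template = _class_pattern(class_idx, image_size)
        for j in range(n):
            noise = rng.standard_normal((image_size, image_size)) * 0.25
            frame = 0.3 + separation * 0.5 * template + noise
            frame = np.clip(frame, 0.0, 1.0)
            rgb = np.stack(
                [frame, np.clip(frame * 0.8 + 0.1, 0, 1), 1.0 - frame], axis=-1
            )
            images.append((rgb * 255).astype(np.uint8))
            rows.append({"image_id": f"{group}_{session}_{j:04d}",
                         "group": group, "session": session, "class_idx": class_idx})
    labels = pd.DataFrame(rows)
    return np.stack(images), labels


def write_scalogram_fixtures(
    images: np.ndarray, labels: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Save fixture PNGs plus a ``manifest.csv`` label table."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, image_id in zip(images, labels["image_id"]):
        p = out_dir / f"{image_id}.png"
        Image.fromarray(img).save(p)
        paths.append(p.name)
    manifest = labels.copy()
    manifest["filename"] = paths
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    """Persist ground truth as a JSON sidecar."""
    import json

    path = Path(path)
    payload = {
        "group": truth.group,
        "session": truth.session,
        "subject": truth.subject,
        "event_times": truth.event_times.tolist(),
        "bursts": truth.bursts.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path
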