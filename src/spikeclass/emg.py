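"""Synthetic multi-channel surface EMG with gesture structure.

The study's 8-channel forearm-bracelet recordings are not publicly deposited,
so this module generates surrogate recordings with the same structure: each
gesture has a per-channel relative amplitude profile (two movement gestures
dominate disjoint channel groups), and the signal envelope scales linearly
with a per-segment *effort* parameter. Each channel is a zero-mean Gaussian
carrier band-passed to 20-95 Hz whose envelope is

    baseline + effort * channel_weight * max_amplitude   (volts)

Segments are joined with a 150 ms raised-cosine ramp. The mean absolute value
(MAV) of a generated segment is therefore affine in effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "GestureProfile",
    "EMGRecording",
    "default_profiles",
    "standard_schedule",
    "generate_emg",
    "mav",
    "DEFAULT_FS_HZ",
    "DEFAULT_MAX_AMPLITUDE_V",
    "DEFAULT_BASELINE_RMS_V",
]

#: EMG sampling rate (Hz) of the emulated 8-channel bracelet
DEFAULT_FS_HZ = 200.0
#: envelope at effort 1.0 on a weight-1.0 channel; with the 2e6 EMG-to-current
#: scaling this drives sensory neurons at ~50-80 Hz during a full-effort
#: gesture, the regime where one-minute competitive learning at the 0.001
#: learning rate can form and hold gesture associations
DEFAULT_MAX_AMPLITUDE_V = 4.0e-5
#: resting-channel envelope (RMS volts)
DEFAULT_BASELINE_RMS_V = 1.5e-7
#: band of the noise carrier (Hz); below Nyquist at 200 Hz sampling
CARRIER_BAND_HZ = (20.0, 95.0)
#: raised-cosine ramp length between gesture segments (ms)
DEFAULT_TRANSITION_MS = 150.0


@dataclass(frozen=True)
class GestureProfile:
    """Per-channel relative amplitude weights of one gesture."""

    name: str
    channel_weights: np.ndarray
    baseline_rms: float = DEFAULT_BASELINE_RMS_V

    def __post_init__(self) -> None:
        w = np.asarray(self.channel_weights, dtype=float)
        object.__setattr__(self, "channel_weights", w)
        if w.min() < 0 or w.max() > 1:
            raise ValueError("channel weights must lie in [0, 1]")
        if self.name != "rest" and w.max() <= 0:
            raise ValueError("non-rest gestures need at least one active channel")
        if self.name == "rest" and w.max() > 0:
            raise ValueError("the rest profile must have all-zero weights")


def default_profiles(n_channels: int = 8) -> dict[str, GestureProfile]:
    """Rest, flexion (dominant on channels 1-3) and extension (dominant on
    channels 5-7), each with a weak secondary channel; the two movement
    profiles have nearly disjoint channel groups (cosine similarity < 0.3)."""
    if n_channels != 8:
        raise ValueError("default profiles are defined for 8 channels")
    flex = np.array([1.0, 0.85, 0.6, 0.15, 0.0, 0.0, 0.0, 0.1])
    ext = np.array([0.0, 0.1, 0.0, 0.15, 0.6, 0.85, 1.0, 0.1])
    return {
        "rest": GestureProfile("rest", np.zeros(8)),
        "flexion": GestureProfile("flexion", flex),
        "extension": GestureProfile("extension", ext),
    }


@dataclass
class EMGRecording:
    """samples: (n_channels, n_samples) volts; per-sample gesture labels and
    effort track aligned with the generating schedule."""

    samples: np.ndarray
    fs_hz: float
    labels: np.ndarray
    effort: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = np.asarray(self.labels)
        self.effort = np.asarray(self.effort, dtype=float)
        n = self.samples.shape[1]
        if self.labels.size != n or self.effort.size != n:
            raise ValueError("labels and effort must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def label_intervals_ms(self, gesture: str) -> list[tuple[float, float]]:
        """Contiguous (start_ms, end_ms) intervals where labels == gesture."""
        mask = self.labels == gesture
        if not mask.any():
            return []
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        starts = [0] if mask[0] else []
        starts += (edges[~mask[edges]] + 1).tolist()
        ends = (edges[mask[edges]] + 1).tolist()
        if mask[-1]:
            ends.append(mask.size)
        step = 1000.0 / self.fs_hz
        return [(s * step, e * step) for s, e in zip(starts, ends)]


def standard_schedule(
    n_cycles: int = 7, gesture_s: float = 3.0, effort: float = 1.0
) -> list[tuple[str, float, float]]:
    """The one-minute training schedule: repeated (rest, flexion, extension)
    segments of about 3 s each."""
    out: list[tuple[str, float, float]] = []
    for _ in range(n_cycles):
        out.append(("rest", gesture_s, 0.0))
        out.append(("flexion", gesture_s, effort))
        out.append(("extension", gesture_s, effort))
    return out


def _bandpassed_carrier(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the carrier band."""
    lo, hi = CARRIER_BAND_HZ
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n_channels, n_samples))
    x = sps.sosfiltfilt(sos, x, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def generate_emg(
    schedule: Sequence[tuple[str, float, float]],
    profiles: Optional[dict[str, GestureProfile]] = None,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
    max_amplitude: float = DEFAULT_MAX_AMPLITUDE_V,
    transition_ms: float = DEFAULT_TRANSITION_MS,
) -> EMGRecording:
    """Generate a labelled recording from a schedule of
    (gesture, duration_s, effort) segments."""
    profiles = profiles or default_profiles()
    n_channels = profiles[next(iter(profiles))].channel_weights.size
    seg_samples = []
    for gesture, dur, effort in schedule:
        if gesture not in profiles:
            raise KeyError(f"unknown gesture {gesture!r}; known: {sorted(profiles)}")
        if dur <= 0:
            raise ValueError("segment durations must be > 0")
        if not (0.0 <= effort <= 1.0):
            raise ValueError("effort must lie in [0, 1]")
        seg_samples.append(int(round(dur * fs)))
    n_total = int(np.sum(seg_samples))

    rng = np.random.default_rng(seed)
    carrier = _bandpassed_carrier(rng, n_channels, n_total, fs)

    envelope = np.zeros((n_channels, n_total))
    labels = np.empty(n_total, dtype=object)
    effort_track = np.zeros(n_total)
    pos = 0
    for (gesture, dur, effort), ns in zip(schedule, seg_samples):
        prof = profiles[gesture]
        env = prof.baseline_rms + effort * prof.channel_weights * max_amplitude
        envelope[:, pos : pos + ns] = env[:, None]
        labels[pos : pos + ns] = gesture
        effort_track[pos : pos + ns] = effort
        pos += ns

    # raised-cosine blend across segment boundaries
    ramp = int(round(transition_ms / 1000.0 * fs))
    if ramp > 1:
        bounds = np.cumsum(seg_samples)[:-1]
        half = ramp // 2
        for bidx in bounds:
            i0, i1 = max(0, bidx - half), min(n_total, bidx + half)
            left = envelope[:, i0 - 1] if i0 > 0 else envelope[:, 0]
            right = envelope[:, i1] if i1 < n_total else envelope[:, -1]
            x = np.linspace(0.0, 1.0, i1 - i0, endpoint=False)
            blend = 0.5 * (1.0 - np.cos(np.pi * x))
            envelope[:, i0:i1] = left[:, None] * (1 - blend) + right[:, None] * blend

    samples = carrier * envelope
    return EMGRecording(samples=samples, fs_hz=fs, labels=np.asarray(labels, dtype="U16"),
                        effort=effort_track)


def mav(
    emg: EMGRecording,
    window_s: Optional[tuple[float, float]] = None,
    channels: Optional[Sequence[int]] = None,
) -> float:
    """Mean absolute value of the signal over a time window (seconds) and a
    channel selection; defaults to the whole recording and all channels."""
    if window_s is None:
        i0, i1 = 0, emg.n_samples
    else:
        t0, t1 = window_s
        if not (0 <= t0 < t1 <= emg.duration_s + 1e-9):
            raise ValueError(f"window ({t0}, {t1}) s not inside the recording")
        i0, i1 = int(round(t0 * emg.fs_hz)), int(round(t1 * emg.fs_hz))
    if i1 <= i0:
        raise ValueError("empty MAV window")
    sel = slice(None) if channels is None else list(channels)
    return float(np.mean(np.abs(emg.samples[sel, i0:i1])))
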