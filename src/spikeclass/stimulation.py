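"""External stimulation protocols.

A :class:`StimulusProtocol` is a time-indexed schedule of external currents
delivered through named *stimulators*; a network binds each stimulator to one
neuron. Two entry kinds exist: rectangular pulse trains (temporal patterns,
rate patterns, the supervised "teacher" electrode) and continuous sampled
currents (EMG-derived drive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PulseTrain",
    "merge_protocols",
    "ContinuousDrive",
    "StimulusProtocol",
    "DEFAULT_RATES_HZ",
    "DEFAULT_PULSE_MS",
    "DEFAULT_PULSE_AMPLITUDE",
    "temporal_pattern",
    "temporal_familiar_unknown_split",
    "rate_pattern",
    "reversed_rate_pattern",
    "emg_current",
    "emg_protocol",
    "teacher_stimulus",
]

#: rate-coding frequencies used throughout (Hz)
DEFAULT_RATES_HZ = (0.1, 0.2, 0.5, 1.0, 2.0, 3.0, 6.0, 12.0, 25.0, 50.0)
#: default rectangular pulse: 2 ms at amplitude 40 — strong enough to fire the
#: regular-spiking neuron even with an elevated recovery variable (1:1 on
#: periodic trains up to 50 Hz), short enough not to double-fire from rest
DEFAULT_PULSE_MS = 2.0
DEFAULT_PULSE_AMPLITUDE = 40.0
#: EMG-to-current scaling coefficient
DEFAULT_K = 2.0e6


@dataclass(frozen=True)
class PulseTrain:
    """Rectangular pulses: onset times (ms), common duration and amplitude."""

    stimulator: int
    onsets_ms: np.ndarray
    pulse_ms: float = DEFAULT_PULSE_MS
    amplitude: float = DEFAULT_PULSE_AMPLITUDE

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets_ms", np.asarray(self.onsets_ms, dtype=float))
        if not np.all(np.isfinite(self.onsets_ms)):
            raise ValueError("pulse onsets must be finite")
        if not np.isfinite(self.amplitude):
            raise ValueError("pulse amplitude must be finite")
        if self.pulse_ms <= 0:
            raise ValueError("pulse duration must be > 0")


@dataclass(frozen=True)
class ContinuousDrive:
    """Continuous current samples (current units) at a fixed sampling rate,
    applied with zero-order hold on the integration grid."""

    stimulator: int
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("current samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be > 0")


Entry = Union[PulseTrain, ContinuousDrive]


@dataclass
class StimulusProtocol:
    """A set of stimulator entries defined on [0, duration_ms]."""

    entries: list[Entry]
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("duration must be >= 0")
        for e in self.entries:
            if isinstance(e, PulseTrain) and e.onsets_ms.size:
                if e.onsets_ms.min() < 0 or e.onsets_ms.max() > self.duration_ms:
                    raise ValueError(
                        f"stimulator {e.stimulator}: pulse onsets outside [0, duration]"
                    )

    @property
    def stimulators(self) -> list[int]:
        return [e.stimulator for e in self.entries]

    def current_matrix(
        self,
        dt: float,
        n_steps: int,
        binding: dict[int, int],
        n_neurons: int,
    ) -> np.ndarray:
        """Dense per-step external current, shape (n_steps, n_neurons).

        binding maps stimulator id -> neuron index; every entry's stimulator
        must be bound, and bindings must point at existing neurons.
        """
        out = np.zeros((n_steps, n_neurons), dtype=np.float32)
        for e in self.entries:
            if e.stimulator not in binding:
                raise KeyError(f"stimulator {e.stimulator} has no neuron binding")
            idx = binding[e.stimulator]
            if not (0 <= idx < n_neurons):
                raise IndexError(f"stimulator {e.stimulator} bound to unknown neuron {idx}")
            if isinstance(e, PulseTrain):
                width = max(1, int(round(e.pulse_ms / dt)))
                for onset in e.onsets_ms:
                    i0 = int(round(onset / dt))
                    if i0 >= n_steps:
                        continue
                    out[i0 : min(i0 + width, n_steps), idx] += e.amplitude
            else:
                t = np.arange(n_steps) * dt  # ms
                si = np.minimum((t * e.fs_hz / 1000.0).astype(np.int64), e.samples.size - 1)
                out[:, idx] += e.samples[si]
        return out


def temporal_pattern(
    delta_t: float,
    n: int = 10,
    repetition_hz: float = 1.0,
    duration_ms: float = 1000.0,
    pulse_ms: float = DEFAULT_PULSE_MS,
    amplitude: float = DEFAULT_PULSE_AMPLITUDE,
) -> StimulusProtocol:
    """Repeating temporal pattern: within each repetition cycle, stimulator j
    fires one pulse at offset (j - 1) * delta_t; the pattern repeats at
    ``repetition_hz`` (default 1 Hz)."""
    if delta_t <= 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    if n < 1:
        raise ValueError("n must be >= 1")
    period = 1000.0 / repetition_hz
    if (n - 1) * delta_t + pulse_ms >= period:
        raise ValueError(
            f"pattern length {(n - 1) * delta_t + pulse_ms} ms does not fit in the "
            f"{period} ms repetition period"
        )
    starts = np.arange(0.0, duration_ms - (n - 1) * delta_t - pulse_ms, period)
    entries = [
        PulseTrain(j, starts + j * delta_t, pulse_ms, amplitude) for j in range(n)
    ]
    return StimulusProtocol(entries, duration_ms)


def temporal_familiar_unknown_split(
    pattern: StimulusProtocol,
) -> tuple[StimulusProtocol, StimulusProtocol]:
    """Split a temporal pattern into familiar (first half of the stimulators,
    with their pulse times) and unknown (second half) protocols."""
    n = len(pattern.entries)
    if n % 2 != 0:
        raise ValueError(f"familiar/unknown split needs an even stimulator count, got {n}")
    half = n // 2
    familiar = StimulusProtocol(list(pattern.entries[:half]), pattern.duration_ms)
    unknown = StimulusProtocol(list(pattern.entries[half:]), pattern.duration_ms)
    return familiar, unknown


def rate_pattern(
    rates_hz: Sequence[float],
    duration_ms: float,
    seed: int,
    refractory_ms: float = 5.0,
    pulse_ms: float = DEFAULT_PULSE_MS,
    amplitude: float = DEFAULT_PULSE_AMPLITUDE,
    mode: str = "poisson",
) -> StimulusProtocol:
    """One stochastic pulse train per requested mean rate.

    ``poisson`` trains draw independent exponential gaps on top of a
    ``refractory_ms`` floor (the exponential rate is adjusted so the mean rate
    equals the request); ``periodic`` trains are regular. rate = 0 gives an
    empty train.
    """
    rates = [float(r) for r in rates_hz]
    if not rates:
        raise ValueError("rates_hz must be non-empty")
    if any(r < 0 for r in rates):
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    entries = []
    for j, r in enumerate(rates):
        if r == 0:
            entries.append(PulseTrain(j, np.empty(0), pulse_ms, amplitude))
            continue
        mean_gap = 1000.0 / r
        if mode == "periodic":
            onsets = np.arange(0.0, duration_ms - pulse_ms, mean_gap)
        elif mode == "poisson":
            if mean_gap <= refractory_ms:
                raise ValueError(
                    f"rate {r} Hz is incompatible with a {refractory_ms} ms refractory floor"
                )
            exp_mean = mean_gap - refractory_ms
            n_guess = int(duration_ms / mean_gap * 1.5) + 20
            onsets_list: list[float] = []
            t = 0.0
            while True:
                gaps = refractory_ms + rng.exponential(exp_mean, size=n_guess)
                times = t + np.cumsum(gaps)
                onsets_list.extend(times[times < duration_ms - pulse_ms].tolist())
                if times[-1] >= duration_ms - pulse_ms:
                    break
                t = times[-1]
            onsets = np.asarray(onsets_list)
        else:
            raise ValueError(f"mode must be 'poisson' or 'periodic', got {mode!r}")
        entries.append(PulseTrain(j, onsets, pulse_ms, amplitude))
    return StimulusProtocol(entries, duration_ms)


def reversed_rate_pattern(rates_hz: Sequence[float]) -> list[float]:
    """Order-reversed rate assignment (the rate-coding 'unknown' pattern)."""
    rates = list(rates_hz)
    if not rates:
        raise ValueError("rates_hz must be non-empty")
    return rates[::-1]


def emg_current(emg_sample: float, k: float = DEFAULT_K) -> float:
    """EMG-associated current I = k * |EMG|; the raw signal is full-wave
    rectified because zero-mean EMG would cancel as a signed current."""
    if not np.isfinite(emg_sample):
        raise ValueError(f"EMG sample must be finite, got {emg_sample!r}")
    return k * abs(emg_sample)


def emg_protocol(recording, k: float = DEFAULT_K) -> StimulusProtocol:
    """Continuous EMG drive: stimulator c carries k * |channel c| as current."""
    entries = [
        ContinuousDrive(c, k * np.abs(recording.samples[c]), recording.fs_hz)
        for c in range(recording.n_channels)
    ]
    return StimulusProtocol(entries, recording.duration_s * 1000.0)


def merge_protocols(*protocols: StimulusProtocol) -> StimulusProtocol:
    """Combine protocols (e.g. EMG drive plus a teacher electrode) into one;
    the merged duration is the maximum of the parts."""
    if not protocols:
        raise ValueError("need at least one protocol")
    entries: list[Entry] = []
    for pr in protocols:
        entries.extend(pr.entries)
    return StimulusProtocol(entries, max(pr.duration_ms for pr in protocols))


def teacher_stimulus(
    target: int,
    intervals_ms: Sequence[tuple[float, float]],
    duration_ms: float,
    rate_hz: float = 40.0,
    pulse_ms: float = DEFAULT_PULSE_MS,
    amplitude: float = DEFAULT_PULSE_AMPLITUDE,
    stimulator: int | None = None,
) -> StimulusProtocol:
    """Supervised 'virtual electrode': a periodic suprathreshold pulse train at
    ``rate_hz`` delivered only during the given (start, end) intervals. The
    stimulator id defaults to the target neuron id."""
    if rate_hz <= 0:
        raise ValueError("teacher rate must be > 0")
    gap = 1000.0 / rate_hz
    onsets: list[np.ndarray] = []
    for start, end in intervals_ms:
        if start < 0 or end > duration_ms or end < start:
            raise ValueError(f"interval ({start}, {end}) outside [0, {duration_ms}]")
        onsets.append(np.arange(start, min(end, duration_ms - pulse_ms), gap))
    all_onsets = np.concatenate(onsets) if onsets else np.empty(0)
    sid = target if stimulator is None else stimulator
    return StimulusProtocol([PulseTrain(sid, all_onsets, pulse_ms, amplitude)], duration_ms)
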