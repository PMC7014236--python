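"""Izhikevich point-neuron dynamics, noise sampling, and driving-current assembly.

The membrane model is the two-variable quadratic integrate-and-reset system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= threshold:  v <- c,  u <- u + d

with v in mV, time in ms, and I the total driving current

    I(t) = xi(t) + I_syn(t) + I_stml(t)

where ``xi`` is zero-mean white Gaussian noise with per-step variance D,
``I_syn`` the synaptic current and ``I_stml`` an external stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "REGULAR_SPIKING",
    "FAST_SPIKING",
    "total_current",
    "sample_noise",
    "step_neuron",
    "SimulationBlowUpError",
]

#: abort threshold for the membrane potential (mV); the quadratic upstroke is
#: reset at the spike threshold, so anything near this magnitude is divergence
BLOWUP_MV = 1.0e3


class SimulationBlowUpError(RuntimeError):
    """Raised when the membrane potential diverges (|v| > 1000 mV)."""


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one Izhikevich neuron.

    a : recovery time scale (1/ms)
    b : recovery sensitivity (dimensionless)
    c : post-spike reset potential (mV)
    d : post-spike recovery increment
    D : white-noise current variance (per integration step)
    g : synaptic scaling factor of the neuron's *outgoing* synapses,
        +2 for excitatory and -2 for inhibitory neurons
    spike_threshold : spike detection level (mV)
    bias : constant background current (0 for ordinary neurons)
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    D: float = 0.0
    g: float = 2.0
    spike_threshold: float = 30.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.g not in (2.0, -2.0, 2, -2):
            raise ValueError(f"g must be +2 (excitatory) or -2 (inhibitory), got {self.g}")
        if self.D < 0:
            raise ValueError(f"noise variance D must be >= 0, got {self.D}")
        if not self.spike_threshold > self.c:
            raise ValueError("spike_threshold must exceed the reset potential c")


#: canonical regular-spiking (excitatory) parameter set
REGULAR_SPIKING = NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0, g=2.0)
#: canonical fast-spiking (inhibitory) parameter set
FAST_SPIKING = NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0, g=-2.0)


@dataclass
class NeuronState:
    """Dynamical state of one neuron: membrane potential v (mV), recovery u,
    and the time of the most recent spike (ms), if any."""

    v: float = -70.0
    u: float = -14.0
    last_spike_time: Optional[float] = None

    @classmethod
    def at_rest(cls, params: NeuronParams) -> "NeuronState":
        """Resting state: the stable fixed point of the noiseless, input-free
        system (v* solving 0.04 v^2 + (5 - b) v + 140 = 0, u* = b v*)."""
        b = params.b
        disc = (5.0 - b) ** 2 - 4.0 * 0.04 * 140.0
        if disc < 0:
            raise ValueError("no resting fixed point exists for these parameters")
        v = (-(5.0 - b) - math.sqrt(disc)) / (2.0 * 0.04)
        return cls(v=v, u=b * v, last_spike_time=None)


def total_current(noise_sample: float, syn_current: float, stim_current: float) -> float:
    """Total driving current I(t) = xi(t) + I_syn(t) + I_stml(t)."""
    for name, val in (
        ("noise_sample", noise_sample),
        ("syn_current", syn_current),
        ("stim_current", stim_current),
    ):
        if not np.isfinite(val):
            raise ValueError(f"non-finite current term: {name} = {val!r}")
    return noise_sample + syn_current + stim_current


def sample_noise(D: float, dt: float, rng: np.random.Generator) -> float:
    """One white-noise current sample, Normal(0, D).

    The variance is interpreted *per integration step*: each step receives an
    independent Normal(0, D) draw regardless of dt (the convention is fixed so
    that a stated variance such as D = 70 has a single meaning).
    """
    if D < 0:
        raise ValueError(f"noise variance D must be >= 0, got {D}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if D == 0:
        return 0.0
    return float(rng.normal(0.0, math.sqrt(D)))


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I: float,
    dt: float,
    t: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one step of length dt (ms).

    Spike detection happens on entry: if v has reached the threshold, the
    neuron is reset (v <- c, u <- u + d) and no integration is performed this
    step; otherwise (v, u) are advanced by forward Euler with the membrane
    update split into two half-steps for stability.
    """
    if not (0.0 < dt <= 1.0):
        raise ValueError(f"dt must satisfy 0 < dt <= 1 ms, got {dt}")
    v, u = state.v, state.u
    if v >= params.spike_threshold:
        return NeuronState(v=params.c, u=u + params.d, last_spike_time=t), True
    for _ in range(2):
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u = u + dt * params.a * (params.b * v - u)
    if abs(v) > BLOWUP_MV:
        raise SimulationBlowUpError(
            f"membrane potential diverged (v = {v:.3g} mV at t = {t:.3g} ms); "
            "reduce dt or the driving current"
        )
    return NeuronState(v=v, u=u, last_spike_time=state.last_spike_time), False
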