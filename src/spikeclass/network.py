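"""Network construction and the time-stepped simulation engine.

Two standard topologies are provided: the 10-to-1 single-neuron learning
testbed and the two-layer EMG classifier (sensory layer with lateral
inhibition and a noise-driven rest detector, classifier layer with
winner-take-all lateral inhibition, all-to-all plastic projections in
between). :func:`simulate` integrates any topology with seeded noise,
returning a spike raster, weight snapshots and the final weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .neurons import (
    FAST_SPIKING,
    REGULAR_SPIKING,
    BLOWUP_MV,
    NeuronParams,
    SimulationBlowUpError,
)
from .plasticity import PlasticityParams, Rule
from .stimulation import StimulusProtocol

__all__ = [
    "Neuron",
    "SynapseSet",
    "NetworkTopology",
    "SpikeRaster",
    "SimulationResult",
    "build_single_neuron_testbed",
    "build_emg_classifier_network",
    "simulate",
    "DEFAULT_ORDINARY_D",
    "REST_DETECTOR_D",
]

#: noise variance for ordinary neurons: low enough that an unstimulated
#: regular-spiking neuron stays below 0.2 Hz baseline at dt = 0.5 ms
DEFAULT_ORDINARY_D = 1.0
#: noise variance for the single-neuron testbed (quieter probe conditions)
TESTBED_D = 0.25
#: noise variance of the rest-detector neuron
REST_DETECTOR_D = 70.0
#: constant bias current of the rest detector: mean-zero noise alone fires it
#: too slowly for its single plastic synapse to compete with the three-channel
#: gesture drives, so the bias makes it run very hot (~270 Hz uninhibited);
#: sensory-layer inhibition silences it whenever a gesture is present
REST_DETECTOR_BIAS = 160.0
#: classifier-layer noise: strong enough that a classifier whose rest-detector
#: weight eroded during early competition can still fire occasionally at rest
#: and relearn the association (escape from the silent state), weak enough for
#: a ~0 Hz unstimulated baseline
CLASSIFIER_D = 5.0
#: forgetting time of the classifier network's plastic synapses: synaptic
#: competition must differentiate the three classifiers within the one-minute
#: online training, ~50x faster than the single-neuron 1000 s protocol
CLASSIFIER_TAU_F = 2.0e4

LAYERS = (
    "sensory",
    "sensory_inhibitory",
    "rest_detector",
    "classifier",
    "classifier_inhibitory",
    "presynaptic",
    "postsynaptic",
)


@dataclass(frozen=True)
class Neuron:
    id: int
    params: NeuronParams
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer tag {self.layer!r}")


@dataclass
class SynapseSet:
    """Parallel arrays describing all synapses: pre/post neuron ids, weights,
    plasticity flags and per-set rule parameters."""

    pre: np.ndarray
    post: np.ndarray
    w: np.ndarray
    plastic: np.ndarray
    rule: Rule = Rule.NONE
    params: PlasticityParams = field(default_factory=PlasticityParams)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.intp)
        self.post = np.asarray(self.post, dtype=np.intp)
        self.w = np.asarray(self.w, dtype=float)
        self.plastic = np.asarray(self.plastic, dtype=bool)
        n = self.pre.size
        if not (self.post.size == n and self.w.size == n and self.plastic.size == n):
            raise ValueError("synapse arrays must have equal length")
        if np.any(self.pre == self.post):
            raise ValueError("self-synapses are not allowed")
        wp = self.w[self.plastic]
        if wp.size and (wp.min() < 0 or wp.max() > 1):
            raise ValueError("plastic weights must lie in [0, 1]")

    def copy(self) -> "SynapseSet":
        return SynapseSet(
            self.pre.copy(), self.post.copy(), self.w.copy(), self.plastic.copy(),
            self.rule, self.params,
        )

    def __len__(self) -> int:
        return int(self.pre.size)


@dataclass
class NetworkTopology:
    neurons: list[Neuron]
    synapses: SynapseSet
    stimulus_bindings: dict[int, int]  # stimulator id -> neuron id

    def __post_init__(self) -> None:
        ids = {n.id for n in self.neurons}
        if len(ids) != len(self.neurons):
            raise ValueError("duplicate neuron ids")
        if ids != set(range(len(self.neurons))):
            raise ValueError("neuron ids must be 0..n-1")
        for arr in (self.synapses.pre, self.synapses.post):
            if arr.size and (arr.min() < 0 or arr.max() >= len(self.neurons)):
                raise ValueError("synapse endpoint refers to a missing neuron")
        for stim, nid in self.stimulus_bindings.items():
            if nid not in ids:
                raise ValueError(f"stimulator {stim} bound to unknown neuron {nid}")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def ids_in_layer(self, layer: str) -> list[int]:
        return [n.id for n in self.neurons if n.layer == layer]

    def with_weights(self, w: np.ndarray) -> "NetworkTopology":
        """A copy of this topology carrying the given synaptic weights."""
        syn = self.synapses.copy()
        syn.w = np.asarray(w, dtype=float).copy()
        if syn.w.size != len(self.synapses):
            raise ValueError("weight vector length mismatch")
        return NetworkTopology(list(self.neurons), syn, dict(self.stimulus_bindings))


@dataclass
class SpikeRaster:
    """Time-ordered spike events (neuron id, time in ms) over [0, duration]."""

    neuron_ids: np.ndarray
    times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.intp)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.neuron_ids.size != self.times_ms.size:
            raise ValueError("ids and times must have equal length")
        if self.times_ms.size:
            if np.any(np.diff(self.times_ms) < 0):
                raise ValueError("spike times must be non-decreasing")
            if self.times_ms[0] < 0 or self.times_ms[-1] > self.duration_ms:
                raise ValueError("spike times outside [0, duration]")

    def __len__(self) -> int:
        return int(self.times_ms.size)

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        return self.times_ms[self.neuron_ids == neuron_id]

    def rate_hz(self, neuron_id: int, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Spike count of one neuron in [t0, t1) divided by the window length."""
        t1 = self.duration_ms if t1 is None else t1
        if t1 <= t0:
            raise ValueError("empty window")
        t = self.spikes_of(neuron_id)
        return float(np.count_nonzero((t >= t0) & (t < t1))) / ((t1 - t0) / 1000.0)


@dataclass
class SimulationResult:
    raster: SpikeRaster
    weight_times_ms: np.ndarray
    weight_history: np.ndarray  # (n_snapshots, n_synapses)
    final_weights: SynapseSet
    topology: NetworkTopology  # input topology carrying the final weights


def _init_weights(rng: np.random.Generator, n: int, init_range: tuple[float, float]) -> np.ndarray:
    lo, hi = init_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("init weight range must satisfy 0 <= lo <= hi <= 1")
    return rng.uniform(lo, hi, size=n)


def build_single_neuron_testbed(
    n_pre: int = 10,
    rule: Rule | str = Rule.PAIR,
    plasticity: PlasticityParams | None = None,
    init_weight_range: tuple[float, float] = (0.25, 0.75),
    ordinary_D: float = TESTBED_D,
    seed: int = 0,
) -> NetworkTopology:
    """n_pre excitatory presynaptic neurons, each driven 1:1 by a stimulator,
    all projecting through plastic synapses onto one postsynaptic neuron."""
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    rng = np.random.default_rng(seed)
    rs = replace(REGULAR_SPIKING, D=ordinary_D)
    neurons = [Neuron(j, rs, "presynaptic") for j in range(n_pre)]
    neurons.append(Neuron(n_pre, rs, "postsynaptic"))
    syn = SynapseSet(
        pre=np.arange(n_pre),
        post=np.full(n_pre, n_pre),
        w=_init_weights(rng, n_pre, init_weight_range),
        plastic=np.ones(n_pre, dtype=bool),
        rule=Rule(rule),
        params=plasticity or PlasticityParams(),
    )
    bindings = {j: j for j in range(n_pre)}
    return NetworkTopology(neurons, syn, bindings)


def build_emg_classifier_network(
    n_channels: int = 8,
    n_classes: int = 3,
    plasticity: PlasticityParams | None = None,
    init_weight_range: tuple[float, float] = (0.5, 1.0),
    ordinary_D: float = CLASSIFIER_D,
    rest_detector_D: float = REST_DETECTOR_D,
    rest_detector_bias: float = REST_DETECTOR_BIAS,
    sensory_to_inhib_w: float = 1.0,
    inhib_to_sensory_w: float = 0.5,
    inhib_to_rest_w: float = 4.0,
    classifier_to_inhib_w: float = 1.0,
    inhib_to_classifier_w: float = 4.0,
    seed: int = 0,
) -> NetworkTopology:
    """Two-layer winner-take-all EMG classifier.

    Sensory layer: one excitatory sensory neuron per EMG channel, each with an
    inhibitory partner providing lateral inhibition of the *other* sensory
    neurons, plus one rest-detector neuron (large individual noise D = 70,
    strong fixed inhibitory input from every sensory-layer partner) that fires
    when the sensory neurons are silent. Output layer: ``n_classes`` excitatory
    classifiers, each with an inhibitory partner inhibiting the other
    classifiers (winner-take-all). Plastic triplet+forgetting synapses run
    from every sensory neuron and the rest detector to every classifier.
    """
    if n_channels < 2 or n_classes < 2:
        raise ValueError("need n_channels >= 2 and n_classes >= 2")
    rng = np.random.default_rng(seed)
    rs = replace(REGULAR_SPIKING, D=ordinary_D)
    fs = FAST_SPIKING
    neurons: list[Neuron] = []
    sens = list(range(0, n_channels))
    sinh = list(range(n_channels, 2 * n_channels))
    rest = 2 * n_channels
    cls = list(range(rest + 1, rest + 1 + n_classes))
    cinh = list(range(rest + 1 + n_classes, rest + 1 + 2 * n_classes))
    for i in sens:
        neurons.append(Neuron(i, rs, "sensory"))
    for i in sinh:
        neurons.append(Neuron(i, fs, "sensory_inhibitory"))
    neurons.append(
        Neuron(
            rest,
            replace(REGULAR_SPIKING, D=rest_detector_D, bias=rest_detector_bias),
            "rest_detector",
        )
    )
    for i in cls:
        neurons.append(Neuron(i, rs, "classifier"))
    for i in cinh:
        neurons.append(Neuron(i, fs, "classifier_inhibitory"))

    pre, post, w, plastic = [], [], [], []

    def add(p, q, weight, is_plastic=False):
        pre.append(p); post.append(q); w.append(weight); plastic.append(is_plastic)

    for i, s in enumerate(sens):
        add(s, sinh[i], sensory_to_inhib_w)
        for j, s2 in enumerate(sens):
            if j != i:
                add(sinh[i], s2, inhib_to_sensory_w)
        add(sinh[i], rest, inhib_to_rest_w)
    n_plastic_pre = len(sens) + 1
    w0 = _init_weights(rng, n_plastic_pre * n_classes, init_weight_range)
    k = 0
    for c in cls:
        for s in sens + [rest]:
            add(s, c, w0[k], True)
            k += 1
    for i, c in enumerate(cls):
        add(c, cinh[i], classifier_to_inhib_w)
        for j, c2 in enumerate(cls):
            if j != i:
                add(cinh[i], c2, inhib_to_classifier_w)

    syn = SynapseSet(
        pre=np.array(pre), post=np.array(post), w=np.array(w),
        plastic=np.array(plastic), rule=Rule.TRIPLET_FORGETTING,
        params=plasticity or PlasticityParams(tau_f=CLASSIFIER_TAU_F),
    )
    bindings = {c: c for c in range(n_channels)}  # EMG channel c -> sensory c
    return NetworkTopology(neurons, syn, bindings)


def _step_range(
    k0, n_sub, v, u, W, y_syn, y1, y2, y_avg, spiked,
    a, b, c, d, g, thr, bias, noise_std, use_noise,
    I_ext, noise, dt, f_syn, f1, f2, f_avg,
    lam, alpha, tau_f, rule_code, pre_p, post_p,
    snap_every, snap_pre, snap_post, snap_buf, snap_times, snap_count,
    spike_steps, spike_ids, n_sp,
):
    """Advance ``n_sub`` steps starting at global step ``k0``.

    Per-step event ordering: spike detection/reset on entry -> trace decay ->
    LTD then LTP reading pre-increment traces -> forgetting -> trace
    increments -> weight snapshot -> current assembly -> membrane integration
    (two half-steps for v). Returns the updated spike/snapshot counts and a
    divergence flag.
    """
    n = v.shape[0]
    n_plast = pre_p.shape[0]
    for kk in range(n_sub):
        k = k0 + kk
        # 1. spike detection / reset on entry
        any_spike = False
        for i in range(n):
            if v[i] >= thr[i]:
                spiked[i] = True
                any_spike = True
                v[i] = c[i]
                u[i] += d[i]
                spike_steps[n_sp] = k
                spike_ids[n_sp] = i
                n_sp += 1
            else:
                spiked[i] = False
        # 2. trace decay
        for i in range(n):
            y_syn[i] *= f_syn
            y1[i] *= f1
            y2[i] *= f2
            y_avg[i] *= f_avg
        # 3. plasticity: LTD then LTP, reading pre-increment traces
        if rule_code >= 1 and any_spike:
            for s in range(n_plast):
                j = pre_p[s]
                i = post_p[s]
                w = W[j, i]
                if spiked[j]:
                    w -= lam * alpha * w * y1[i]
                if spiked[i]:
                    if rule_code == 1:
                        w += lam * (1.0 - w) * y1[j]
                    else:
                        w += lam * (1.0 - w) * y1[j] * y2[i]
                W[j, i] = w
        # 4. forgetting: activity-dependent weight decay, every step
        if rule_code == 3:
            for s in range(n_plast):
                j = pre_p[s]
                i = post_p[s]
                W[j, i] *= math.exp(-(dt / tau_f) * y_avg[i])
        # 5. trace increments of the spiking neurons
        if any_spike:
            for i in range(n):
                if spiked[i]:
                    y_syn[i] += 1.0
                    y1[i] += 1.0
                    y2[i] += 1.0
                    y_avg[i] += 1.0
        if snap_every > 0 and k % snap_every == 0:
            for s in range(snap_pre.shape[0]):
                snap_buf[snap_count, s] = W[snap_pre[s], snap_post[s]]
            snap_times[snap_count] = k * dt
            snap_count += 1
        # 6. total current and membrane integration (skip freshly reset cells)
        for i in range(n):
            if spiked[i]:
                continue
            I = bias[i] + I_ext[kk, i]
            for j in range(n):
                I += g[j] * y_syn[j] * W[j, i]
            if use_noise:
                I += noise_std[i] * noise[kk, i]
            vi = v[i]
            ui = u[i]
            vi += 0.5 * dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I)
            vi += 0.5 * dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I)
            ui += dt * a[i] * (b[i] * vi - ui)
            if not (math.isfinite(vi) and math.isfinite(ui)):
                return n_sp, snap_count, True
            v[i] = vi
            u[i] = ui
    return n_sp, snap_count, False


try:  # pragma: no cover - exercised whenever numba is installed
    from numba import njit

    _step_range_fast = njit(cache=True)(_step_range)
except ImportError:  # pragma: no cover
    _step_range_fast = _step_range


def simulate(
    net: NetworkTopology,
    stimuli: StimulusProtocol | None,
    duration_ms: float,
    dt: float = 0.5,
    learning: bool = True,
    seed: int = 0,
    record_weights_every_ms: Optional[float] = None,
    extra_bindings: dict[int, int] | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration_ms`` with step ``dt`` (ms).

    Deterministic given (topology, stimuli, seed, dt). With learning=False all
    plastic weights are frozen. ``extra_bindings`` adds stimulator->neuron
    bindings on top of the topology's own (used by the teacher electrode,
    whose stimulator id addresses a classifier directly).

    Per-step event ordering: spike detection/reset on entry -> trace decay ->
    LTD then LTP reading pre-increment traces -> forgetting -> trace increments
    -> current assembly -> membrane integration (two half-steps for v).
    """
    if duration_ms < 0:
        raise ValueError("duration must be >= 0")
    if not (0 < dt <= 1.0):
        raise ValueError("dt must satisfy 0 < dt <= 1 ms")
    n = net.n_neurons
    n_steps = int(round(duration_ms / dt))

    binding = dict(net.stimulus_bindings)
    if extra_bindings:
        binding.update(extra_bindings)
    if stimuli is not None:
        I_ext = stimuli.current_matrix(dt, n_steps, binding, n)
    else:
        I_ext = np.zeros((max(n_steps, 1), n), dtype=np.float32)

    p = net.synapses.params
    a = np.array([nr.params.a for nr in net.neurons])
    b = np.array([nr.params.b for nr in net.neurons])
    c = np.array([nr.params.c for nr in net.neurons])
    d = np.array([nr.params.d for nr in net.neurons])
    g = np.array([nr.params.g for nr in net.neurons])
    thr = np.array([nr.params.spike_threshold for nr in net.neurons])
    bias = np.array([nr.params.bias for nr in net.neurons])
    noise_std = np.sqrt(np.array([nr.params.D for nr in net.neurons]))
    any_noise = bool(np.any(noise_std > 0))

    # resting initial conditions
    disc = (5.0 - b) ** 2 - 0.16 * 140.0
    v = (-(5.0 - b) - np.sqrt(disc)) / 0.08
    u = b * v

    W = np.zeros((n, n))
    syn0 = net.synapses
    W[syn0.pre, syn0.post] = syn0.w
    pl = syn0.plastic
    pre_p = syn0.pre[pl]
    post_p = syn0.post[pl]
    rule = syn0.rule if learning else Rule.NONE
    do_plast = rule in (Rule.PAIR, Rule.TRIPLET, Rule.TRIPLET_FORGETTING) and pre_p.size > 0
    do_forget = rule is Rule.TRIPLET_FORGETTING and pre_p.size > 0

    y_syn = np.zeros(n)
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    y_avg = np.zeros(n)
    f_syn = math.exp(-dt / p.tau_syn)
    f1 = math.exp(-dt / p.tau1)
    f2 = math.exp(-dt / p.tau2)
    f_avg = math.exp(-dt / p.tau_o)
    lam, alpha, tau_f = p.lam, p.alpha, p.tau_f

    rule_code = {Rule.NONE: 0, Rule.PAIR: 1, Rule.TRIPLET: 2, Rule.TRIPLET_FORGETTING: 3}[rule]
    if pre_p.size == 0:
        rule_code = 0

    rng = np.random.default_rng(seed)
    snap_every = (
        0 if record_weights_every_ms is None
        else max(1, int(round(record_weights_every_ms / dt)))
    )
    n_snaps = (n_steps - 1) // snap_every + 1 if (snap_every and n_steps) else 0
    snap_buf = np.zeros((n_snaps, len(syn0)))
    snap_times = np.zeros(n_snaps)
    snap_count = 0

    spiked = np.zeros(n, dtype=np.bool_)
    all_steps: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    I_ext64 = np.ascontiguousarray(I_ext, dtype=np.float64)
    no_noise = np.zeros((1, n))

    chunk = 16384
    spike_steps = np.zeros(chunk * n, dtype=np.int64)
    spike_ids_arr = np.zeros(chunk * n, dtype=np.int64)
    k0 = 0
    while k0 < n_steps:
        n_sub = min(chunk, n_steps - k0)
        noise = rng.standard_normal((n_sub, n)) if any_noise else no_noise
        n_sp, snap_count, diverged = _step_range_fast(
            k0, n_sub, v, u, W, y_syn, y1, y2, y_avg, spiked,
            a, b, c, d, g, thr, bias, noise_std, any_noise,
            I_ext64[k0 : k0 + n_sub], noise,
            dt, f_syn, f1, f2, f_avg,
            lam, alpha, tau_f, rule_code, pre_p, post_p,
            snap_every, syn0.pre, syn0.post, snap_buf, snap_times, snap_count,
            spike_steps, spike_ids_arr, 0,
        )
        if diverged:
            raise SimulationBlowUpError(
                f"membrane potential diverged near t = {k0 * dt:.1f} ms"
            )
        if n_sp:
            all_steps.append(spike_steps[:n_sp].copy())
            all_ids.append(spike_ids_arr[:n_sp].copy())
        k0 += n_sub

    if all_ids:
        ids = np.concatenate(all_ids).astype(np.intp)
        times = np.concatenate(all_steps) * dt
    else:
        ids = np.empty(0, dtype=np.intp)
        times = np.empty(0)
    raster = SpikeRaster(ids, times, duration_ms)

    final = net.synapses.copy()
    final.w = W[syn0.pre, syn0.post].copy()
    return SimulationResult(
        raster=raster,
        weight_times_ms=snap_times[:snap_count],
        weight_history=snap_buf[:snap_count],
        final_weights=final,
        topology=net.with_weights(final.w),
    )
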