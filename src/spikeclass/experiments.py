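"""Experiment pipelines.

Three families: single-neuron temporal coding (weights vs. rank of spiking,
familiar = first half of the pulse sequence), single-neuron rate coding
(weights vs. presynaptic rate, unknown = rate-reversed pattern), and the
two-layer EMG classifier with unsupervised or supervised (teacher-stimulated)
competitive learning, plus the gradual-response and weight/amplitude-profile
analyses of the trained network.

All evaluation phases run with learning disabled; reported rates are spike
counts divided by window length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .emg import EMGRecording, default_profiles, generate_emg, mav
from .network import (
    NetworkTopology,
    SimulationResult,
    SpikeRaster,
    build_single_neuron_testbed,
    simulate,
)
from .plasticity import Rule
from .stimulation import (
    DEFAULT_RATES_HZ,
    emg_protocol,
    merge_protocols,
    rate_pattern,
    reversed_rate_pattern,
    teacher_stimulus,
    temporal_familiar_unknown_split,
    temporal_pattern,
)

__all__ = [
    "CodingExperimentReport",
    "ClassifierReport",
    "run_temporal_coding",
    "run_rate_coding",
    "train_unsupervised",
    "train_supervised",
    "assign_labels",
    "optimal_assignment",
    "classification_accuracy",
    "gradual_response",
    "weight_amplitude_profile",
]


@dataclass
class CodingExperimentReport:
    """Outcome of a single-neuron coding experiment."""

    rule: Rule
    final_weights: np.ndarray          # indexed by presynaptic rank / rate slot
    condition: np.ndarray              # spike rank (temporal) or rate in Hz (rate)
    familiar_hz: float
    unknown_hz: float
    correlation: float                 # Spearman rho of (weights, condition)

    @property
    def selectivity_ratio(self) -> float:
        """familiar/unknown response ratio; inf if only the familiar pattern
        evokes spikes, nan if neither does."""
        if self.unknown_hz > 0:
            return self.familiar_hz / self.unknown_hz
        return math.inf if self.familiar_hz > 0 else math.nan


@dataclass
class ClassifierReport:
    assignment: dict[str, int]          # gesture -> classifier neuron id
    per_gesture_accuracy: dict[str, float]
    overall_accuracy: float
    winner_sequence: list[Optional[int]]
    response_matrix: np.ndarray         # (n_classifiers, n_gestures), Hz
    gestures: list[str]
    classifier_ids: list[int]
    degenerate: bool = False


def _post_rate(raster: SpikeRaster, neuron_id: int, duration_ms: float) -> float:
    return len(raster.spikes_of(neuron_id)) / (duration_ms / 1000.0)


def run_temporal_coding(
    delta_t: float,
    rule: Rule | str = Rule.PAIR,
    train_s: float = 1000.0,
    test_s: float = 30.0,
    n_pre: int = 10,
    dt: float = 0.5,
    seed: int = 0,
    plasticity=None,
) -> CodingExperimentReport:
    """Train the 10-to-1 testbed on a repeating pulse sequence with inter-pulse
    interval ``delta_t`` (1 Hz repetition), then measure frozen responses to
    the familiar (first-half) and unknown (second-half) sub-patterns."""
    rule = Rule(rule)
    # fully potentiated start: the pattern must initially drive the neuron to
    # fire within the pulse sequence so depression can carve the rank order
    net = build_single_neuron_testbed(
        n_pre, rule, plasticity=plasticity, init_weight_range=(1.0, 1.0), seed=seed
    )
    post = n_pre
    train = temporal_pattern(delta_t, n_pre, 1.0, train_s * 1000.0)
    res = simulate(net, train, train_s * 1000.0, dt=dt, learning=True, seed=seed + 1)
    trained = res.topology
    probe = temporal_pattern(delta_t, n_pre, 1.0, test_s * 1000.0)
    fam, unk = temporal_familiar_unknown_split(probe)
    r_fam = simulate(trained, fam, test_s * 1000.0, dt=dt, learning=False, seed=seed + 2)
    r_unk = simulate(trained, unk, test_s * 1000.0, dt=dt, learning=False, seed=seed + 3)
    w = res.final_weights.w
    ranks = np.arange(1, n_pre + 1, dtype=float)
    rho = float(stats.spearmanr(w, ranks).statistic)
    return CodingExperimentReport(
        rule=rule,
        final_weights=w,
        condition=ranks,
        familiar_hz=_post_rate(r_fam.raster, post, test_s * 1000.0),
        unknown_hz=_post_rate(r_unk.raster, post, test_s * 1000.0),
        correlation=rho,
    )


def run_rate_coding(
    rule: Rule | str = Rule.TRIPLET_FORGETTING,
    rates_hz: Sequence[float] = DEFAULT_RATES_HZ,
    train_s: float = 1000.0,
    test_s: float = 30.0,
    dt: float = 0.5,
    seed: int = 0,
    plasticity=None,
) -> CodingExperimentReport:
    """Train the testbed on Poisson trains at the given per-input mean rates,
    then measure frozen responses to a familiar (same rates) and an unknown
    (rate-reversed) pattern."""
    rule = Rule(rule)
    rates = [float(r) for r in rates_hz]
    n_pre = len(rates)
    # mid-range start: the steady-state weight-rate relation is probed without
    # the downward transient a saturated start would superimpose
    net = build_single_neuron_testbed(
        n_pre, rule, plasticity=plasticity, init_weight_range=(0.5, 0.5), seed=seed
    )
    post = n_pre
    train = rate_pattern(rates, train_s * 1000.0, seed=seed + 10)
    res = simulate(net, train, train_s * 1000.0, dt=dt, learning=True, seed=seed + 1)
    trained = res.topology
    fam = rate_pattern(rates, test_s * 1000.0, seed=seed + 11)
    unk = rate_pattern(reversed_rate_pattern(rates), test_s * 1000.0, seed=seed + 12)
    r_fam = simulate(trained, fam, test_s * 1000.0, dt=dt, learning=False, seed=seed + 2)
    r_unk = simulate(trained, unk, test_s * 1000.0, dt=dt, learning=False, seed=seed + 3)
    w = res.final_weights.w
    rho = float(stats.spearmanr(w, rates).statistic)
    return CodingExperimentReport(
        rule=rule,
        final_weights=w,
        condition=np.asarray(rates),
        familiar_hz=_post_rate(r_fam.raster, post, test_s * 1000.0),
        unknown_hz=_post_rate(r_unk.raster, post, test_s * 1000.0),
        correlation=rho,
    )


def train_unsupervised(
    net: NetworkTopology,
    emg: EMGRecording,
    seed: int = 0,
    dt: float = 0.5,
    k: float = 2.0e6,
) -> tuple[NetworkTopology, SimulationResult]:
    """Online unsupervised learning: EMG-derived currents drive the sensory
    layer for the whole recording with plasticity active. Labels are never
    used during training."""
    protocol = emg_protocol(emg, k=k)
    res = simulate(net, protocol, emg.duration_s * 1000.0, dt=dt, learning=True, seed=seed)
    return res.topology, res


def train_supervised(
    net: NetworkTopology,
    emg: EMGRecording,
    targets: dict[str, int],
    seed: int = 0,
    dt: float = 0.5,
    k: float = 2.0e6,
    teacher_rate_hz: float = 40.0,
) -> tuple[NetworkTopology, SimulationResult]:
    """Supervised learning: during each labelled gesture segment a 40 Hz
    teacher electrode drives the mapped classifier; plasticity stays active
    throughout, including between teacher stimuli."""
    if len(set(targets.values())) != len(targets):
        raise ValueError("target map must be a bijection (distinct classifiers)")
    classifier_ids = set(net.ids_in_layer("classifier"))
    if not set(targets.values()) <= classifier_ids:
        raise ValueError("target map must point at classifier neurons")
    duration_ms = emg.duration_s * 1000.0
    protos = [emg_protocol(emg, k=k)]
    extra = {}
    for gesture, cid in targets.items():
        intervals = emg.label_intervals_ms(gesture)
        protos.append(
            teacher_stimulus(cid, intervals, duration_ms, rate_hz=teacher_rate_hz)
        )
        extra[cid] = cid
    proto = merge_protocols(*protos)
    res = simulate(
        net, proto, duration_ms, dt=dt, learning=True, seed=seed, extra_bindings=extra
    )
    return res.topology, res


def optimal_assignment(
    response_matrix: np.ndarray,
    classifier_ids: Sequence[int],
    gestures: Sequence[str],
) -> dict[str, int]:
    """Bijective gesture -> classifier assignment maximizing the total
    own-class spike rate, by exhaustive search over permutations."""
    R = np.asarray(response_matrix, dtype=float)
    n = len(gestures)
    if R.shape != (len(classifier_ids), n):
        raise ValueError("response matrix shape mismatch")
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(len(classifier_ids)), n):
        score = sum(R[perm[j], j] for j in range(n))
        if score > best + 1e-12:
            best, best_perm = score, perm
    return {g: int(classifier_ids[best_perm[j]]) for j, g in enumerate(gestures)}


def _response_matrix(
    raster: SpikeRaster, emg: EMGRecording, classifier_ids: Sequence[int],
    gestures: Sequence[str],
) -> np.ndarray:
    """Spike rate (Hz) of each classifier during each gesture's samples."""
    fs = emg.fs_hz
    spike_samples = {
        cid: np.minimum(
            (raster.spikes_of(cid) * fs / 1000.0).astype(np.int64), emg.n_samples - 1
        )
        for cid in classifier_ids
    }
    R = np.zeros((len(classifier_ids), len(gestures)))
    for j, gesture in enumerate(gestures):
        mask = emg.labels == gesture
        dur_s = mask.sum() / fs
        if dur_s == 0:
            R[:, j] = np.nan
            continue
        for i, cid in enumerate(classifier_ids):
            R[i, j] = mask[spike_samples[cid]].sum() / dur_s
    return R


def assign_labels(
    trained: NetworkTopology,
    emg: EMGRecording,
    seed: int = 0,
    dt: float = 0.5,
    k: float = 2.0e6,
) -> tuple[dict[str, int], np.ndarray, bool]:
    """Run the trained network frozen on a labelled recording and assign each
    gesture the classifier it excites most (exhaustive over permutations).

    Returns (assignment, response_matrix, degenerate); a degenerate (all-zero)
    response yields a deterministic but arbitrary assignment and is flagged.
    """
    classifier_ids = trained.ids_in_layer("classifier")
    gestures = sorted(set(emg.labels.tolist()))
    res = simulate(
        trained, emg_protocol(emg, k=k), emg.duration_s * 1000.0,
        dt=dt, learning=False, seed=seed,
    )
    R = _response_matrix(res.raster, emg, classifier_ids, gestures)
    degenerate = bool(np.nansum(R) == 0)
    return optimal_assignment(np.nan_to_num(R), classifier_ids, gestures), R, degenerate


def classification_accuracy(
    raster: SpikeRaster,
    emg: EMGRecording,
    assignment: dict[str, int],
    window_ms: float = 500.0,
    exclude_transition_ms: float = 0.0,
) -> ClassifierReport:
    """Accuracy per the rate-ratio definition: for each gesture, the assigned
    classifier's spike rate during that gesture divided by the summed rates of
    all classifiers; overall accuracy is the duration-weighted mean.

    ``exclude_transition_ms`` optionally drops spikes within that many ms
    after a label change (errors cluster at movement changes).
    """
    if len(set(assignment.values())) != len(assignment):
        raise ValueError("assignment must be bijective")
    gestures = sorted(assignment)
    classifier_ids = sorted(assignment.values())
    fs = emg.fs_hz
    valid = np.ones(emg.n_samples, dtype=bool)
    if exclude_transition_ms > 0:
        k_excl = int(round(exclude_transition_ms / 1000.0 * fs))
        changes = np.flatnonzero(emg.labels[1:] != emg.labels[:-1]) + 1
        for ch in changes:
            valid[ch : ch + k_excl] = False

    counts = np.zeros((len(classifier_ids), len(gestures)))
    durations = np.zeros(len(gestures))
    for j, gesture in enumerate(gestures):
        mask = (emg.labels == gesture) & valid
        durations[j] = mask.sum() / fs
        for i, cid in enumerate(classifier_ids):
            s = np.minimum(
                (raster.spikes_of(cid) * fs / 1000.0).astype(np.int64), emg.n_samples - 1
            )
            counts[i, j] = mask[s].sum()

    per_gesture: dict[str, float] = {}
    weights, accs = [], []
    for j, gesture in enumerate(gestures):
        total = counts[:, j].sum()
        if total == 0 or durations[j] == 0:
            per_gesture[gesture] = math.nan
            continue
        own = counts[classifier_ids.index(assignment[gesture]), j]
        acc = own / total
        per_gesture[gesture] = acc
        weights.append(durations[j])
        accs.append(acc)
    overall = float(np.average(accs, weights=weights)) if accs else math.nan

    # per-window winner sequence
    winners: list[Optional[int]] = []
    duration_ms = emg.duration_s * 1000.0
    n_win = int(math.ceil(duration_ms / window_ms))
    spike_times = {cid: raster.spikes_of(cid) for cid in classifier_ids}
    for wdx in range(n_win):
        t0, t1 = wdx * window_ms, (wdx + 1) * window_ms
        c = [np.count_nonzero((spike_times[cid] >= t0) & (spike_times[cid] < t1))
             for cid in classifier_ids]
        winners.append(classifier_ids[int(np.argmax(c))] if max(c) > 0 else None)

    R = counts / np.where(durations > 0, durations, np.nan)
    return ClassifierReport(
        assignment=dict(assignment),
        per_gesture_accuracy=per_gesture,
        overall_accuracy=overall,
        winner_sequence=winners,
        response_matrix=R,
        gestures=gestures,
        classifier_ids=classifier_ids,
    )


def gradual_response(
    trained: NetworkTopology,
    assignment: dict[str, int],
    gesture: str = "flexion",
    effort_levels: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    level_s: float = 10.0,
    profiles=None,
    seed: int = 0,
    dt: float = 0.5,
    k: float = 2.0e6,
) -> dict:
    """Present one gesture at several effort levels (10 s each, frozen
    weights); relate the winning classifier's rate to the segment MAV.

    Returns per-level MAV and rate plus the Pearson r and linear-fit slope.
    """
    if len(effort_levels) < 3:
        raise ValueError("need at least 3 effort levels for the linear fit")
    profiles = profiles or default_profiles()
    cid = assignment[gesture]
    mavs, rates = [], []
    for i, eff in enumerate(effort_levels):
        rec = generate_emg([(gesture, level_s, float(eff))], profiles, seed=seed + i)
        res = simulate(
            trained, emg_protocol(rec, k=k), level_s * 1000.0,
            dt=dt, learning=False, seed=seed + 100 + i,
        )
        mavs.append(mav(rec))
        rates.append(_post_rate(res.raster, cid, level_s * 1000.0))
    fit = stats.linregress(mavs, rates)
    return {
        "effort_levels": list(effort_levels),
        "mav_v": mavs,
        "rate_hz": rates,
        "pearson_r": float(fit.rvalue),
        "slope_hz_per_v": float(fit.slope),
        "monotone": bool(np.all(np.diff(rates) >= 0)),
    }


def weight_amplitude_profile(
    trained: NetworkTopology,
    emg: EMGRecording,
    assignment: dict[str, int],
) -> dict[str, float]:
    """Pearson correlation, per movement gesture, between the per-channel mean
    rectified EMG amplitude and the learned weights from the corresponding
    sensory neurons to that gesture's classifier."""
    sensory = trained.ids_in_layer("sensory")
    syn = trained.synapses
    out: dict[str, float] = {}
    for gesture, cid in assignment.items():
        if gesture == "rest":
            continue
        mask = emg.labels == gesture
        if not mask.any():
            continue
        amps = np.abs(emg.samples[:, mask]).mean(axis=1)
        amps = amps / amps.max()
        w = np.array([
            syn.w[(syn.pre == s) & (syn.post == cid)][0] for s in sensory
        ])
        out[gesture] = float(stats.pearsonr(amps, w).statistic)
    return out
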