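"""Synaptic traces and the three learning rules.

Every trace obeys

    dy/dt = -y / tau + sum_k delta(t - t_k)

i.e. exponential decay between spikes of its source neuron and a unit jump at
each spike. Four traces are kept per neuron:

* ``y_syn``  (tau = 100 ms)  — synaptic output, the amount of transmitter a
  presynaptic neuron releases; enters the synaptic current.
* ``y1``     (tau1 = 10 ms)  — fast plasticity trace.
* ``y2``     (tau2 = 100 ms) — slow plasticity trace (triplet rule).
* ``y_avg``  (tau_o = 100 ms)— averaged activity, drives forgetting.

Weight updates use the multiplicative soft bounds

    F+(w) = lambda (1 - w),   F-(w) = lambda alpha w

so that plastic weights stay inside [0, 1]:

* pair LTP  (at a post spike):   dw = +F+(w) * y1_pre
* pair LTD  (at a pre  spike):   dw = -F-(w) * y1_post
* triplet LTP (at a post spike): dw = +F+(w) * y1_pre * y2_post
  where y2_post is read *before* the current spike's own increment
* forgetting (continuous):       dw/dt = -w * y_avg_post / tau_f

At a spike, the event ordering is: decay all traces, apply the weight updates
reading the post-decay / pre-increment traces, then increment the traces of
the neurons that spiked. Simultaneous pre and post spikes apply LTD first,
then LTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Rule",
    "PlasticityParams",
    "Trace",
    "decay_and_bump_trace",
    "bound_factors",
    "pair_ltp_on_post_spike",
    "pair_ltd_on_pre_spike",
    "triplet_ltp_on_post_spike",
    "forgetting_step",
    "replay_events",
]


class Rule(str, Enum):
    """Which learning rule a plastic synapse follows."""

    NONE = "none"
    PAIR = "pair"
    TRIPLET = "triplet"
    TRIPLET_FORGETTING = "triplet+forgetting"


@dataclass(frozen=True)
class PlasticityParams:
    """Rule parameters shared by a set of synapses.

    lam    : learning rate lambda (default 0.001)
    alpha  : LTD/LTP asymmetry (default 1)
    tau1   : fast trace decay (ms, default 10)
    tau2   : slow trace decay (ms, default 100)
    tau_o  : averaged-activity trace decay (ms, default 100)
    tau_f  : forgetting decay time of weights (ms). Sets the synaptic-
             competition strength; the default is calibrated for the
             single-neuron rate-coding protocol so forgetting balances the
             lambda-scale potentiation over its 1000 s course (the classifier
             network uses a faster preset matched to its one-minute training;
             see the methods note).
    tau_syn: synaptic-output trace decay (ms, default 100)
    """

    lam: float = 0.001
    alpha: float = 1.0
    tau1: float = 10.0
    tau2: float = 100.0
    tau_o: float = 100.0
    tau_f: float = 1.0e6
    tau_syn: float = 100.0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau_o", "tau_f", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lam < 0 or self.alpha < 0:
            raise ValueError("lambda and alpha must be >= 0")


@dataclass
class Trace:
    """Exponentially decaying local variable with unit jumps at spikes."""

    value: float = 0.0
    tau: float = 100.0
    increment: float = 1.0


def decay_and_bump_trace(trace: Trace, dt: float, spiked: bool = False) -> Trace:
    """Advance a trace one step: exact exponential decay, then (if the source
    neuron spiked this step) add the increment."""
    if trace.tau <= 0:
        raise ValueError(f"trace tau must be > 0, got {trace.tau}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    value = trace.value * math.exp(-dt / trace.tau)
    if spiked:
        value += trace.increment
    return Trace(value=value, tau=trace.tau, increment=trace.increment)


def bound_factors(w: float, lam: float, alpha: float) -> tuple[float, float]:
    """Multiplicative soft-bound factors (F+, F-) = (lambda(1-w), lambda*alpha*w)."""
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"plastic weight must lie in [0, 1], got {w}")
    return lam * (1.0 - w), lam * alpha * w


def pair_ltp_on_post_spike(w: float, y_pre1: float, lam: float, alpha: float = 1.0) -> float:
    """Weight increment at a postsynaptic spike, pair rule: F+(w) * y1_pre."""
    f_plus, _ = bound_factors(w, lam, alpha)
    return f_plus * y_pre1


def pair_ltd_on_pre_spike(w: float, y_post1: float, lam: float, alpha: float = 1.0) -> float:
    """Weight decrement at a presynaptic spike, pair rule: -F-(w) * y1_post."""
    _, f_minus = bound_factors(w, lam, alpha)
    return -f_minus * y_post1


def triplet_ltp_on_post_spike(
    w: float, y_pre1: float, y_post2: float, lam: float, alpha: float = 1.0
) -> float:
    """Weight increment at a postsynaptic spike, triplet rule:
    F+(w) * y1_pre * y2_post, with y2_post read before the spike's own bump."""
    f_plus, _ = bound_factors(w, lam, alpha)
    return f_plus * y_pre1 * y_post2


def forgetting_step(w: float, y_post_avg: float, dt: float, tau_f: float) -> float:
    """Integrate dw/dt = -w * y_avg / tau_f exactly over one step; returns the
    new weight w * exp(-y_avg * dt / tau_f) (y_avg held constant over dt)."""
    if tau_f <= 0:
        raise ValueError(f"tau_f must be > 0, got {tau_f}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if y_post_avg < 0:
        raise ValueError("activity trace must be >= 0")
    return w * math.exp(-y_post_avg * dt / tau_f)


def replay_events(
    events: list[tuple[float, str]],
    rule: Rule | str = Rule.PAIR,
    params: PlasticityParams | None = None,
    w0: float = 0.0,
    mode: str = "event",
    dt: float = 0.5,
) -> float:
    """Evolve a single synapse's weight through a scripted spike sequence.

    events : list of (time_ms, side) with side in {"pre", "post"}, any order.
    mode   : "event" uses exact exponentials between spikes (the event-driven
             reference); "stepped" advances traces on the dt grid exactly as
             the network engine does (spike times are snapped to the grid).

    Forgetting (rule = triplet+forgetting) is integrated continuously in both
    modes. Returns the final weight.
    """
    rule = Rule(rule)
    p = params or PlasticityParams()
    evs = sorted(events, key=lambda e: (e[0], 0 if e[1] == "pre" else 1))
    for _, side in evs:
        if side not in ("pre", "post"):
            raise ValueError(f"event side must be 'pre' or 'post', got {side!r}")

    w = float(w0)
    y1 = {"pre": 0.0, "post": 0.0}
    y2 = {"pre": 0.0, "post": 0.0}
    y_avg_post = 0.0

    def apply_updates(spiked_pre: bool, spiked_post: bool) -> None:
        # LTD first, then LTP, both reading pre-increment traces
        nonlocal w
        if rule is Rule.NONE:
            return
        if spiked_pre:
            w = min(1.0, max(0.0, w + pair_ltd_on_pre_spike(w, y1["post"], p.lam, p.alpha)))
        if spiked_post:
            if rule is Rule.PAIR:
                dw = pair_ltp_on_post_spike(w, y1["pre"], p.lam, p.alpha)
            else:
                dw = triplet_ltp_on_post_spike(w, y1["pre"], y2["post"], p.lam, p.alpha)
            w = min(1.0, max(0.0, w + dw))

    def bump(spiked_pre: bool, spiked_post: bool) -> None:
        nonlocal y_avg_post
        for side, s in (("pre", spiked_pre), ("post", spiked_post)):
            if s:
                y1[side] += 1.0
                y2[side] += 1.0
        if spiked_post:
            y_avg_post += 1.0

    def decay(span: float) -> None:
        nonlocal y_avg_post, w
        if span <= 0:
            return
        for side in ("pre", "post"):
            y1[side] *= math.exp(-span / p.tau1)
            y2[side] *= math.exp(-span / p.tau2)
        if rule is Rule.TRIPLET_FORGETTING:
            # exact integral of dw/dt = -w y(t)/tau_f with y decaying at tau_o
            integral = y_avg_post * p.tau_o * (1.0 - math.exp(-span / p.tau_o))
            w *= math.exp(-integral / p.tau_f)
        y_avg_post *= math.exp(-span / p.tau_o)

    if mode == "event":
        t_prev = 0.0
        i = 0
        while i < len(evs):
            t = evs[i][0]
            decay(t - t_prev)
            here = [e[1] for e in evs if e[0] == t]
            spiked_pre, spiked_post = "pre" in here, "post" in here
            apply_updates(spiked_pre, spiked_post)
            bump(spiked_pre, spiked_post)
            t_prev = t
            i += sum(1 for e in evs if e[0] == t)
        return w
    if mode == "stepped":
        if not evs:
            return w
        n_steps = int(math.ceil(evs[-1][0] / dt)) + 1
        pre_steps = {int(round(t / dt)) for t, s in evs if s == "pre"}
        post_steps = {int(round(t / dt)) for t, s in evs if s == "post"}
        for k in range(n_steps):
            for side in ("pre", "post"):
                y1[side] *= math.exp(-dt / p.tau1)
                y2[side] *= math.exp(-dt / p.tau2)
            y_avg_post *= math.exp(-dt / p.tau_o)
            spiked_pre, spiked_post = k in pre_steps, k in post_steps
            apply_updates(spiked_pre, spiked_post)
            if rule is Rule.TRIPLET_FORGETTING:
                w = forgetting_step(w, y_avg_post, dt, p.tau_f)
            bump(spiked_pre, spiked_post)
        return w
    raise ValueError(f"mode must be 'event' or 'stepped', got {mode!r}")
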