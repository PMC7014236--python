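"""Traces, soft-bound factors, and the three learning rules against
closed-form exponential oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeclass.plasticity import (
    PlasticityParams,
    Rule,
    Trace,
    bound_factors,
    decay_and_bump_trace,
    forgetting_step,
    pair_ltd_on_pre_spike,
    pair_ltp_on_post_spike,
    replay_events,
    triplet_ltp_on_post_spike,
)


class TestTrace:
    def test_zero_fixed_point(self):
        t = decay_and_bump_trace(Trace(0.0, tau=100.0), 0.5, spiked=False)
        assert t.value == 0.0

    def test_exponential_decay_closed_form(self):
        t = Trace(1.0, tau=100.0)
        for _ in range(200):  # 100 ms at dt = 0.5
            t = decay_and_bump_trace(t, 0.5)
        assert t.value == pytest.approx(math.exp(-1.0), abs=1e-3)

    def test_unit_jump(self):
        t = decay_and_bump_trace(Trace(0.0, tau=100.0), 0.5, spiked=True)
        assert t.value == 1.0

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            decay_and_bump_trace(Trace(0.0, tau=0.0), 0.5)


class TestBoundFactors:
    @pytest.mark.parametrize(
        "w,expected",
        [(1.0, (0.0, 0.001)), (0.0, (0.001, 0.0)), (0.5, (0.0005, 0.0005))],
    )
    def test_multiplicative_rule(self, w, expected):
        fp, fm = bound_factors(w, 0.001, 1.0)
        assert (fp, fm) == pytest.approx(expected)

    def test_weight_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            bound_factors(1.2, 0.001, 1.0)


class TestPairRule:
    def test_ltp_closed_form(self):
        # pre spike 10 ms before post, tau1 = 10 ms, w = 0
        dw = pair_ltp_on_post_spike(0.0, math.exp(-1.0), lam=0.001)
        assert dw == pytest.approx(0.001 * math.exp(-1.0), abs=1e-9)
        assert dw == pytest.approx(3.679e-4, abs=1e-6)

    def test_ltp_zero_cases(self):
        assert pair_ltp_on_post_spike(0.5, 0.0, 0.001) == 0.0
        assert pair_ltp_on_post_spike(1.0, 0.9, 0.001) == 0.0

    def test_ltd_closed_form(self):
        dw = pair_ltd_on_pre_spike(0.5, math.exp(-1.0), lam=0.001, alpha=1.0)
        assert dw == pytest.approx(-1.839e-4, abs=1e-6)

    def test_ltd_zero_cases(self):
        assert pair_ltd_on_pre_spike(0.0, 0.9, 0.001) == 0.0
        assert pair_ltd_on_pre_spike(0.5, 0.0, 0.001) == 0.0

    def test_antisymmetry_at_midpoint(self):
        # equal lags, alpha = 1, w = 0.5: equal magnitude, opposite sign
        y = math.exp(-0.7)
        ltp = pair_ltp_on_post_spike(0.5, y, 0.001)
        ltd = pair_ltd_on_pre_spike(0.5, y, 0.001, 1.0)
        assert ltp == pytest.approx(-ltd)


class TestTripletRule:
    def test_requires_prior_post_spike(self):
        assert triplet_ltp_on_post_spike(0.0, 0.9, 0.0, 0.001) == 0.0

    def test_closed_form_product_of_traces(self):
        # pre spike 10 ms before (tau1=10), previous post 50 ms before (tau2=100)
        dw = triplet_ltp_on_post_spike(0.0, math.exp(-1.0), math.exp(-0.5), 0.001)
        assert dw == pytest.approx(0.001 * math.exp(-1.5), abs=1e-9)
        assert dw == pytest.approx(2.231e-4, abs=1e-6)

    def test_ceiling(self):
        assert triplet_ltp_on_post_spike(1.0, 0.9, 0.9, 0.001) == 0.0


class TestForgetting:
    def test_silent_neuron_forgets_nothing(self):
        assert forgetting_step(0.7, 0.0, 0.5, 10.0) == 0.7

    def test_closed_form_decay(self):
        # constant activity trace 1, tau_f = 10 ms: after 10 ms w = e^-1
        w = 1.0
        for _ in range(20):
            w = forgetting_step(w, 1.0, 0.5, 10.0)
        assert w == pytest.approx(math.exp(-1.0), abs=1e-3)

    def test_floor_fixed_point(self):
        assert forgetting_step(0.0, 2.0, 0.5, 10.0) == 0.0

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            forgetting_step(0.5, 1.0, 0.5, 0.0)


class TestReplay:
    """Scripted spike sequences through the event-driven and stepped updaters."""

    def test_pair_pre_post_event_mode_matches_closed_form(self):
        w = replay_events([(0.0, "pre"), (10.0, "post")], Rule.PAIR, w0=0.0)
        assert w == pytest.approx(0.001 * math.exp(-1.0), abs=1e-6)

    def test_pair_pre_post_stepped_matches_closed_form_on_grid(self):
        w = replay_events([(0.0, "pre"), (10.0, "post")], Rule.PAIR, w0=0.0,
                          mode="stepped", dt=0.5)
        assert w == pytest.approx(0.001 * math.exp(-1.0), abs=1e-6)

    def test_triplet_sequence_both_modes(self):
        events = [(0.0, "post"), (40.0, "pre"), (50.0, "post")]
        # at t=50: y1_pre = e^-1, y2_post = e^-0.5 (pre-increment), plus the
        # LTD at t=40 reading y1_post = e^-4 of the t=0 post spike at w0=0
        expected_ltd = 0.0  # w0 = 0 -> F- = 0
        expected = 0.001 * math.exp(-1.0) * math.exp(-0.5)
        for mode in ("event", "stepped"):
            w = replay_events(events, Rule.TRIPLET, w0=0.0, mode=mode)
            assert w == pytest.approx(expected + expected_ltd, abs=1e-6), mode

    def test_stepped_converges_to_event_mode(self):
        """Off-grid spike times: stepped error shrinks with dt."""
        events = [(0.3, "pre"), (7.9, "post"), (13.1, "pre"), (20.7, "post")]
        exact = replay_events(events, Rule.TRIPLET, w0=0.4, mode="event")
        errs = []
        for dt in (0.5, 0.25, 0.125):
            approx = replay_events(events, Rule.TRIPLET, w0=0.4, mode="stepped", dt=dt)
            errs.append(abs(approx - exact))
        assert errs[0] < 5e-5
        assert errs[2] < errs[0]

    def test_forgetting_between_events(self):
        # one post spike, then 100 ms of silence: the activity trace decays
        # with tau_o while the weight decays by exp(-integral y / tau_f)
        p = PlasticityParams(tau_f=1000.0)
        w = replay_events([(0.0, "post"), (100.0, "pre")],
                          Rule.TRIPLET_FORGETTING, params=p, w0=1.0)
        integral = 100.0 * (1.0 - math.exp(-1.0))  # tau_o * (1 - e^-span/tau_o)
        # the pre spike at t=100 applies LTD with y1_post = e^-10 ~ 5e-5
        expected = math.exp(-integral / 1000.0)
        expected -= 0.001 * expected * math.exp(-10.0)
        assert w == pytest.approx(expected, abs=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(0.0, 500.0), st.sampled_from(["pre", "post"])),
        min_size=0, max_size=40,
    ),
    st.sampled_from([Rule.PAIR, Rule.TRIPLET, Rule.TRIPLET_FORGETTING]),
    st.floats(0.0, 1.0),
)
def test_weights_stay_bounded_under_any_spike_sequence(events, rule, w0):
    """Multiplicative bounds plus forgetting keep w in [0, 1] always."""
    for mode in ("event", "stepped"):
        w = replay_events(events, rule, w0=w0, mode=mode)
        assert 0.0 <= w <= 1.0
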