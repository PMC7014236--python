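"""Topology construction and simulation-engine contracts."""

import numpy as np
import pytest

from spikeclass.network import (
    NetworkTopology,
    Neuron,
    SynapseSet,
    build_emg_classifier_network,
    build_single_neuron_testbed,
    simulate,
)
from spikeclass.neurons import REGULAR_SPIKING, NeuronParams
from spikeclass.plasticity import Rule
from spikeclass.stimulation import (
    ContinuousDrive,
    PulseTrain,
    StimulusProtocol,
    rate_pattern,
    temporal_pattern,
)


def _single(params=None, binding=True):
    empty = SynapseSet(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0, bool))
    return NetworkTopology(
        [Neuron(0, params or REGULAR_SPIKING, "postsynaptic")], empty,
        {0: 0} if binding else {},
    )


class TestTestbed:
    def test_counts(self):
        net = build_single_neuron_testbed(10, Rule.PAIR)
        assert net.n_neurons == 11
        assert len(net.synapses) == 10
        assert net.synapses.plastic.all()
        assert len(net.stimulus_bindings) == 10

    def test_minimal(self):
        net = build_single_neuron_testbed(1, Rule.PAIR)
        assert net.n_neurons == 2 and len(net.synapses) == 1

    def test_zero_presynaptic_rejected(self):
        with pytest.raises(ValueError):
            build_single_neuron_testbed(0, Rule.PAIR)

    def test_initial_weights_in_range(self):
        net = build_single_neuron_testbed(10, Rule.PAIR, init_weight_range=(0.3, 0.4))
        assert (net.synapses.w >= 0.3).all() and (net.synapses.w <= 0.4).all()


class TestClassifierTopology:
    def test_default_counts(self):
        net = build_emg_classifier_network()
        assert net.n_neurons == 8 + 8 + 1 + 3 + 3
        assert net.synapses.plastic.sum() == 9 * 3

    def test_scaling_with_classes(self):
        net = build_emg_classifier_network(n_classes=2)
        assert len(net.ids_in_layer("classifier")) == 2
        assert net.synapses.plastic.sum() == 18

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_emg_classifier_network(n_channels=1)
        with pytest.raises(ValueError):
            build_emg_classifier_network(n_classes=1)

    def test_lateral_inhibition_wiring(self):
        """Each classifier-inhibitory neuron inhibits all classifiers except
        its own driver, and inhibitory neurons are g = -2."""
        net = build_emg_classifier_network()
        cls = net.ids_in_layer("classifier")
        cinh = net.ids_in_layer("classifier_inhibitory")
        syn = net.synapses
        for i, inh in enumerate(cinh):
            targets = set(syn.post[syn.pre == inh].tolist())
            assert targets == set(cls) - {cls[i]}
        for n in net.neurons:
            if "inhibitory" in n.layer:
                assert n.params.g == -2.0

    def test_rest_detector_properties(self):
        net = build_emg_classifier_network()
        rest = net.ids_in_layer("rest_detector")
        assert len(rest) == 1
        rd = net.neurons[rest[0]]
        assert rd.params.D == 70.0
        # inhibited by every sensory-layer partner
        syn = net.synapses
        sinh = set(net.ids_in_layer("sensory_inhibitory"))
        pres = set(syn.pre[syn.post == rest[0]].tolist())
        assert sinh <= pres

    def test_no_self_synapses(self):
        net = build_emg_classifier_network()
        assert not np.any(net.synapses.pre == net.synapses.post)


class TestSimulate:
    def test_zero_duration(self):
        net = build_single_neuron_testbed(4, Rule.PAIR, seed=1)
        res = simulate(net, None, 0.0, seed=0)
        assert len(res.raster) == 0
        np.testing.assert_array_equal(res.final_weights.w, net.synapses.w)

    def test_learning_freeze(self):
        net = build_single_neuron_testbed(10, Rule.PAIR, seed=1)
        stim = temporal_pattern(5.0, 10, duration_ms=5000.0)
        res = simulate(net, stim, 5000.0, learning=False, seed=0)
        np.testing.assert_array_equal(res.final_weights.w, net.synapses.w)
        assert len(res.raster) > 0  # it did spike, weights still frozen

    def test_seed_determinism(self):
        net = build_single_neuron_testbed(10, Rule.TRIPLET, seed=1)
        stim = rate_pattern([5.0] * 10, 5000.0, seed=3)
        a = simulate(net, stim, 5000.0, learning=True, seed=42)
        b = simulate(net, stim, 5000.0, learning=True, seed=42)
        np.testing.assert_array_equal(a.raster.times_ms, b.raster.times_ms)
        np.testing.assert_array_equal(a.raster.neuron_ids, b.raster.neuron_ids)
        np.testing.assert_array_equal(a.final_weights.w, b.final_weights.w)

    def test_pulse_entrainment_one_to_one(self):
        net = _single(NeuronParams(D=0.0))
        stim = StimulusProtocol(
            [PulseTrain(0, np.arange(0.0, 10_000.0, 100.0))], 10_000.0
        )
        res = simulate(net, stim, 10_000.0, seed=0)
        assert len(res.raster) == 100

    def test_unknown_binding_rejected_before_stepping(self):
        net = _single(binding=False)
        stim = temporal_pattern(5.0, n=1, duration_ms=1000.0)
        with pytest.raises(KeyError):
            simulate(net, stim, 1000.0, seed=0)

    def test_weight_snapshots(self):
        net = build_single_neuron_testbed(10, Rule.PAIR, seed=1)
        stim = temporal_pattern(5.0, 10, duration_ms=3000.0)
        res = simulate(net, stim, 3000.0, seed=0, record_weights_every_ms=1000.0)
        assert res.weight_history.shape == (3, 10)
        assert (res.weight_times_ms == [0.0, 1000.0, 2000.0]).all()
        np.testing.assert_array_equal(res.weight_history[0], net.synapses.w)

    def test_learning_locality(self):
        """Synapses onto a postsynaptic neuron that never fires are unchanged."""
        net = build_single_neuron_testbed(
            10, Rule.TRIPLET_FORGETTING, init_weight_range=(0.05, 0.05),
            ordinary_D=0.0, seed=1,
        )
        # weak drive through near-zero weights: the postsynaptic neuron stays
        # silent, so no LTP, no LTD (its traces stay 0) and no forgetting
        stim = rate_pattern([5.0] + [0.0] * 9, 10_000.0, seed=0)
        res = simulate(net, stim, 10_000.0, learning=True, seed=0)
        post = 10
        assert len(res.raster.spikes_of(post)) == 0
        # LTD requires a postsynaptic trace, also zero here
        np.testing.assert_array_equal(res.final_weights.w, net.synapses.w)

    def test_raster_is_time_ordered_and_bounded(self):
        net = build_emg_classifier_network(seed=0)
        res = simulate(net, None, 2000.0, seed=3)
        t = res.raster.times_ms
        assert (np.diff(t) >= 0).all()
        assert t.min() >= 0 and t.max() <= 2000.0


def test_python_fallback_kernel_matches_jitted_engine(monkeypatch):
    """The undecorated step kernel (used when the JIT compiler is absent)
    performs the identical update sequence: bit-identical rasters/weights."""
    import spikeclass.network as nw

    net = build_single_neuron_testbed(10, Rule.TRIPLET_FORGETTING, seed=1)
    stim = rate_pattern([5.0] * 10, 3000.0, seed=3)
    fast = simulate(net, stim, 3000.0, learning=True, seed=42)
    kernel = getattr(nw._step_range_fast, "py_func", nw._step_range_fast)
    monkeypatch.setattr(nw, "_step_range_fast", kernel)
    slow = simulate(net, stim, 3000.0, learning=True, seed=42)
    np.testing.assert_array_equal(fast.raster.times_ms, slow.raster.times_ms)
    np.testing.assert_array_equal(fast.final_weights.w, slow.final_weights.w)


class TestFuzzedBoundedness:
    @pytest.mark.parametrize("rule", [Rule.PAIR, Rule.TRIPLET, Rule.TRIPLET_FORGETTING])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_weights_bounded_under_random_drive(self, rule, seed):
        """60 s of randomized Poisson drive never pushes a plastic weight
        outside [0, 1] under any rule."""
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0.0, 50.0, size=10)
        net = build_single_neuron_testbed(
            10, rule, init_weight_range=(rng.uniform(0, 0.3), rng.uniform(0.7, 1.0)),
            seed=seed,
        )
        stim = rate_pattern(rates, 60_000.0, seed=seed + 1)
        res = simulate(net, stim, 60_000.0, learning=True, seed=seed + 2,
                       record_weights_every_ms=500.0)
        assert (res.weight_history >= 0).all() and (res.weight_history <= 1).all()
        assert (res.final_weights.w >= 0).all() and (res.final_weights.w <= 1).all()
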