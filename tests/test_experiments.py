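"""Label assignment, the rate-ratio accuracy metric, and training contracts."""

import itertools

import numpy as np
import pytest

from spikeclass.emg import EMGRecording, default_profiles, generate_emg, standard_schedule
from spikeclass.experiments import (
    classification_accuracy,
    optimal_assignment,
    train_supervised,
    train_unsupervised,
)
from spikeclass.network import SpikeRaster, build_emg_classifier_network


GESTURES = ["extension", "flexion", "rest"]
CIDS = [17, 18, 19]


class TestOptimalAssignment:
    def test_diagonal_dominant_matrix(self):
        R = np.array([[9.0, 1.0, 0.0], [0.5, 8.0, 1.0], [0.0, 0.2, 7.0]])
        a = optimal_assignment(R, CIDS, GESTURES)
        assert a == {"extension": 17, "flexion": 18, "rest": 19}

    def test_permuted_diagonal_recovers_inverse_permutation(self):
        R = np.zeros((3, 3))
        # classifier 0 responds to gesture 2, 1 -> 0, 2 -> 1
        R[0, 2], R[1, 0], R[2, 1] = 5.0, 6.0, 7.0
        a = optimal_assignment(R, CIDS, GESTURES)
        assert a == {"extension": 18, "flexion": 19, "rest": 17}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.uniform(0, 20, size=(3, 3))
        a = optimal_assignment(R, CIDS, GESTURES)
        # independent brute force over permutations
        best = max(
            itertools.permutations(range(3)),
            key=lambda p: sum(R[p[j], j] for j in range(3)),
        )
        assert a == {g: CIDS[best[j]] for j, g in enumerate(GESTURES)}


def _raster_from_rates(rates: dict[int, dict[str, float]], emg) -> SpikeRaster:
    """Regular spike trains per classifier at a given rate within each gesture."""
    fs = emg.fs_hz
    times, ids = [], []
    for cid, by_gesture in rates.items():
        for gesture, rate in by_gesture.items():
            if rate <= 0:
                continue
            for t0, t1 in emg.label_intervals_ms(gesture):
                n = int(round(rate * (t1 - t0) / 1000.0))
                for t in t0 + (t1 - t0) * np.arange(n) / max(n, 1):
                    times.append(t)
                    ids.append(cid)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        np.array(ids, dtype=int)[order], np.array(times)[order],
        emg.duration_s * 1000.0,
    )


@pytest.fixture(scope="module")
def labelled_recording():
    # 4 s segments so that half-integer rates are exactly realizable
    return generate_emg(
        standard_schedule(2, gesture_s=4.0), default_profiles(), seed=3
    )


class TestAccuracyMetric:
    def test_rate_ratio_definition(self, labelled_recording):
        # own classifier at 9 Hz, two others at 0.5 Hz -> accuracy 0.9
        rates = {
            17: {"extension": 9.0, "flexion": 0.5, "rest": 0.5},
            18: {"extension": 0.5, "flexion": 9.0, "rest": 0.5},
            19: {"extension": 0.5, "flexion": 0.5, "rest": 9.0},
        }
        raster = _raster_from_rates(rates, labelled_recording)
        assignment = {"extension": 17, "flexion": 18, "rest": 19}
        rep = classification_accuracy(raster, labelled_recording, assignment)
        for g in GESTURES:
            assert rep.per_gesture_accuracy[g] == pytest.approx(0.9, abs=0.02)
        assert rep.overall_accuracy == pytest.approx(0.9, abs=0.02)

    def test_only_own_classifier_fires(self, labelled_recording):
        rates = {17: {"extension": 5.0}, 18: {"flexion": 5.0}, 19: {"rest": 5.0}}
        raster = _raster_from_rates(rates, labelled_recording)
        rep = classification_accuracy(
            raster, labelled_recording, {"extension": 17, "flexion": 18, "rest": 19}
        )
        assert rep.overall_accuracy == pytest.approx(1.0)

    def test_chance_level_when_all_fire_equally(self, labelled_recording):
        rates = {c: {g: 6.0 for g in GESTURES} for c in CIDS}
        raster = _raster_from_rates(rates, labelled_recording)
        rep = classification_accuracy(
            raster, labelled_recording, {"extension": 17, "flexion": 18, "rest": 19}
        )
        assert rep.overall_accuracy == pytest.approx(1 / 3, abs=0.02)

    def test_invariant_to_global_rate_rescaling(self, labelled_recording):
        base = {
            17: {"extension": 8.0, "flexion": 2.0, "rest": 1.0},
            18: {"extension": 1.0, "flexion": 6.0, "rest": 2.0},
            19: {"extension": 1.0, "flexion": 1.0, "rest": 8.0},
        }
        scaled = {c: {g: 2 * r for g, r in by.items()} for c, by in base.items()}
        assignment = {"extension": 17, "flexion": 18, "rest": 19}
        a = classification_accuracy(
            _raster_from_rates(base, labelled_recording), labelled_recording, assignment
        )
        b = classification_accuracy(
            _raster_from_rates(scaled, labelled_recording), labelled_recording, assignment
        )
        assert a.overall_accuracy == pytest.approx(b.overall_accuracy, abs=0.02)

    def test_zero_spikes_in_gesture_reported_missing(self, labelled_recording):
        rates = {17: {"extension": 5.0}, 18: {"flexion": 5.0}, 19: {}}
        raster = _raster_from_rates(rates, labelled_recording)
        rep = classification_accuracy(
            raster, labelled_recording, {"extension": 17, "flexion": 18, "rest": 19}
        )
        assert np.isnan(rep.per_gesture_accuracy["rest"])

    def test_non_bijective_assignment_rejected(self, labelled_recording):
        raster = _raster_from_rates({17: {"rest": 1.0}}, labelled_recording)
        with pytest.raises(ValueError):
            classification_accuracy(
                raster, labelled_recording, {"extension": 17, "flexion": 17, "rest": 19}
            )


class TestTrainingContracts:
    def test_unsupervised_is_seed_deterministic(self, labelled_recording):
        net = build_emg_classifier_network(seed=0)
        a, _ = train_unsupervised(net, labelled_recording, seed=4)
        b, _ = train_unsupervised(net, labelled_recording, seed=4)
        np.testing.assert_array_equal(a.synapses.w, b.synapses.w)

    def test_supervised_requires_bijective_targets(self, labelled_recording):
        net = build_emg_classifier_network(seed=0)
        with pytest.raises(ValueError):
            train_supervised(
                net, labelled_recording,
                {"extension": 17, "flexion": 17, "rest": 19}, seed=0,
            )
        with pytest.raises(ValueError):
            train_supervised(
                net, labelled_recording,
                {"extension": 0, "flexion": 1, "rest": 2}, seed=0,  # not classifiers
            )

    def test_teacher_makes_target_win_during_its_gesture(self, labelled_recording):
        net = build_emg_classifier_network(seed=0)
        targets = {"extension": 17, "flexion": 18, "rest": 19}
        trained, res = train_supervised(net, labelled_recording, targets, seed=5)
        fs = labelled_recording.fs_hz
        for gesture, cid in targets.items():
            mask = labelled_recording.labels == gesture
            counts = {}
            for c in (17, 18, 19):
                s = np.minimum(
                    (res.raster.spikes_of(c) * fs / 1000.0).astype(int),
                    labelled_recording.n_samples - 1,
                )
                counts[c] = mask[s].sum()
            assert counts[cid] == max(counts.values())
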