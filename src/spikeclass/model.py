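"""Model/Results front-end for the EMG classifier.

:class:`EMGClassifierModel` wraps network construction, training, label
assignment and evaluation behind a fit() interface; the returned
:class:`EMGClassifierResults` carries the trained topology, the label
assignment, accuracies and diagnostics, with a text summary().
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .emg import EMGRecording, default_profiles, standard_schedule, generate_emg
from .experiments import (
    ClassifierReport,
    assign_labels,
    classification_accuracy,
    gradual_response,
    train_supervised,
    train_unsupervised,
    weight_amplitude_profile,
)
from .network import NetworkTopology, SimulationResult, build_emg_classifier_network, simulate
from .plasticity import PlasticityParams
from .stimulation import emg_protocol

__all__ = ["EMGClassifierModel", "EMGClassifierResults"]


@dataclass
class EMGClassifierResults:
    """Fitted-classifier results: trained weights, label assignment and the
    rate-ratio accuracy report on the evaluation recording."""

    model: "EMGClassifierModel"
    topology: NetworkTopology
    mode: str
    seed: int
    assignment: dict[str, int]
    report: ClassifierReport
    train_result: SimulationResult
    degenerate: bool

    @property
    def accuracy(self) -> float:
        return self.report.overall_accuracy

    @property
    def per_gesture_accuracy(self) -> dict[str, float]:
        return self.report.per_gesture_accuracy

    def input_weights(self, gesture: str) -> np.ndarray:
        """Learned weights from the sensory neurons (channel order) and the
        rest detector onto the gesture's classifier."""
        cid = self.assignment[gesture]
        syn = self.topology.synapses
        pres = self.topology.ids_in_layer("sensory") + self.topology.ids_in_layer(
            "rest_detector"
        )
        return np.array([syn.w[(syn.pre == p) & (syn.post == cid)][0] for p in pres])

    def weight_profile_correlations(self) -> dict[str, float]:
        return weight_amplitude_profile(self.topology, self.model.eval_recording, self.assignment)

    def gradual_response(self, gesture: str = "flexion", **kw) -> dict:
        return gradual_response(self.topology, self.assignment, gesture=gesture,
                                profiles=self.model.profiles, dt=self.model.dt,
                                k=self.model.k, **kw)

    def summary(self) -> str:
        lines = [
            "EMG spiking-network classifier results",
            "=" * 46,
            f"mode: {self.mode}    seed: {self.seed}"
            f"    training: {self.model.recording.duration_s:.0f} s",
            f"overall accuracy (rate-ratio): {self.accuracy:.3f}",
            "",
            f"{'gesture':<12}{'classifier':>10}{'accuracy':>10}",
            "-" * 32,
        ]
        for g in self.report.gestures:
            acc = self.report.per_gesture_accuracy.get(g, float('nan'))
            lines.append(f"{g:<12}{self.assignment[g]:>10d}{acc:>10.3f}")
        if self.degenerate:
            lines.append("WARNING: degenerate (all-zero) responses; assignment arbitrary")
        return "\n".join(lines)


class EMGClassifierModel:
    """Two-layer winner-take-all spiking classifier built from a labelled
    multi-channel EMG recording.

    Parameters
    ----------
    recording : training recording (labels are used only by supervised mode's
        teacher schedule and for post-hoc evaluation, never by the
        unsupervised learning rule)
    eval_recording : held-out labelled recording for label assignment and
        accuracy; defaults to the training recording (offline re-scoring)
    n_classes : number of classifier neurons (= number of gestures)
    plasticity : rule parameters (lambda, taus, forgetting time)
    """

    def __init__(
        self,
        recording: EMGRecording,
        eval_recording: Optional[EMGRecording] = None,
        n_classes: int = 3,
        plasticity: Optional[PlasticityParams] = None,
        dt: float = 0.5,
        k: float = 2.0e6,
        profiles=None,
    ) -> None:
        self.recording = recording
        self.eval_recording = eval_recording or recording
        self.n_classes = n_classes
        self.plasticity = plasticity  # None -> the classifier network preset
        self.dt = dt
        self.k = k
        self.profiles = profiles or default_profiles()

    @classmethod
    def from_synthetic(cls, seed: int = 0, n_cycles: int = 7, **kw) -> "EMGClassifierModel":
        """Convenience constructor: a synthetic ~1 min alternating-gesture
        training recording plus an independent evaluation recording."""
        profiles = kw.pop("profiles", None) or default_profiles()
        train = generate_emg(standard_schedule(n_cycles), profiles, seed=seed)
        test = generate_emg(standard_schedule(max(2, n_cycles // 2)), profiles, seed=seed + 5000)
        return cls(train, eval_recording=test, profiles=profiles, **kw)

    def build_network(self, seed: int) -> NetworkTopology:
        return build_emg_classifier_network(
            n_channels=self.recording.n_channels,
            n_classes=self.n_classes,
            plasticity=self.plasticity,
            seed=seed,
        )

    def fit(
        self,
        mode: str = "unsupervised",
        targets: Optional[dict[str, int]] = None,
        seed: int = 0,
        exclude_transition_ms: float = 0.0,
    ) -> EMGClassifierResults:
        """Train the network on the recording and evaluate it frozen.

        mode='unsupervised' uses pure competitive learning; mode='supervised'
        additionally drives the ``targets`` classifier (gesture -> neuron id;
        defaults to gestures in sorted order onto the classifiers in id order)
        with a 40 Hz teacher during its gesture segments.
        """
        net = self.build_network(seed)
        if mode == "unsupervised":
            trained, train_res = train_unsupervised(
                net, self.recording, seed=seed + 1, dt=self.dt, k=self.k
            )
        elif mode == "supervised":
            if targets is None:
                gestures = sorted(set(self.recording.labels.tolist()))
                cids = net.ids_in_layer("classifier")
                targets = {g: cids[i] for i, g in enumerate(gestures)}
            trained, train_res = train_supervised(
                net, self.recording, targets, seed=seed + 1, dt=self.dt, k=self.k
            )
        else:
            raise ValueError("mode must be 'unsupervised' or 'supervised'")

        assignment, _, degenerate = assign_labels(
            trained, self.eval_recording, seed=seed + 2, dt=self.dt, k=self.k
        )
        eval_res = simulate(
            trained, emg_protocol(self.eval_recording, k=self.k),
            self.eval_recording.duration_s * 1000.0,
            dt=self.dt, learning=False, seed=seed + 3,
        )
        report = classification_accuracy(
            eval_res.raster, self.eval_recording, assignment,
            exclude_transition_ms=exclude_transition_ms,
        )
        return EMGClassifierResults(
            model=self, topology=trained, mode=mode, seed=seed,
            assignment=assignment, report=report, train_result=train_res,
            degenerate=degenerate,
        )
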