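"""Structured run configuration: defaults, YAML loading, strict validation.

Every key has a default; unknown keys are rejected with a closest-match
suggestion. The fully resolved configuration can be persisted alongside every
run so that (config, seed) reproduces it exactly.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .plasticity import PlasticityParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class NeuronConfig:
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    D: float = 1.0
    g: float = 2.0
    threshold: float = 30.0


@dataclass
class IntegrationConfig:
    dt_ms: float = 0.5


@dataclass
class PlasticityConfig:
    rule: str = "triplet+forgetting"
    lam: float = 0.001
    alpha: float = 1.0
    tau1_ms: float = 10.0
    tau2_ms: float = 100.0
    tau_syn_ms: float = 100.0
    tau_o_ms: float = 100.0
    # forgetting time constant; calibrated so synaptic competition balances
    # the lambda-scale potentiation over the 1000 s single-neuron protocol
    # (the classifier network uses network.tau_f_ms; see the methods note)
    tau_f_ms: float = 1.0e6

    def to_params(self) -> PlasticityParams:
        return PlasticityParams(
            lam=self.lam, alpha=self.alpha, tau1=self.tau1_ms, tau2=self.tau2_ms,
            tau_o=self.tau_o_ms, tau_f=self.tau_f_ms, tau_syn=self.tau_syn_ms,
        )


@dataclass
class NetworkConfig:
    n_channels: int = 8
    n_classes: int = 3
    init_weight_range: tuple = (0.5, 1.0)
    sensory_to_inhib_w: float = 1.0
    inhib_to_sensory_w: float = 0.5
    inhib_to_rest_w: float = 4.0
    classifier_to_inhib_w: float = 1.0
    inhib_to_classifier_w: float = 4.0
    rest_detector_D: float = 70.0
    rest_detector_bias: float = 160.0
    classifier_D: float = 5.0
    # classifier-synapse forgetting time: competition at the 1-minute scale
    tau_f_ms: float = 2.0e4


@dataclass
class StimulationConfig:
    pulse_ms: float = 2.0
    amplitude: float = 40.0
    k: float = 2.0e6
    refractory_ms: float = 5.0
    teacher_rate_hz: float = 40.0


@dataclass
class EmgConfig:
    fs_hz: float = 200.0
    max_amplitude_v: float = 4.0e-5
    baseline_rms_v: float = 1.5e-7
    transition_ms: float = 150.0


@dataclass
class ExperimentConfig:
    train_s: float = 1000.0
    test_s: float = 30.0
    window_ms: float = 500.0
    n_seeds: int = 5
    effort_levels: tuple = (0.25, 0.5, 0.75, 1.0)
    exclude_transition_ms: float = 0.0


@dataclass
class RunConfig:
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    stimulation: StimulationConfig = field(default_factory=StimulationConfig)
    emg: EmgConfig = field(default_factory=EmgConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        return asdict(self)


_ALIASES = {"lambda": "lam"}


def _apply_section(obj: Any, data: dict, path: str) -> None:
    valid = {f.name for f in fields(obj)}
    for key, val in data.items():
        key = _ALIASES.get(key, key)
        if key not in valid:
            hint = difflib.get_close_matches(key, valid | set(_ALIASES), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {path}{key!r}{suggestion}")
        current = getattr(obj, key)
        if isinstance(val, dict):
            raise ConfigError(f"{path}{key}: expected a value, got a mapping")
        if isinstance(current, bool) and not isinstance(val, bool):
            raise ConfigError(f"{path}{key}: expected bool, got {type(val).__name__}")
        if isinstance(current, (int, float)) and not isinstance(val, (int, float)):
            raise ConfigError(f"{path}{key}: expected a number, got {type(val).__name__}")
        if isinstance(current, tuple):
            val = tuple(val)
        setattr(obj, key, val)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file (empty or missing sections fall back to
    defaults); unknown keys are rejected naming the key."""
    cfg = RunConfig()
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    sections = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    for key, val in data.items():
        if key in ("seed", "outdir"):
            if key == "seed" and not isinstance(val, int):
                raise ConfigError(f"seed: expected int, got {type(val).__name__}")
            setattr(cfg, key, val)
            continue
        if key not in sections:
            hint = difflib.get_close_matches(key, sections, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config section {key!r}{suggestion}")
        if not isinstance(val, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        _apply_section(sections[key], val, f"{key}.")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
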