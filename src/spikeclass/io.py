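"""Serialization: rasters and weight snapshots as CSV, topologies as JSON,
EMG recordings as CSV or NPZ, and a checksummed artifact manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EMGRecording
from .network import NetworkTopology, Neuron, SimulationResult, SpikeRaster, SynapseSet
from .neurons import NeuronParams
from .plasticity import PlasticityParams, Rule

__all__ = [
    "write_raster_csv", "read_raster_csv",
    "write_weights_csv", "read_weights_csv",
    "save_network", "load_network",
    "write_emg_csv", "read_emg_csv", "write_emg_npz", "read_emg_npz",
    "write_artifacts", "verify_manifest",
]

RASTER_COLUMNS = ["neuron_id", "time_ms"]
WEIGHT_COLUMNS = ["pre_id", "post_id", "weight", "time_ms"]


def write_raster_csv(raster: SpikeRaster, path) -> None:
    pd.DataFrame(
        {"neuron_id": raster.neuron_ids, "time_ms": raster.times_ms}
    ).to_csv(path, index=False)


def read_raster_csv(path, duration_ms: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    if list(df.columns) != RASTER_COLUMNS:
        raise ValueError(f"raster CSV must have columns {RASTER_COLUMNS}")
    if duration_ms is None:
        duration_ms = float(df["time_ms"].max()) if len(df) else 0.0
    return SpikeRaster(df["neuron_id"].to_numpy(), df["time_ms"].to_numpy(), duration_ms)


def write_weights_csv(result: SimulationResult, path) -> None:
    """Weight snapshots, long format: (pre_id, post_id, weight, time_ms)."""
    syn = result.final_weights
    rows = []
    for t, w in zip(result.weight_times_ms, result.weight_history):
        rows.append(pd.DataFrame({
            "pre_id": syn.pre, "post_id": syn.post, "weight": w,
            "time_ms": t,
        }))
    rows.append(pd.DataFrame({
        "pre_id": syn.pre, "post_id": syn.post, "weight": syn.w,
        "time_ms": result.raster.duration_ms,
    }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_weights_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != WEIGHT_COLUMNS:
        raise ValueError(f"weights CSV must have columns {WEIGHT_COLUMNS}")
    return df


def save_network(net: NetworkTopology, path) -> None:
    data = {
        "neurons": [
            {"id": n.id, "layer": n.layer, "params": dataclasses.asdict(n.params)}
            for n in net.neurons
        ],
        "synapses": {
            "pre": net.synapses.pre.tolist(),
            "post": net.synapses.post.tolist(),
            "w": net.synapses.w.tolist(),
            "plastic": net.synapses.plastic.tolist(),
            "rule": net.synapses.rule.value,
            "params": dataclasses.asdict(net.synapses.params),
        },
        "stimulus_bindings": {str(k): v for k, v in net.stimulus_bindings.items()},
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_network(path) -> NetworkTopology:
    data = json.loads(Path(path).read_text())
    neurons = [
        Neuron(n["id"], NeuronParams(**n["params"]), n["layer"]) for n in data["neurons"]
    ]
    s = data["synapses"]
    syn = SynapseSet(
        pre=np.array(s["pre"]), post=np.array(s["post"]), w=np.array(s["w"]),
        plastic=np.array(s["plastic"]), rule=Rule(s["rule"]),
        params=PlasticityParams(**s["params"]),
    )
    bindings = {int(k): v for k, v in data["stimulus_bindings"].items()}
    return NetworkTopology(neurons, syn, bindings)


def write_emg_csv(emg: EMGRecording, path) -> None:
    cols = {f"ch{c}": emg.samples[c] for c in range(emg.n_channels)}
    cols["label"] = emg.labels
    cols["effort"] = emg.effort
    df = pd.DataFrame(cols)
    df.attrs["fs_hz"] = emg.fs_hz
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={emg.fs_hz}\n")
        df.to_csv(fh, index=False)


def read_emg_csv(path) -> EMGRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fs_hz="):
            raise ValueError("EMG CSV must start with a '# fs_hz=' line")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    channels = [c for c in df.columns if c.startswith("ch")]
    return EMGRecording(
        samples=df[channels].to_numpy().T, fs_hz=fs,
        labels=df["label"].to_numpy(dtype="U16"), effort=df["effort"].to_numpy(),
    )


def write_emg_npz(emg: EMGRecording, path) -> None:
    np.savez_compressed(
        path, samples=emg.samples, fs_hz=emg.fs_hz,
        labels=emg.labels.astype("U16"), effort=emg.effort,
    )


def read_emg_npz(path) -> EMGRecording:
    z = np.load(path, allow_pickle=False)
    return EMGRecording(
        samples=z["samples"], fs_hz=float(z["fs_hz"]),
        labels=z["labels"], effort=z["effort"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_artifacts(
    result: SimulationResult,
    outdir,
    reports: dict | None = None,
    config_text: str | None = None,
    log_lines: list[str] | None = None,
) -> dict:
    """Write raster CSV, weight CSV, report JSON, resolved config and log to a
    directory; returns (and writes) a manifest with SHA-256 checksums."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster_csv(result.raster, out / "raster.csv")
    write_weights_csv(result, out / "weights.csv")
    if reports is not None:
        (out / "report.json").write_text(json.dumps(reports, indent=1, default=float))
    if config_text is not None:
        (out / "config.yaml").write_text(config_text)
    if log_lines:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def verify_manifest(outdir) -> list[str]:
    """Return the names of files whose checksum no longer matches."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    return [name for name, digest in manifest.items() if _sha256(out / name) != digest]
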