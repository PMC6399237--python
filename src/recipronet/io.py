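"""Configuration files, spike event tables and run manifests.

Configs are YAML mappings mirroring the nested structure of
:class:`~recipronet.engine.RunConfig`; omitted fields fall back to the
dataclass defaults (each defaulted field is logged at DEBUG level), unknown
or out-of-range fields raise with the offending field path.

Spike data are stored as a CSV event table with columns
``trial, neuron_id, population, time_ms`` (0-based neuron ids within the
whole network, times to 0.01 ms) — transparently gzipped when the path ends
in ``.gz`` — plus a JSON sidecar with the trial metadata and a checksum of
the table.
"""

from __future__ import annotations

import gzip
import hashlib
import io as std_io
import json
import logging
import time
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import RunConfig, SpikeData
from .inputs import BackgroundParams, FeedforwardParams, SynapseParams
from .neuron import NeuronParams
from .topology import TopologyConfig

__all__ = [
    "load_config",
    "save_config",
    "write_spikes",
    "read_spikes",
    "write_manifest",
]

log = logging.getLogger("recipronet")

_SECTIONS = {
    "topology": TopologyConfig,
    "neuron_e": NeuronParams,
    "neuron_i": NeuronParams,
    "synapse": SynapseParams,
    "background_e": BackgroundParams,
    "background_i": BackgroundParams,
    "feedforward_e": FeedforwardParams,
    "feedforward_i": FeedforwardParams,
}


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown field(s) {sorted(unknown)} in '{path}'")
    for name in valid - set(data):
        log.debug("config: '%s.%s' not given, using default", path, name)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section '{path}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    if "topology" not in raw:
        raise ValueError(f"{path}: missing required section 'topology'")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], val, key)
        elif key == "orientations":
            kwargs[key] = tuple(float(x) for x in val)
        elif key in ("dt", "t_transient", "t_measure", "contrast"):
            kwargs[key] = float(val)
        elif key in ("n_trials", "seed"):
            kwargs[key] = int(val)
        else:
            raise ValueError(f"unknown top-level field '{key}'")
    top_fields = {f.name for f in fields(RunConfig)}
    for name in top_fields - set(kwargs):
        log.debug("config: '%s' not given, using default", name)
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as YAML; ``load_config`` round-trips it."""
    doc = {}
    for f in fields(RunConfig):
        val = getattr(config, f.name)
        if f.name in _SECTIONS:
            doc[f.name] = {k: (v.item() if isinstance(v, np.generic) else v)
                           for k, v in asdict(val).items()}
        elif f.name == "orientations":
            doc[f.name] = [float(x) for x in val]
        else:
            doc[f.name] = val
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _table_checksum(csv_bytes: bytes) -> str:
    return hashlib.sha256(csv_bytes).hexdigest()


def write_spikes(data: SpikeData, path: str | Path, trial: int = 0) -> None:
    """Write one trial's spikes as a CSV event table (gzipped for ``.gz``
    paths) with a JSON metadata sidecar carrying a table checksum."""
    path = Path(path)
    rows = []
    for i, t in enumerate(data.trains):
        pop = "E" if i < data.n_e else "I"
        for ts in np.asarray(t):
            rows.append((trial, i, pop, round(float(ts), 2)))
    df = pd.DataFrame(rows, columns=["trial", "neuron_id", "population",
                                     "time_ms"])
    csv_bytes = df.to_csv(index=False, float_format="%.2f").encode()
    if path.suffix == ".gz":
        path.write_bytes(gzip.compress(csv_bytes))
    else:
        path.write_bytes(csv_bytes)
    meta = {
        "n_e": data.n_e,
        "n_neurons": data.n_neurons,
        "duration_ms": data.duration_ms,
        "theta": data.theta,
        "seed": data.seed,
        "sha256": _table_checksum(csv_bytes),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_spikes(path: str | Path) -> SpikeData:
    """Read an event table back; verifies the sidecar checksum."""
    path = Path(path)
    raw = path.read_bytes()
    if path.suffix == ".gz":
        raw = gzip.decompress(raw)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if _table_checksum(raw) != meta["sha256"]:
        raise ValueError(f"{path}: checksum mismatch, file corrupt")
    df = pd.read_csv(std_io.BytesIO(raw))
    trains = [np.array([]) for _ in range(meta["n_neurons"])]
    for nid, grp in df.groupby("neuron_id"):
        trains[int(nid)] = np.sort(grp["time_ms"].to_numpy(dtype=float))
    return SpikeData(trains=trains, n_e=meta["n_e"],
                     duration_ms=meta["duration_ms"], theta=meta["theta"],
                     seed=meta["seed"])


def write_manifest(out_dir: str | Path, config: RunConfig,
                   stage: str, outputs: list[str],
                   wall_time_s: float | None = None) -> Path:
    """Append provenance for one pipeline stage to ``manifest.json`` in the
    output directory: config hash, seeds, produced files with checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": []})
    cfg_yaml = yaml.safe_dump(
        {f.name: str(getattr(config, f.name)) for f in fields(RunConfig)},
        sort_keys=True,
    )
    entry = {
        "stage": stage,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "outputs": {},
        "wall_time_s": wall_time_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name in outputs:
        p = out_dir / name
        entry["outputs"][name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest["stages"].append(entry)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
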