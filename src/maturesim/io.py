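"""Plain-text I/O: spike-train CSV, feature TSV, and config documents.

Spike trains are stored as ``unit_id,spike_time_s`` rows (times with six
decimal places, sorted by unit then time) plus a JSON sidecar
``<path>.meta.json`` carrying the duration, unit count and provenance so
silent units survive a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import NetworkSpec, ParameterBounds
from .simulator import SimulationConfig, SpikeTrainSet

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "write_features_tsv",
    "read_features_tsv",
    "read_config",
    "write_config",
]

_TIME_DECIMALS = 6


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_spike_trains(path, spike_trains: SpikeTrainSet,
                       n_units=None) -> None:
    """Write (the first ``n_units`` of) a train set as CSV + sidecar."""
    path = Path(path)
    units = spike_trains.n_units if n_units is None else n_units
    with open(path, "w") as fh:
        fh.write("unit_id,spike_time_s\n")
        for u in range(units):
            for t in spike_trains.trains[u]:
                fh.write(f"{u},{t:.{_TIME_DECIMALS}f}\n")
    meta = {
        "n_units": units,
        "duration_s": spike_trains.duration_s,
        "provenance": spike_trains.provenance,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_spike_trains(path, duration_s=None) -> SpikeTrainSet:
    """Read a spike-train CSV (with sidecar when present).

    Malformed or negative-time rows raise ``ValueError`` naming the line
    number. Without a sidecar, ``duration_s`` must be supplied and the
    unit count is inferred from the data.
    """
    path = Path(path)
    meta = None
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    if meta is None and duration_s is None:
        raise ValueError(
            f"{path}: no sidecar metadata found; pass duration_s explicitly"
        )

    by_unit: dict = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "unit_id,spike_time_s":
            raise ValueError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            try:
                unit = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed row: {exc}"
                ) from None
            if unit < 0:
                raise ValueError(f"{path}:{lineno}: negative unit id")
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time")
            by_unit.setdefault(unit, []).append(t)

    n_units = (
        meta["n_units"] if meta is not None
        else (max(by_unit) + 1 if by_unit else 0)
    )
    duration = meta["duration_s"] if meta is not None else duration_s
    trains = [
        np.sort(np.asarray(by_unit.get(u, []), dtype=float))
        for u in range(n_units)
    ]
    provenance = meta.get("provenance", {}) if meta is not None else {}
    return SpikeTrainSet(
        trains=trains, duration_s=duration, provenance=provenance
    )


def write_features_tsv(path, features: pd.DataFrame) -> None:
    features.to_csv(path, sep="\t", index=False, na_rep="NA",
                    float_format="%.6g")


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


_NETWORK_KEYS = {
    "n_neurons", "inhibitory_fraction", "connection_probability",
    "triangular_mode_fraction", "seed", "c_upper", "y_exc_upper",
    "y_inh_upper",
}
_SIMULATION_KEYS = {
    "duration_s", "dt_s", "history_factor", "time_unit", "seed",
}


def read_config(path):
    """Load a JSON/YAML config with ``network`` and ``simulation`` sections.

    Unknown keys anywhere in the document are rejected. Returns
    ``(NetworkSpec, SimulationConfig)``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = (
            json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        )
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(doc) - {"network", "simulation"}
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")

    net = dict(doc.get("network", {}))
    unknown = set(net) - _NETWORK_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown network keys {sorted(unknown)}")
    bounds = ParameterBounds(
        c_upper=net.pop("c_upper", 0.0),
        y_exc_upper=net.pop("y_exc_upper", 0.0),
        y_inh_upper=net.pop("y_inh_upper", 0.0),
    )
    net_spec = NetworkSpec(bounds=bounds, **net)

    sim = dict(doc.get("simulation", {}))
    unknown = set(sim) - _SIMULATION_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown simulation keys {sorted(unknown)}")
    sim_config = SimulationConfig(**sim)
    return net_spec, sim_config


def write_config(path, net_spec: NetworkSpec,
                 sim_config: SimulationConfig) -> None:
    path = Path(path)
    doc = {
        "network": {
            "n_neurons": net_spec.n_neurons,
            "inhibitory_fraction": net_spec.inhibitory_fraction,
            "connection_probability": net_spec.connection_probability,
            "triangular_mode_fraction": net_spec.triangular_mode_fraction,
            "seed": net_spec.seed,
            "c_upper": net_spec.bounds.c_upper,
            "y_exc_upper": net_spec.bounds.y_exc_upper,
            "y_inh_upper": net_spec.bounds.y_inh_upper,
        },
        "simulation": {
            "duration_s": sim_config.duration_s,
            "dt_s": sim_config.dt_s,
            "history_factor": sim_config.history_factor,
            "time_unit": sim_config.time_unit,
            "seed": sim_config.seed,
        },
    }
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh)
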