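"""End-to-end maturation experiment.

Six developmental stages are simulated as independent networks of
increasing connectivity (1, 2, 4, 6, 8, 10 % by default), each stage run
as several fresh network realizations. Per-unit features of the first
nine units of every run (one simulated unit standing in for one
recording electrode of a 6-well array) are pooled across runs and
summarized as quartiles, then compared to the embedded experimental
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import BurstConfig, analyze_spike_trains, FEATURE_COLUMNS
from .network import NetworkSpec, ParameterBounds, generate_network
from .simulator import SimulationConfig, simulate
from .stats import compare_to_reference, select_units_and_pool, summarize
from . import io as msio
from . import reference as refdata

__all__ = ["MaturationSchedule", "MaturationReport", "default_schedule",
           "run_maturation"]


@dataclass(frozen=True)
class MaturationSchedule:
    vmtps: tuple
    connection_probabilities: tuple
    bounds: tuple  # one ParameterBounds per stage
    runs_per_vmtp: int = 10
    n_neurons: int = 1000
    inhibitory_fraction: float = 0.2
    triangular_mode_fraction: float = 1.0
    sim_config: SimulationConfig = SimulationConfig()

    def __post_init__(self) -> None:
        k = len(self.vmtps)
        if not (len(self.connection_probabilities) == len(self.bounds) == k):
            raise ValueError("schedule fields must have equal length")
        probs = self.connection_probabilities
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("connection probabilities must be non-decreasing")
        if self.runs_per_vmtp < 1:
            raise ValueError("runs_per_vmtp must be >= 1")


def default_schedule(**overrides) -> MaturationSchedule:
    """The published six-stage schedule with the published selected bounds."""
    bounds = refdata.selected_bounds()
    schedule = refdata.connectivity_schedule()
    mtps = tuple(sorted(schedule))
    kwargs = dict(
        vmtps=mtps,
        connection_probabilities=tuple(schedule[m] for m in mtps),
        bounds=tuple(bounds[m] for m in mtps),
    )
    kwargs.update(overrides)
    return MaturationSchedule(**kwargs)


@dataclass
class MaturationReport:
    summaries: dict  # {vmtp: {feature: Quartiles}}
    comparison: pd.DataFrame
    provenance: dict
    counts: dict


def run_maturation(schedule: MaturationSchedule, seed: int = 0,
                   n_units: int = 9,
                   burst_config: BurstConfig = BurstConfig(),
                   reference: pd.DataFrame | None = None,
                   out_dir=None) -> MaturationReport:
    """Run every stage of ``schedule`` and summarize against the reference.

    One master seed drives the whole experiment; each (stage, run) gets
    its own spawned network and simulation substreams, so the full report
    reproduces bit-for-bit. When ``out_dir`` is given, per-stage spike
    trains, feature tables and summaries plus a top-level report TSV and
    provenance JSON are written beneath it.
    """
    if reference is None:
        reference = refdata.mea_reference()
    master = np.random.SeedSequence(seed)
    stage_streams = master.spawn(len(schedule.vmtps))
    out_path = Path(out_dir) if out_dir is not None else None

    summaries: dict = {}
    counts = {"networks": 0, "spikes": 0, "bursts": 0}
    summary_rows = []
    for (vmtp, p_conn, bounds), stream in zip(
        zip(schedule.vmtps, schedule.connection_probabilities,
            schedule.bounds),
        stage_streams,
    ):
        run_streams = stream.spawn(2 * schedule.runs_per_vmtp)
        tables = []
        stage_dir = None
        if out_path is not None:
            stage_dir = out_path / f"vmtp{vmtp}"
            stage_dir.mkdir(parents=True, exist_ok=True)
        for r in range(schedule.runs_per_vmtp):
            net_seed = int(run_streams[2 * r].generate_state(1)[0])
            sim_seed = int(run_streams[2 * r + 1].generate_state(1)[0])
            net = generate_network(
                NetworkSpec(
                    n_neurons=schedule.n_neurons,
                    inhibitory_fraction=schedule.inhibitory_fraction,
                    connection_probability=p_conn,
                    bounds=bounds,
                    triangular_mode_fraction=(
                        schedule.triangular_mode_fraction
                    ),
                    seed=net_seed,
                )
            )
            counts["networks"] += 1
            trains = simulate(net, schedule.sim_config, seed=sim_seed)
            counts["spikes"] += int(trains.spike_counts().sum())
            table = analyze_spike_trains(trains, burst_config,
                                         n_units=n_units)
            counts["bursts"] += int(table["n_bursts"].sum())
            tables.append(table)
            if stage_dir is not None:
                msio.write_spike_trains(
                    stage_dir / f"run{r}_spikes.csv", trains,
                    n_units=n_units,
                )
                msio.write_features_tsv(
                    stage_dir / f"run{r}_features.tsv", table
                )
        pooled = select_units_and_pool(tables, n_units=n_units)
        summaries[vmtp] = {f: summarize(v) for f, v in pooled.items()}
        for f in FEATURE_COLUMNS:
            q = summaries[vmtp][f]
            summary_rows.append(
                {"vmtp": vmtp, "feature": f, "q1": q.q1, "median": q.median,
                 "q3": q.q3, "n": q.n}
            )

    comparison = compare_to_reference(summaries, reference)
    provenance = {
        "seed": int(seed),
        "package_version": __version__,
        "n_units": n_units,
        "runs_per_vmtp": schedule.runs_per_vmtp,
        "n_neurons": schedule.n_neurons,
        "time_unit": schedule.sim_config.time_unit,
        "triangular_mode_fraction": schedule.triangular_mode_fraction,
        "duration_s": schedule.sim_config.duration_s,
        "dt_s": schedule.sim_config.dt_s,
        "history_factor": schedule.sim_config.history_factor,
        "burst_config": burst_config.__dict__ | {},
    }
    report = MaturationReport(
        summaries=summaries, comparison=comparison,
        provenance=provenance, counts=counts,
    )
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(summary_rows).to_csv(
            out_path / "summaries.tsv", sep="\t", index=False,
            na_rep="NA",
        )
        comparison.to_csv(
            out_path / "comparison.tsv", sep="\t", index=False, na_rep="NA"
        )
        with open(out_path / "provenance.json", "w") as fh:
            json.dump(provenance | {"counts": counts}, fh, indent=2)
    return report
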