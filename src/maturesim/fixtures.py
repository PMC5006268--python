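"""Synthetic spike trains with planted, ground-truth bursts.

Used for detector validation: bursts of known timing (short intra-burst
ISIs, long guaranteed gaps) are superimposed on optional Poisson
background activity, and the planted bursts are returned alongside the
trains so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bursts import Burst
from .simulator import SpikeTrainSet

__all__ = ["FixtureSpec", "generate_bursty_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    n_units: int = 1
    n_bursts: int = 20
    spikes_per_burst: int = 5
    intra_burst_isi_s: float = 0.01
    min_gap_s: float = 1.0  # guaranteed silence flanking every burst
    background_rate_hz: float = 0.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.spikes_per_burst < 1:
            raise ValueError("n_units and spikes_per_burst must be >= 1")
        if self.n_bursts < 0 or self.background_rate_hz < 0:
            raise ValueError("n_bursts and background rate must be >= 0")
        if self.intra_burst_isi_s >= self.min_gap_s:
            raise ValueError("intra-burst ISI must be < inter-burst gap")
        span = (self.spikes_per_burst - 1) * self.intra_burst_isi_s
        if self.n_bursts and (
            self.n_bursts * (span + self.min_gap_s) + self.min_gap_s
            > self.duration_s
        ):
            raise ValueError(
                "duration too short to place the requested bursts with the "
                "requested gaps"
            )


def generate_bursty_fixture(spec: FixtureSpec):
    """Build the fixture; returns ``(SpikeTrainSet, ground_truth)`` where
    ground truth is a per-unit list of planted :class:`Burst` objects."""
    rng = np.random.default_rng(spec.seed)
    span = (spec.spikes_per_burst - 1) * spec.intra_burst_isi_s
    period = (
        (spec.duration_s - spec.min_gap_s) / spec.n_bursts
        if spec.n_bursts else 0.0
    )
    trains = []
    truth = []
    for _ in range(spec.n_units):
        starts = []
        for k in range(spec.n_bursts):
            slack = period - span - spec.min_gap_s
            jitter = rng.uniform(0.0, slack) if slack > 0 else 0.0
            starts.append(spec.min_gap_s / 2 + k * period + jitter)
        burst_times = [
            s + np.arange(spec.spikes_per_burst) * spec.intra_burst_isi_s
            for s in starts
        ]
        unit_truth = [
            Burst(start_s=float(b[0]), end_s=float(b[-1]),
                  n_spikes=spec.spikes_per_burst)
            for b in burst_times
        ]
        n_bg = rng.poisson(spec.background_rate_hz * spec.duration_s)
        background = rng.uniform(0.0, spec.duration_s, size=n_bg)
        all_times = np.concatenate(burst_times + [background]) if (
            burst_times or n_bg
        ) else np.empty(0)
        all_times = np.unique(all_times)
        trains.append(np.sort(all_times))
        truth.append(unit_truth)
    sts = SpikeTrainSet(
        trains=trains, duration_s=spec.duration_s,
        provenance={"fixture_seed": spec.seed},
    )
    return sts, truth
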