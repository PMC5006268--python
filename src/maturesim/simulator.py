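"""Discrete-time stochastic spiking dynamics.

Each neuron is a two-state unit updated synchronously on a fixed time
grid (default 5 ms). The momentary rate of neuron i is

    lambda_i = max(0, c_i + sum_j y_ji * s_j(previous slice))

and the probability of one spike in a slice is

    P_i = exp(-lambda_i * dt) * (lambda_i * dt),

the probability of exactly one event of an inhomogeneous Poisson process
in the slice. A spike is emitted when a uniform draw x_i falls below P_i;
in the slice immediately after a spike, x_i is first multiplied by the
history factor f (default 0.1), transiently facilitating repeat firing.

The product ``lambda * dt`` is unit-ambiguous in the source formulation;
``SimulationConfig.time_unit`` records the convention explicitly and is a
calibration degree of freedom (see :mod:`maturesim.search`).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._kernel import step_block
from .network import Network

__all__ = [
    "TIME_UNITS",
    "SimulationConfig",
    "SpikeTrainSet",
    "firing_rate",
    "spike_probability",
    "advance_slice",
    "simulate",
]

#: Supported conventions for expressing ``lambda * dt``.
TIME_UNITS = ("per_second", "per_millisecond", "per_slice")

_BLOCK_SLICES = 4000  # uniforms are drawn in blocks of this many slices


@dataclass(frozen=True)
class SimulationConfig:
    duration_s: float = 300.0
    dt_s: float = 0.005
    history_factor: float = 0.1
    time_unit: str = "per_second"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if not 0.0 < self.history_factor <= 1.0:
            raise ValueError("history_factor must be in (0, 1]")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(
                f"time_unit must be one of {TIME_UNITS}, got {self.time_unit!r}"
            )

    @property
    def n_slices(self) -> int:
        return int(math.floor(self.duration_s / self.dt_s))

    @property
    def dt_effective(self) -> float:
        """dt expressed in the active time-unit convention."""
        if self.time_unit == "per_second":
            return self.dt_s
        if self.time_unit == "per_millisecond":
            return self.dt_s * 1000.0
        return 1.0  # per_slice

    def content_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike times (seconds) over a fixed duration."""

    trains: list  # list of 1-D float arrays, one per unit
    duration_s: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for u, t in enumerate(self.trains):
            if len(t) and (t[0] < 0 or t[-1] >= self.duration_s):
                raise ValueError(
                    f"unit {u}: spike times must lie in [0, duration_s)"
                )
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"unit {u}: spike times must be increasing")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains])


def firing_rate(c_i, incoming_weights, prev_spike_indicators) -> float:
    """Clamped momentary rate of a single neuron (reference arithmetic)."""
    w = np.asarray(incoming_weights, dtype=float)
    s = np.asarray(prev_spike_indicators, dtype=float)
    if w.shape != s.shape:
        raise ValueError(
            f"weight/indicator length mismatch: {w.shape} vs {s.shape}"
        )
    return max(0.0, float(c_i) + float(w @ s))


def spike_probability(lam, dt_effective):
    """P(exactly one spike in a slice) = exp(-lam*dt) * lam*dt.

    Bounded by 1/e, attained at ``lam * dt == 1``. Accepts scalars or
    arrays; negative rates are rejected.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("firing rate must be >= 0")
    if dt_effective <= 0:
        raise ValueError("dt_effective must be > 0")
    x = lam_arr * dt_effective
    out = np.exp(-x) * x
    return float(out) if np.isscalar(lam) else out


def _history_threshold(x, p, spiked_previously, f):
    """The spike decision rule: scale x by f after a spike, fire iff x < p."""
    if spiked_previously:
        x = f * x
    return x < p


def advance_slice(previous_spikes, network: Network, config: SimulationConfig,
                  rng) -> np.ndarray:
    """Advance one slice; consumes exactly ``n_neurons`` uniforms from rng."""
    prev = np.asarray(previous_spikes, dtype=np.uint8).copy()
    n = network.n_neurons
    if len(prev) != n:
        raise ValueError("previous_spikes length must equal n_neurons")
    u = rng.random(n)
    w = network.weights
    out = step_block(
        u[None, :], prev, network.basic_activity, w.indptr, w.indices, w.data,
        config.dt_effective, config.history_factor, use_numba=False,
    )
    return out[0]


def simulate(network: Network, config: SimulationConfig,
             seed=None, use_numba=True) -> SpikeTrainSet:
    """Run the full dynamics from an all-silent initial state.

    ``seed`` overrides ``config.seed`` when given. Spike times are the
    start times of their slices. Deterministic for a given seed; the
    numba and pure-numpy paths produce identical output.
    """
    actual_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(actual_seed)
    n = network.n_neurons
    n_slices = config.n_slices
    w = network.weights.tocsr()
    prev = np.zeros(n, dtype=np.uint8)

    slice_idx: list = []
    unit_idx: list = []
    done = 0
    while done < n_slices:
        block = min(_BLOCK_SLICES, n_slices - done)
        uniforms = rng.random((block, n))
        spikes = step_block(
            uniforms, prev, network.basic_activity,
            w.indptr, w.indices, w.data,
            config.dt_effective, config.history_factor, use_numba=use_numba,
        )
        t_loc, u_loc = np.nonzero(spikes)
        slice_idx.append(t_loc + done)
        unit_idx.append(u_loc)
        done += block

    slices = np.concatenate(slice_idx) if slice_idx else np.empty(0, int)
    units = np.concatenate(unit_idx) if unit_idx else np.empty(0, int)
    trains = [
        slices[units == u].astype(float) * config.dt_s for u in range(n)
    ]
    provenance = {
        "seed": int(actual_seed),
        "config_hash": config.content_hash(),
        "time_unit": config.time_unit,
        "dt_s": config.dt_s,
        "history_factor": config.history_factor,
    }
    return SpikeTrainSet(
        trains=trains, duration_s=n_slices * config.dt_s,
        provenance=provenance,
    )
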