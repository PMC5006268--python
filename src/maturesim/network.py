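"""Random excitatory/inhibitory network construction.

Networks are directed, weighted, autapse-free random graphs. Per-neuron
spontaneous ("basic") activity and per-edge synaptic strengths are drawn
from a triangular distribution on ``[0, upper]``; inhibitory presynaptic
neurons carry negative outgoing weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EXCITATORY",
    "INHIBITORY",
    "ParameterBounds",
    "NetworkSpec",
    "Network",
    "sample_triangular",
    "generate_network",
]

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass(frozen=True)
class ParameterBounds:
    """Upper bounds of the triangular distributions for model parameters.

    Attributes
    ----------
    c_upper : float
        Upper bound of per-neuron basic activity, in ``[0, 1]``.
    y_exc_upper : float
        Upper bound of excitatory synaptic strength, in ``[0, 1]``.
    y_inh_upper : float
        Bound of inhibitory synaptic strength, stored as the (negative)
        extreme value, in ``[-1, 0]``.
    """

    c_upper: float
    y_exc_upper: float
    y_inh_upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_upper <= 1.0:
            raise ValueError(f"c_upper must be in [0, 1], got {self.c_upper}")
        if not 0.0 <= self.y_exc_upper <= 1.0:
            raise ValueError(
                f"y_exc_upper must be in [0, 1], got {self.y_exc_upper}"
            )
        if not -1.0 <= self.y_inh_upper <= 0.0:
            raise ValueError(
                f"y_inh_upper must be in [-1, 0], got {self.y_inh_upper}"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for one random network realization."""

    n_neurons: int
    inhibitory_fraction: float
    connection_probability: float
    bounds: ParameterBounds
    triangular_mode_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must be in [0, 1]")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ValueError("connection_probability must be in [0, 1]")
        if not 0.0 <= self.triangular_mode_fraction <= 1.0:
            raise ValueError("triangular_mode_fraction must be in [0, 1]")


@dataclass
class Network:
    """A realized network.

    ``weights`` is a CSR matrix with row = presynaptic neuron j, column =
    postsynaptic neuron i; the diagonal is structurally zero (no autapses).
    """

    neuron_types: np.ndarray  # array of EXCITATORY / INHIBITORY labels
    basic_activity: np.ndarray  # per-neuron c_i >= 0
    weights: sp.csr_matrix
    spec: NetworkSpec | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.basic_activity)

    @property
    def inhibitory_mask(self) -> np.ndarray:
        return self.neuron_types == INHIBITORY

    def to_json(self) -> str:
        coo = self.weights.tocoo()
        doc = {
            "neuron_types": self.neuron_types.tolist(),
            "basic_activity": self.basic_activity.tolist(),
            "edges": [
                [int(j), int(i), float(w)]
                for j, i, w in zip(coo.row, coo.col, coo.data)
            ],
            "spec": None if self.spec is None else _spec_to_dict(self.spec),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        types = np.asarray(doc["neuron_types"], dtype=object)
        c = np.asarray(doc["basic_activity"], dtype=float)
        n = len(c)
        edges = doc["edges"]
        if edges:
            j, i, w = (np.asarray(col) for col in zip(*edges))
        else:
            j = i = np.empty(0, dtype=int)
            w = np.empty(0, dtype=float)
        weights = sp.csr_matrix(
            (w.astype(float), (j.astype(int), i.astype(int))), shape=(n, n)
        )
        spec = None
        if doc.get("spec") is not None:
            spec = _spec_from_dict(doc["spec"])
        return cls(
            neuron_types=types, basic_activity=c, weights=weights, spec=spec
        )


def _spec_to_dict(spec: NetworkSpec) -> dict:
    d = asdict(spec)
    d["bounds"] = asdict(spec.bounds)
    return d


def _spec_from_dict(d: dict) -> NetworkSpec:
    d = dict(d)
    d["bounds"] = ParameterBounds(**d["bounds"])
    return NetworkSpec(**d)


def sample_triangular(upper, mode_fraction, rng, size=None):
    """Draw from a triangular distribution on ``[0, upper]``.

    The mode sits at ``mode_fraction * upper``. ``upper`` may be a scalar or
    an array (per-draw upper bounds); ``upper == 0`` yields 0. The draw is
    realized as ``upper * Triangular(0, mode_fraction, 1)`` so a random
    variate is consumed even for degenerate bounds, keeping the stream
    layout independent of the bound values.
    """
    upper = np.asarray(upper, dtype=float)
    if np.any(upper < 0):
        raise ValueError("upper bound of triangular distribution must be >= 0")
    if not 0.0 <= mode_fraction <= 1.0:
        raise ValueError("mode_fraction must be in [0, 1]")
    unit = rng.triangular(0.0, mode_fraction, 1.0, size=size)
    out = upper * unit
    if size is None and out.ndim == 0:
        return float(out)
    return out


def generate_network(spec: NetworkSpec) -> Network:
    """Instantiate a random network from ``spec``.

    Exactly ``round(n * inhibitory_fraction)`` neurons are inhibitory
    (positions chosen at random); each ordered pair (j, i), j != i, is
    connected independently with ``connection_probability``; strengths and
    basic activities are triangular draws from the type-appropriate bound.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    b = spec.bounds

    n_inh = int(round(n * spec.inhibitory_fraction))
    inhibitory = np.zeros(n, dtype=bool)
    inhibitory[rng.permutation(n)[:n_inh]] = True

    c = np.atleast_1d(
        sample_triangular(b.c_upper, spec.triangular_mode_fraction, rng, size=n)
    )

    mask = rng.random((n, n)) < spec.connection_probability
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)  # row-major, deterministic order

    edge_upper = np.where(inhibitory[rows], -b.y_inh_upper, b.y_exc_upper)
    magnitudes = np.atleast_1d(
        sample_triangular(
            edge_upper, spec.triangular_mode_fraction, rng, size=len(rows)
        )
    )
    signs = np.where(inhibitory[rows], -1.0, 1.0)
    weights = sp.csr_matrix(
        (signs * magnitudes, (rows, cols)), shape=(n, n)
    )

    types = np.where(inhibitory, INHIBITORY, EXCITATORY).astype(object)
    return Network(
        neuron_types=types, basic_activity=c, weights=weights, spec=spec
    )
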