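"""Reservoir interconnect topologies and their graph metrics.

The reservoir of an echo state network is a fixed, randomly weighted
recurrent layer.  This module builds the five interconnect patterns the
simulator supports:

``one_way_ring``
    Each neuron receives from its predecessor only (a simple cycle).
``two_way_ring``
    Each neuron receives from both neighbours.
``center``
    Every neuron couples to a single linear hub ("center") neuron and back;
    no direct neuron-to-neuron links.
``hybrid``
    One-way ring plus the center hub: every neuron feeds the hub through an
    "up" synapse and receives the hub state through a "down" synapse.  The
    hub gives every neuron a two-hop path to every other neuron, so the
    directed diameter is 2 and the mean distance is below 2 regardless of
    reservoir size.
``random``
    Classical dense random reservoir with Bernoulli-masked connectivity.

Weights are drawn once from a configurable law and never trained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from ._exceptions import ConfigurationError, ShapeError

__all__ = [
    "TopologySpec",
    "ReservoirWeights",
    "build_topology",
    "graph_diameter",
    "average_distance",
    "synapses_per_neuron",
    "n_synapses",
    "toroidal_report",
    "INFINITE_DIAMETER",
    "TOPOLOGY_KINDS",
    "WEIGHT_LAWS",
]

TOPOLOGY_KINDS = ("one_way_ring", "two_way_ring", "center", "hybrid", "random")
WEIGHT_LAWS = ("uniform_pm1", "normal", "lognormal_mismatch")

#: Sentinel returned by :func:`graph_diameter` for a disconnected graph.
INFINITE_DIAMETER = math.inf

#: Node key used for the center (hub) neuron in the topology graph.
CENTER_NODE = "center"


@dataclass(frozen=True)
class TopologySpec:
    """Immutable description of a reservoir interconnect.

    Parameters
    ----------
    kind : str
        One of ``one_way_ring``, ``two_way_ring``, ``center``, ``hybrid``,
        ``random``.
    n : int
        Number of reservoir neurons (the hub neuron of center/hybrid kinds
        is extra and not counted).
    k : int
        Number of input channels.
    m : int
        Number of outputs (bookkeeping for cost models; the readout itself
        lives elsewhere).
    connectivity : float
        Fraction of nonzero recurrent links, used only by ``random``.
    weight_law : str
        Distribution of the random weights: ``uniform_pm1`` (uniform on
        [-1, 1]), ``normal`` (N(0, sigma)), or ``lognormal_mismatch``
        (sign-symmetric lognormal magnitudes, the distribution produced by
        transistor threshold-voltage mismatch).
    weight_scale : float
        Law parameter: half-width for uniform, sigma for normal, sigma of
        the log-magnitude for lognormal_mismatch.
    seed : int
        Seed for the weight draw; the same (spec, seed) pair regenerates
        bit-identical weights.
    """

    kind: str = "hybrid"
    n: int = 100
    k: int = 1
    m: int = 1
    connectivity: float = 0.5
    weight_law: str = "uniform_pm1"
    weight_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ConfigurationError(
                f"topology.kind={self.kind!r} is not one of {TOPOLOGY_KINDS}"
            )
        if self.n < 1 or (self.kind != "random" and self.kind != "center" and self.n < 2):
            raise ConfigurationError(
                f"topology.n={self.n} is too small for kind={self.kind!r}"
            )
        if self.k < 1:
            raise ConfigurationError(f"topology.k={self.k} must be >= 1")
        if self.m < 1:
            raise ConfigurationError(f"topology.m={self.m} must be >= 1")
        if self.kind == "random" and not (0.0 < self.connectivity <= 1.0):
            raise ConfigurationError(
                f"topology.connectivity={self.connectivity} must lie in (0, 1]"
            )
        if self.weight_law not in WEIGHT_LAWS:
            raise ConfigurationError(
                f"topology.weight_law={self.weight_law!r} is not one of {WEIGHT_LAWS}"
            )


@dataclass
class ReservoirWeights:
    """Frozen random weight sets plus the interconnect graph.

    ``w_in`` is N x K; ``w_ring``/``w_ring_rev``/``w_up``/``w_down`` are
    length-N vectors (unused sets are zero); ``w_x`` is the dense N x N
    recurrent matrix of the random kind (zero entries encode absent links).
    ``graph`` is a directed graph over reservoir node indices 0..N-1 plus
    the optional ``"center"`` hub node; its edges mirror nonzero weights.
    """

    spec: TopologySpec
    w_in: np.ndarray
    w_ring: np.ndarray
    w_ring_rev: np.ndarray
    w_up: np.ndarray
    w_down: np.ndarray
    w_x: Optional[np.ndarray]
    graph: nx.DiGraph = field(repr=False)

    @property
    def n(self) -> int:
        return self.spec.n

    @property
    def kind(self) -> str:
        return self.spec.kind

    @property
    def has_center(self) -> bool:
        return self.spec.kind in ("center", "hybrid")


def _draw(rng: np.random.Generator, law: str, scale: float, shape) -> np.ndarray:
    if law == "uniform_pm1":
        return rng.uniform(-scale, scale, size=shape)
    if law == "normal":
        return rng.normal(0.0, scale, size=shape)
    # lognormal_mismatch: sign-symmetric lognormal magnitudes, the weight
    # distribution generated by threshold-voltage mismatch in current mirrors
    mags = rng.lognormal(mean=0.0, sigma=scale, size=shape)
    signs = rng.choice([-1.0, 1.0], size=shape)
    return mags * signs


def build_topology(spec: TopologySpec) -> ReservoirWeights:
    """Generate the weight sets and interconnect graph for ``spec``.

    The draw is fully determined by ``(spec, spec.seed)``; weights are
    frozen thereafter (an echo state network never trains them).
    """
    n, k = spec.n, spec.k
    rng = np.random.default_rng(spec.seed)
    scale = spec.weight_scale
    law = spec.weight_law

    w_in = _draw(rng, law, scale, (n, k))
    w_ring = np.zeros(n)
    w_ring_rev = np.zeros(n)
    w_up = np.zeros(n)
    w_down = np.zeros(n)
    w_x = None

    g = nx.DiGraph()
    g.add_nodes_from(range(n))

    ring_kinds = ("one_way_ring", "two_way_ring", "hybrid")
    if spec.kind in ring_kinds:
        w_ring = _nonzero(_draw(rng, law, scale, (n,)), rng, law, scale)
        # neuron s receives from neuron s-1 (mod N)
        g.add_edges_from(((s - 1) % n, s) for s in range(n))
    if spec.kind == "two_way_ring":
        w_ring_rev = _nonzero(_draw(rng, law, scale, (n,)), rng, law, scale)
        g.add_edges_from(((s + 1) % n, s) for s in range(n))
    if spec.kind in ("center", "hybrid"):
        w_up = _nonzero(_draw(rng, law, scale, (n,)), rng, law, scale)
        w_down = _nonzero(_draw(rng, law, scale, (n,)), rng, law, scale)
        g.add_node(CENTER_NODE)
        g.add_edges_from((s, CENTER_NODE) for s in range(n))
        g.add_edges_from((CENTER_NODE, s) for s in range(n))
    if spec.kind == "random":
        w_x = _draw(rng, law, scale, (n, n))
        mask = rng.random((n, n)) < spec.connectivity
        np.fill_diagonal(mask, False)  # no self-loops
        w_x = np.where(mask, w_x, 0.0)
        g.add_edges_from(
            (j, i) for i in range(n) for j in range(n) if w_x[i, j] != 0.0
        )

    return ReservoirWeights(
        spec=spec,
        w_in=w_in,
        w_ring=w_ring,
        w_ring_rev=w_ring_rev,
        w_up=w_up,
        w_down=w_down,
        w_x=w_x,
        graph=g,
    )


def _nonzero(w: np.ndarray, rng, law, scale) -> np.ndarray:
    # an exactly-zero draw would silently delete a structural link
    while np.any(w == 0.0):
        idx = w == 0.0
        w[idx] = _draw(rng, law, scale, (int(idx.sum()),))
    return w


def _reservoir_distances(weights: ReservoirWeights) -> np.ndarray:
    """All-pairs shortest directed distances between reservoir neurons.

    Paths may route through the center node but the center is never an
    endpoint. Unreachable pairs are ``inf``.
    """
    n = weights.n
    dist = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(weights.graph):
        if src == CENTER_NODE:
            continue
        for dst, d in lengths.items():
            if dst == CENTER_NODE:
                continue
            dist[src, dst] = d
    return dist


def graph_diameter(weights: ReservoirWeights) -> float:
    """Longest shortest directed path over ordered reservoir-neuron pairs.

    Returns :data:`INFINITE_DIAMETER` when some ordered pair is
    unreachable. For the hybrid topology the result is 2 for any N >= 3;
    for the one-way ring it is N - 1.
    """
    n = weights.n
    if n < 2:
        return 0
    dist = _reservoir_distances(weights)
    off = dist[~np.eye(n, dtype=bool)]
    dmax = off.max()
    return INFINITE_DIAMETER if math.isinf(dmax) else int(dmax)


def average_distance(weights: ReservoirWeights) -> float:
    """Mean shortest directed distance over ordered pairs of distinct neurons."""
    n = weights.n
    if n < 2:
        return 0.0
    dist = _reservoir_distances(weights)
    off = dist[~np.eye(n, dtype=bool)]
    if np.isinf(off).any():
        return INFINITE_DIAMETER
    return float(off.mean())


def synapses_per_neuron(weights: ReservoirWeights) -> np.ndarray:
    """Number of synaptic links owned by each reservoir neuron.

    Counts the input synapse, the ring synapse(s) feeding the neuron and,
    for center/hybrid kinds, the up and down synapses coupling it to the
    hub.  The hybrid thus has 4 per neuron, two more than the one-way
    ring's 2 (input + ring); the output tap is not a weighted synapse and
    is not counted.
    """
    n = weights.n
    count = np.ones(n, dtype=int)  # input synapse
    kind = weights.kind
    if kind in ("one_way_ring", "hybrid"):
        count += 1
    elif kind == "two_way_ring":
        count += 2
    if kind in ("center", "hybrid"):
        count += 2  # up + down
    if kind == "random":
        count += np.count_nonzero(weights.w_x, axis=1)
    return count


def n_synapses(weights: ReservoirWeights) -> int:
    """Total synapse count of the reservoir.

    Counts one input synapse per neuron per input channel plus every
    recurrent/hub synapse; used by the area and power cost models.
    """
    per_neuron = synapses_per_neuron(weights)
    extra_inputs = (weights.spec.k - 1) * weights.n  # K > 1 input channels
    return int(per_neuron.sum()) + extra_inputs


def toroidal_report(weights: ReservoirWeights, rows: int, cols: int):
    """Describe the doubly twisted toroidal placement of a hybrid reservoir.

    Each neuron is assigned to one torus node of a ``rows x cols`` grid in
    row-major ring order.  A torus node carries eight physical links — two
    per ring (input, ring, center, output) — of which four are incoming:
    the input-ring tap, the ring link from the predecessor neuron, the
    center-ring down link, and the output-ring pass-through.  The report is
    purely descriptive (no physical place and route is attempted).

    Returns a :class:`pandas.DataFrame` with one row per (neuron, link).
    """
    import pandas as pd

    if weights.kind != "hybrid":
        raise ConfigurationError(
            f"toroidal_report requires kind='hybrid', got {weights.kind!r}"
        )
    n = weights.n
    if rows * cols != n:
        raise ShapeError(f"rows*cols = {rows}*{cols} = {rows * cols} != n = {n}")

    records = []
    for s in range(n):
        r, c = divmod(s, cols)
        links = [
            ("input", "in"), ("input", "out"),
            ("ring", "in"), ("ring", "out"),
            ("center_down", "in"), ("center_up", "out"),
            ("output", "in"), ("output", "out"),
        ]
        for ring_name, direction in links:
            records.append(
                {
                    "neuron": s,
                    "row": r,
                    "col": c,
                    "ring": ring_name,
                    "direction": direction,
                }
            )
    return pd.DataFrame.from_records(records)
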