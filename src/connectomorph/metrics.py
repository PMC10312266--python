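"""Binary undirected graph metrics and degree-preserving null models.

Implements the nine network-level metrics used throughout the trade-off
analyses — clustering coefficient (Cp), characteristic path length (Lp),
their null-normalized forms (gamma, lambda), small-worldness (sigma = gamma /
lambda), global and local efficiency (Eg, Eloc), Newman-Girvan modularity (Q)
and module count (Mn) — plus Maslov-Sneppen degree-preserving rewiring for
the null ensembles that normalize the small-world metrics.

Conventions for disconnected graphs: Eg treats unreachable pairs as
contributing 0 (1/inf); Lp averages over reachable pairs only (an error-mode
alternative is available); nodes with degree < 2 contribute 0 to Cp and to
nodal local efficiency.

Community detection uses the Louvain algorithm (igraph's C implementation)
restarted with distinct sub-seeds; the best-Q partition is kept, with ties
broken by first occurrence so results are deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np

from . import _kernels
from .network import BinaryNetwork

__all__ = [
    "NullEnsembleConfig",
    "MetricVector",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "characteristic_path_length",
    "modularity_louvain",
    "degree_preserving_rewire",
    "small_world_metrics",
    "metric_vector",
]

# igraph draws from this dedicated RNG; reseeded before every Louvain call so
# partitions are reproducible without touching the global `random` state.
_IG_RNG = random.Random()
ig.set_random_number_generator(_IG_RNG)


@dataclass(frozen=True)
class NullEnsembleConfig:
    """Degree-preserving null ensemble settings.

    ``n_nulls`` rewired networks, each produced by ``swaps_per_edge * m``
    attempted double-edge swaps on an m-edge network.
    """

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1 or self.swaps_per_edge < 1:
            raise ValueError("n_nulls and swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class MetricVector:
    """The nine network-level topological metrics of one network."""

    cp: float
    lp: float
    gamma: float
    lambda_: float
    sigma: float
    eg: float
    eloc: float
    q: float
    mn: int

    NAMES = ("cp", "lp", "gamma", "lambda_", "sigma", "eg", "eloc", "q", "mn")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.NAMES], dtype=float)


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d(i, j) over ordered node pairs; unreachable pairs add 0."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return _kernels.global_efficiency_adj(net.adjacency)


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean nodal local efficiency (efficiency of each neighbor subgraph)."""
    if net.n_nodes < 2:
        raise ValueError("local efficiency requires at least 2 nodes")
    return _kernels.local_efficiency_adj(net.adjacency)


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Watts-Strogatz mean clustering coefficient."""
    if net.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    return _kernels.clustering_adj(net.adjacency)


def characteristic_path_length(
    net: BinaryNetwork, disconnected: str = "ignore"
) -> float:
    """Mean shortest-path length.

    ``disconnected="ignore"`` (default) averages over reachable ordered pairs
    only; ``"error"`` raises if any off-diagonal pair is unreachable.
    """
    dist = _kernels.hop_distances(net.adjacency)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = off & np.isfinite(dist)
    if disconnected == "error" and finite.sum() < off.sum():
        raise ValueError("network is disconnected")
    if not finite.any():
        raise ValueError("no reachable node pair: path length undefined")
    return float(dist[finite].mean())


def _louvain_best(
    adj: np.ndarray, n_restarts: int, seed: int
) -> tuple[float, np.ndarray]:
    """Best-of-restarts Louvain partition; returns (Q, membership array)."""
    if adj.sum() == 0:
        raise ValueError("modularity undefined on an edgeless network")
    iu, ju = np.nonzero(np.triu(adj, 1))
    g = ig.Graph(n=adj.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))
    best_q, best_part = -np.inf, None
    for restart in range(n_restarts):
        _IG_RNG.seed((int(seed) * 1_000_003 + restart) % (2**31))
        part = g.community_multilevel()
        q = part.modularity  # igraph's C Newman-Girvan score, for ranking only
        if q > best_q:  # strict: ties keep the first-found partition
            best_q, best_part = q, part
    membership = np.asarray(best_part.membership)
    return _kernels.newman_girvan_q(adj, membership), membership


def modularity_louvain(
    net: BinaryNetwork, n_restarts: int = 100, seed: int = 0
) -> tuple[float, dict[str, int]]:
    """Best-of-restarts Louvain modularity and its partition.

    Returns (Q, partition) where partition maps node label -> module id.
    """
    q, membership = _louvain_best(net.adjacency, n_restarts, seed)
    return q, {lab: int(m) for lab, m in zip(net.node_labels, membership)}


def _rewire_adjacency(
    adj: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> np.ndarray:
    a = adj.astype(bool).copy()
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = np.column_stack([iu, ju])
    m = len(edges)
    pick = rng.integers(0, m, size=(n_attempts, 2))
    orient = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if orient[t]:
            x, y = y, x
        # propose (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y or a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = False
        a[x, y] = a[y, x] = False
        a[u, x] = a[x, u] = True
        a[v, y] = a[y, v] = True
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
    return a.astype(np.uint8)


def degree_preserving_rewire(
    net: BinaryNetwork, cfg: NullEnsembleConfig = NullEnsembleConfig()
) -> list[BinaryNetwork]:
    """Maslov-Sneppen double-edge-swap null networks.

    Every null has exactly the degree sequence (hence node and edge counts)
    of the input.  Each null applies ``swaps_per_edge * m`` attempted swaps.
    """
    m = net.n_edges
    if m < 2:
        raise ValueError("cannot rewire a network with fewer than 2 edges")
    rng = np.random.default_rng(cfg.seed)
    attempts = cfg.swaps_per_edge * m
    return [
        BinaryNetwork(
            _rewire_adjacency(net.adjacency, attempts, rng), net.node_labels
        )
        for _ in range(cfg.n_nulls)
    ]


def small_world_metrics(
    net: BinaryNetwork,
    cfg: NullEnsembleConfig = NullEnsembleConfig(),
    nulls: list[BinaryNetwork] | None = None,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) normalized against degree-preserving nulls.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda.
    A precomputed null ensemble can be passed to share it across metrics.
    """
    if nulls is None:
        nulls = degree_preserving_rewire(net, cfg)
    null_cp = np.mean([_kernels.clustering_adj(n.adjacency) for n in nulls])
    null_lp = np.mean([_kernels.path_length_adj(n.adjacency) for n in nulls])
    if null_cp == 0 or null_lp == 0:
        raise ValueError("null ensemble has zero mean Cp or Lp")
    gamma = clustering_coefficient(net) / null_cp
    lambda_ = characteristic_path_length(net) / null_lp
    return float(gamma), float(lambda_), float(gamma / lambda_)


def metric_vector(
    net: BinaryNetwork,
    cfg: NullEnsembleConfig = NullEnsembleConfig(),
    louvain_restarts: int = 100,
) -> MetricVector:
    """Bundle the nine metrics; Q and Mn come from the same best partition."""
    cp = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    gamma, lambda_, sigma = small_world_metrics(net, cfg)
    eg = global_efficiency(net)
    eloc = local_efficiency(net)
    q, partition = modularity_louvain(net, n_restarts=louvain_restarts, seed=cfg.seed)
    return MetricVector(
        cp=cp,
        lp=lp,
        gamma=gamma,
        lambda_=lambda_,
        sigma=sigma,
        eg=eg,
        eloc=eloc,
        q=q,
        mn=len(set(partition.values())),
    )
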