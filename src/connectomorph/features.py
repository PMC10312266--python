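"""Representative-network extraction and node-level / robustness analyses.

Covers: selecting the archive member that best recovers the empirical group
network within its cost range; agreement between modular partitions (greedy
module matching followed by Cohen's kappa); nodal degree correlation; hub
identification (top 20% degree) and hub overlap; and random / targeted node
attack curves with their trapezoidal AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from . import _kernels
from .comparison import cost_range_filter, recovery_rate
from .evolution import ParetoArchive
from .network import BinaryNetwork

__all__ = [
    "PartitionAgreement",
    "HubReport",
    "AttackCurve",
    "select_representative",
    "partition_kappa",
    "degree_correlation",
    "identify_hubs",
    "hub_overlap",
    "random_attack",
    "targeted_attack",
    "attack_auc",
]

ATTACK_FRACTIONS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class PartitionAgreement:
    kappa: float
    matched_label_map: dict[int, int]
    contingency: np.ndarray


@dataclass(frozen=True)
class HubReport:
    hub_set: frozenset[str]
    threshold_rank: int
    fully_tied: bool = False

    def overlap(self, other: "HubReport") -> int:
        return len(self.hub_set & other.hub_set)


@dataclass(frozen=True)
class AttackCurve:
    removal_fractions: tuple[float, ...]
    preserved_eg: np.ndarray
    preserved_eloc: np.ndarray
    eg_sd: np.ndarray | None = None
    eloc_sd: np.ndarray | None = None
    repetitions: int = 1


def select_representative(
    archive: ParetoArchive,
    empirical: BinaryNetwork,
    cost_min: float,
    cost_max: float,
    rule: str = "geometric",
) -> BinaryNetwork:
    """Archive member with the highest recovery rate within the cost range.

    Ties are broken by lower F_c, then lexicographically smaller genome, so
    the choice is deterministic.
    """
    filtered = cost_range_filter(archive, cost_min, cost_max)
    if not filtered.members:
        raise ValueError("no archive member inside the cost range")
    scored = [
        (
            -recovery_rate(net, empirical, rule=rule).r,
            obj.f_c,
            net.genome().tobytes(),
            net,
        )
        for net, obj in filtered.members
    ]
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def _as_membership(partition, labels: tuple[str, ...]) -> np.ndarray:
    if isinstance(partition, dict):
        return np.array([partition[lab] for lab in labels])
    return np.asarray(partition)


def partition_kappa(
    p1: dict[str, int] | np.ndarray,
    p2: dict[str, int] | np.ndarray,
    node_labels: tuple[str, ...] | None = None,
) -> PartitionAgreement:
    """Cohen's kappa between two modular partitions after module matching.

    Module labels of ``p2`` are aligned to ``p1`` by a greedy one-to-one
    maximum-overlap assignment on the contingency table; unmatched modules
    receive fresh labels.  Kappa is then computed on the aligned vectors.
    """
    if isinstance(p1, dict) != isinstance(p2, dict):
        raise ValueError("partitions must both be dicts or both arrays")
    if isinstance(p1, dict):
        if set(p1) != set(p2):
            raise ValueError("partitions must cover the same node set")
        node_labels = tuple(sorted(p1))
    m1 = _as_membership(p1, node_labels)
    m2 = _as_membership(p2, node_labels)
    if m1.shape != m2.shape:
        raise ValueError("partitions must cover the same node set")
    mods1, inv1 = np.unique(m1, return_inverse=True)
    mods2, inv2 = np.unique(m2, return_inverse=True)
    contingency = np.zeros((len(mods1), len(mods2)), dtype=np.int64)
    np.add.at(contingency, (inv1, inv2), 1)
    # greedy one-to-one matching on descending overlap (ties by index)
    order = np.argsort(-contingency, axis=None, kind="stable")
    used1: set[int] = set()
    used2: set[int] = set()
    mapping: dict[int, int] = {}
    for flat in order:
        i, j = divmod(int(flat), len(mods2))
        if i in used1 or j in used2 or contingency[i, j] == 0:
            continue
        mapping[int(mods2[j])] = int(mods1[i])
        used1.add(i)
        used2.add(j)
        if len(mapping) == min(len(mods1), len(mods2)):
            break
    fresh = int(max(mods1.max(), mods2.max())) + 1
    aligned = np.empty_like(m2)
    for j, mod in enumerate(mods2):
        if int(mod) in mapping:
            aligned[m2 == mod] = mapping[int(mod)]
        else:
            aligned[m2 == mod] = fresh
            fresh += 1
    kappa = 1.0 if np.array_equal(m1, aligned) else float(
        cohen_kappa_score(m1, aligned)
    )
    return PartitionAgreement(kappa, mapping, contingency)


def degree_correlation(a: BinaryNetwork, b: BinaryNetwork) -> tuple[float, float]:
    """Pearson correlation of nodal degrees with two-sided p-value."""
    if a.n_nodes != b.n_nodes:
        raise ValueError("networks must share the node ordering")
    da, db = a.degrees().astype(float), b.degrees().astype(float)
    if da.std() == 0 or db.std() == 0:
        raise ValueError("degree correlation undefined: zero variance")
    r, p = stats.pearsonr(da, db)
    return float(r), float(p)


def identify_hubs(net: BinaryNetwork, top_fraction: float = 0.20) -> HubReport:
    """Top ``floor(top_fraction * N)`` nodes by degree (ties by node index)."""
    if net.n_nodes < 5:
        raise ValueError("hub identification needs at least 5 nodes")
    k = int(np.floor(top_fraction * net.n_nodes))
    deg = net.degrees()
    order = np.argsort(-deg, kind="stable")  # descending degree, index ties
    hubs = frozenset(net.node_labels[i] for i in order[:k])
    return HubReport(hubs, k, fully_tied=bool(deg.min() == deg.max()))


def hub_overlap(h1: HubReport, h2: HubReport) -> int:
    return h1.overlap(h2)


def _subgraph_efficiencies(adj: np.ndarray, keep: np.ndarray) -> tuple[float, float]:
    sub = adj[np.ix_(keep, keep)]
    if sub.shape[0] < 2:
        return 0.0, 0.0
    return (
        _kernels.global_efficiency_adj(sub),
        _kernels.local_efficiency_adj(sub),
    )


def random_attack(
    net: BinaryNetwork, repetitions: int = 100, seed: int = 0
) -> AttackCurve:
    """Efficiency decay under uniform random node removal.

    At each fraction f in 0.1..0.9, ``round(f * N)`` nodes are removed and
    Eg/Eloc recomputed on the remaining induced subgraph; curves are averaged
    over repetitions with the standard deviation recorded.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    eg = np.empty((repetitions, len(ATTACK_FRACTIONS)))
    eloc = np.empty_like(eg)
    for rep in range(repetitions):
        order = rng.permutation(n)
        for fi, f in enumerate(ATTACK_FRACTIONS):
            keep = np.sort(order[int(round(f * n)):])
            eg[rep, fi], eloc[rep, fi] = _subgraph_efficiencies(net.adjacency, keep)
    return AttackCurve(
        ATTACK_FRACTIONS,
        eg.mean(axis=0),
        eloc.mean(axis=0),
        eg.std(axis=0),
        eloc.std(axis=0),
        repetitions,
    )


def targeted_attack(net: BinaryNetwork, adaptive: bool = False) -> AttackCurve:
    """Efficiency decay removing nodes in descending degree order.

    Static mode (default) ranks by initial degree once; adaptive mode
    recomputes degrees after each removal.  Degree ties break by node index.
    """
    n = net.n_nodes
    if adaptive:
        order = []
        alive = np.ones(n, dtype=bool)
        adj = net.adjacency.astype(np.int64)
        for _ in range(n):
            deg = np.where(alive, (adj[:, alive]).sum(axis=1), -1)
            victim = int(np.argmax(deg))  # argmax takes the lowest index on ties
            order.append(victim)
            alive[victim] = False
    else:
        order = np.argsort(-net.degrees(), kind="stable").tolist()
    eg = np.empty(len(ATTACK_FRACTIONS))
    eloc = np.empty_like(eg)
    for fi, f in enumerate(ATTACK_FRACTIONS):
        keep = np.sort(np.array(order[int(round(f * n)):], dtype=np.int64))
        eg[fi], eloc[fi] = _subgraph_efficiencies(net.adjacency, keep)
    return AttackCurve(ATTACK_FRACTIONS, eg, eloc)


def attack_auc(curve: AttackCurve) -> tuple[float, float]:
    """Trapezoidal AUC of raw preserved Eg and Eloc over fractions 0.1-0.9."""
    x = np.asarray(curve.removal_fractions)
    if np.isnan(curve.preserved_eg).any() or np.isnan(curve.preserved_eloc).any():
        raise ValueError("attack curve has missing grid points")
    return (
        float(np.trapezoid(curve.preserved_eg, x)),
        float(np.trapezoid(curve.preserved_eloc, x)),
    )
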