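"""Trade-off model objective functions and Pareto dominance.

Three trade-off models are defined over a binary network embedded in region
geometry.  All share the cost objective

    F_c = sum of Euclidean centroid distances over connected region pairs (mm)

and differ in the efficiency objective F_e (both minimized; smaller F_e means
better communication efficiency):

    dual      F_e = 1 - Eg
    tri_eloc  F_e = w_Eloc (1 - Eg) + (1 - w_Eloc)(1 - Eloc)
    tri_q     F_e = w_Q (1 - Eg) + (1 - w_Q)(1 - Q)

with default weights w_Eloc = 0.9 and w_Q = 0.8.  The efficiency index
1 - F_e together with F_c spans the model's morphospace.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels
from .metrics import _louvain_best
from .network import BinaryNetwork, RegionGeometry

__all__ = [
    "MODEL_NAMES",
    "TradeoffModelSpec",
    "ObjectivePair",
    "wiring_cost",
    "efficiency_objective",
    "evaluate_network",
    "dominates",
]

MODEL_NAMES = ("dual", "tri_eloc", "tri_q")


@dataclass(frozen=True)
class TradeoffModelSpec:
    """One trade-off model: name, segregation weights, Louvain policy.

    ``louvain_restarts`` is the in-loop restart count used when Q enters the
    objective (kept small because evolution needs ~1e5 evaluations; final
    reporting uses :func:`connectomorph.metrics.modularity_louvain` with its
    own, larger default).
    """

    name: str = "dual"
    w_eloc: float = 0.9
    w_q: float = 0.8
    louvain_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")
        if not (0 < self.w_eloc < 1 and 0 < self.w_q < 1):
            raise ValueError("weights must lie strictly inside (0, 1)")
        if self.louvain_restarts < 1:
            raise ValueError("louvain_restarts must be >= 1")


@dataclass(frozen=True)
class ObjectivePair:
    """(F_c, F_e) evaluation of one network under one trade-off model."""

    f_c: float
    f_e: float

    def __post_init__(self) -> None:
        if self.f_c < 0:
            raise ValueError("F_c must be nonnegative")
        if not -1e-9 <= self.f_e <= 1 + 1e-9:
            raise ValueError("F_e must lie in [0, 1]")

    @property
    def efficiency_index(self) -> float:
        return 1.0 - self.f_e


def wiring_cost(net: BinaryNetwork, geom: RegionGeometry) -> float:
    """F_c: sum of Euclidean distances over connected region pairs (mm)."""
    if geom.n_regions != net.n_nodes:
        raise ValueError("geometry does not match network node count")
    return float((net.adjacency * geom.distance).sum() / 2.0)


def _efficiency_from_adj(adj, spec: TradeoffModelSpec, louvain_seed: int) -> float:
    eg = _kernels.global_efficiency_adj(adj)
    if spec.name == "dual":
        return 1.0 - eg
    if spec.name == "tri_eloc":
        eloc = _kernels.local_efficiency_adj(adj)
        return spec.w_eloc * (1.0 - eg) + (1.0 - spec.w_eloc) * (1.0 - eloc)
    q, _ = _louvain_best(adj, spec.louvain_restarts, louvain_seed)
    return spec.w_q * (1.0 - eg) + (1.0 - spec.w_q) * (1.0 - max(q, 0.0))


def efficiency_objective(net: BinaryNetwork, spec: TradeoffModelSpec) -> float:
    """F_e under the given model (smaller is better).

    For ``tri_q`` the modularity term is the best-of-restarts Louvain Q with
    the spec's seed; an edgeless network raises because Q is undefined.
    """
    return _efficiency_from_adj(net.adjacency, spec, spec.seed)


def evaluate_network(
    net: BinaryNetwork, geom: RegionGeometry, spec: TradeoffModelSpec
) -> ObjectivePair:
    """Joint (F_c, F_e) evaluation; deterministic for a fixed spec seed."""
    return ObjectivePair(wiring_cost(net, geom), efficiency_objective(net, spec))


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """Pareto dominance with both objectives minimized."""
    return (
        a.f_c <= b.f_c
        and a.f_e <= b.f_e
        and (a.f_c < b.f_c or a.f_e < b.f_e)
    )
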