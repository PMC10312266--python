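"""Comparing synthetic networks with empirical ones.

Recovery rate R combines the fraction of empirical non-edges reproduced (R0)
and the fraction of empirical edges reproduced (R1) over the off-diagonal
upper triangle.  The default combination is the geometric mean
sqrt(R0 * R1); the raw product is available via ``rule="product"``.
Distance-binned recovery restricts the same statistic to node pairs whose
centroid distance falls in 20 mm bins spanning 0-120 mm, and the mid/long
range AUC integrates per-bin R over bin midpoints at and above 40 mm.
Topological dissimilarity z-scores the nine network metrics over the pooled
synthetic + empirical set and measures each synthetic network's Euclidean
distance to the empirical centroid in that normalized space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .evolution import ParetoArchive
from .metrics import MetricVector
from .network import BinaryNetwork, RegionGeometry

__all__ = [
    "DEFAULT_BIN_EDGES",
    "RecoveryReport",
    "DistanceBinReport",
    "DissimilarityReport",
    "recovery_rate",
    "distance_binned_recovery",
    "bin_auc",
    "cost_range_filter",
    "topological_dissimilarity",
]

DEFAULT_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)


@dataclass(frozen=True)
class RecoveryReport:
    r: float
    r0: float
    r1: float
    rule: str = "geometric"


@dataclass(frozen=True)
class DistanceBinReport:
    bin_edges: tuple[float, ...]
    per_bin_r: tuple[float | None, ...]
    per_bin_r1: tuple[float | None, ...]
    per_bin_pairs: tuple[int, ...] | None = None  # None: pair counts unknown
    overflow_pairs: int = 0

    def midpoints(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return (edges[:-1] + edges[1:]) / 2.0


@dataclass(frozen=True)
class DissimilarityReport:
    per_network_distance: dict[str, np.ndarray]
    metric_names: tuple[str, ...]
    normalization_mean: np.ndarray
    normalization_sd: np.ndarray
    empirical_centroid: np.ndarray
    excluded_metrics: tuple[str, ...] = ()


def _combine(r0: float, r1: float, rule: str) -> float:
    if rule == "geometric":
        return math.sqrt(r0 * r1)
    if rule == "product":
        return r0 * r1
    raise ValueError(f"unknown combination rule {rule!r}")


def _upper_entries(net: BinaryNetwork) -> np.ndarray:
    return net.genome().astype(bool)


def recovery_rate(
    synthetic: BinaryNetwork,
    empirical: BinaryNetwork,
    rule: str = "geometric",
    _mask: np.ndarray | None = None,
) -> RecoveryReport:
    """Entry-overlap recovery of an empirical network by a synthetic one.

    R1 = matched empirical 1-entries / empirical 1-entries, R0 analogous for
    0-entries, both over the off-diagonal upper triangle (optionally
    restricted to ``_mask``); R combines them per ``rule``.
    """
    if synthetic.n_nodes != empirical.n_nodes:
        raise ValueError("networks must have the same node count")
    s, e = _upper_entries(synthetic), _upper_entries(empirical)
    if _mask is not None:
        s, e = s[_mask], e[_mask]
    ones = int(e.sum())
    zeros = int(e.size - ones)
    if ones == 0 or zeros == 0:
        raise ValueError("empirical network needs both 1- and 0-entries")
    r1 = float((s & e).sum() / ones)
    r0 = float((~s & ~e).sum() / zeros)
    return RecoveryReport(_combine(r0, r1, rule), r0, r1, rule)


def distance_binned_recovery(
    synthetic: BinaryNetwork,
    empirical: BinaryNetwork,
    geom: RegionGeometry,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    rule: str = "geometric",
) -> DistanceBinReport:
    """Recovery rate restricted to Euclidean-distance bins.

    Bins are left-closed/right-open, the last bin closed.  Bins without both
    empirical 1s and 0s are reported as missing (None), not 0.  Pairs beyond
    the last edge are counted in ``overflow_pairs`` and excluded.
    """
    if geom.n_regions != synthetic.n_nodes or geom.n_regions != empirical.n_nodes:
        raise ValueError("geometry must match both networks")
    dvec = geom.upper_tri_distances()
    edges = np.asarray(bin_edges, dtype=float)
    per_r: list[float | None] = []
    per_r1: list[float | None] = []
    per_pairs: list[int] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dvec >= lo) & ((dvec <= hi) if hi == edges[-1] else (dvec < hi))
        per_pairs.append(int(mask.sum()))
        try:
            rep = recovery_rate(synthetic, empirical, rule=rule, _mask=mask)
            per_r.append(rep.r)
            per_r1.append(rep.r1)
        except ValueError:
            per_r.append(None)
            per_r1.append(None)
    overflow = int((dvec > edges[-1]).sum())
    return DistanceBinReport(
        tuple(edges), tuple(per_r), tuple(per_r1), tuple(per_pairs), overflow
    )


def bin_auc(
    report: DistanceBinReport, min_distance: float = 40.0, method: str = "trapezoid"
) -> float:
    """Area under per-bin recovery at bin midpoints >= ``min_distance`` (mm).

    The default trapezoid rule integrates R over the midpoint span (e.g.
    midpoints 50/70/90/110 mm for the 40-120 mm bins); ``method="rectangle"``
    sums R times bin width instead.  Bins containing no node pairs at all
    (geometry never reaches that distance) are excluded; bins that have
    pairs but a missing recovery value raise.
    """
    mids = report.midpoints()
    pair_counts = report.per_bin_pairs or (1,) * len(mids)
    keep, widths = [], []
    for m, r, lo, hi, pairs in zip(
        mids,
        report.per_bin_r,
        report.bin_edges[:-1],
        report.bin_edges[1:],
        pair_counts,
    ):
        if lo < min_distance or pairs == 0:
            continue
        if r is None:
            raise ValueError("bins at/above min_distance have missing recovery values")
        keep.append((m, r))
        widths.append(hi - lo)
    xs = np.array([m for m, _ in keep])
    ys = np.array([r for _, r in keep])
    if method == "rectangle":
        return float((ys * np.array(widths)).sum())
    if len(xs) < 2:
        raise ValueError("need at least 2 bins for a trapezoid AUC")
    return float(np.trapezoid(ys, xs))


def cost_range_filter(
    archive: ParetoArchive, cost_min: float, cost_max: float
) -> ParetoArchive:
    """Members whose F_c falls in [cost_min, cost_max] (inclusive)."""
    if cost_min > cost_max:
        raise ValueError("cost_min must not exceed cost_max")
    members = [
        (net, obj) for net, obj in archive.members if cost_min <= obj.f_c <= cost_max
    ]
    return replace(archive, members=members)


def topological_dissimilarity(
    synthetic_vectors: dict[str, list[MetricVector]],
    empirical_vectors: list[MetricVector],
) -> DissimilarityReport:
    """Distance of each synthetic network to the empirical metric centroid.

    Each of the nine metrics is z-scored over the pooled set (all synthetic
    networks of all models plus all empirical networks); metrics with zero
    spread are excluded and flagged.  The centroid is the mean normalized
    empirical vector.
    """
    pooled = [
        mv.as_array() for vecs in synthetic_vectors.values() for mv in vecs
    ] + [mv.as_array() for mv in empirical_vectors]
    if len(pooled) < 2:
        raise ValueError("need at least 2 networks for z-score normalization")
    if not empirical_vectors:
        raise ValueError("need at least one empirical network")
    pooled = np.array(pooled)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    names = np.array(MetricVector.NAMES)
    keep = sd > 0
    centroid = (
        (np.array([mv.as_array() for mv in empirical_vectors]) - mean) / np.where(keep, sd, 1.0)
    )[:, keep].mean(axis=0)
    distances = {}
    for model, vecs in synthetic_vectors.items():
        if vecs:
            z = (np.array([mv.as_array() for mv in vecs]) - mean)[:, keep] / sd[keep]
            distances[model] = np.sqrt(((z - centroid) ** 2).sum(axis=1))
        else:
            distances[model] = np.array([])
    return DissimilarityReport(
        per_network_distance=distances,
        metric_names=tuple(names[keep]),
        normalization_mean=mean[keep],
        normalization_sd=sd[keep],
        empirical_centroid=centroid,
        excluded_metrics=tuple(names[~keep]),
    )
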