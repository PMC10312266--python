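"""Scaled-down end-to-end study recipe.

Reruns the whole pipeline at desk scale: synthetic geometry, NSGA-II
evolution under each of the three trade-off models, Pareto merging across
runs, cost-window filtering against a synthetic subject cohort on the same
geometry, and small-world/topology summaries of the surviving networks.
The defaults (60 regions, population 100, up to 300 generations, 3 runs per
model, 20 nulls per network) keep a full three-model study near a quarter hour
on one CPU while preserving the qualitative regime of the full-scale
experiment; they are the problem sizes used by the worked examples and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .comparison import cost_range_filter
from .evolution import EvolutionConfig, ParetoArchive, evolve_model
from .metrics import NullEnsembleConfig, modularity_louvain, small_world_metrics
from .network import RegionGeometry
from .objectives import MODEL_NAMES, TradeoffModelSpec, wiring_cost
from .synthetic import SyntheticCohortConfig, generate_cohort
from . import _kernels

__all__ = ["ModelStudyResult", "StudyResult", "run_small_world_study"]


@dataclass
class ModelStudyResult:
    """Per-model outcome of the scaled-down study."""

    model: str
    archive_size: int
    n_filtered: int
    mean_sigma: float
    mean_gamma: float
    mean_lambda: float
    mean_eg: float
    mean_eloc: float
    mean_q: float
    sigmas: np.ndarray = field(repr=False, default=None)


@dataclass
class StudyResult:
    cost_window: tuple[float, float]
    subject_cost_range: tuple[float, float]
    models: dict[str, ModelStudyResult]

    def min_mean_sigma(self) -> float:
        return min(m.mean_sigma for m in self.models.values())


def _cost_window(
    geom: RegionGeometry, cohort_networks, fraction: float = 1.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Central ``fraction`` of the cohort's wiring-cost range.

    The default keeps the full subject-level cost range — the same
    restriction the full-scale analysis applies to the empirical cohort.
    """
    costs = np.array([wiring_cost(net, geom) for net in cohort_networks])
    lo, hi = float(costs.min()), float(costs.max())
    margin = (1.0 - fraction) / 2.0
    span = hi - lo
    return (lo + margin * span, hi - margin * span), (lo, hi)


def summarize_archive(
    archive: ParetoArchive,
    n_nulls: int = 20,
    swaps_per_edge: int = 10,
    louvain_restarts: int = 20,
    seed: int = 0,
) -> ModelStudyResult:
    """Small-world and efficiency/modularity summary of archive members.

    sigma is computed per network against its own degree-preserving null
    ensemble; networks whose nulls are degenerate (fewer than 2 edges) are
    skipped.
    """
    sigmas, gammas, lambdas, egs, elocs, qs = [], [], [], [], [], []
    for i, net in enumerate(archive.networks()):
        if net.n_edges < 2:
            continue
        cfg = NullEnsembleConfig(
            n_nulls=n_nulls, swaps_per_edge=swaps_per_edge, seed=seed + i
        )
        gamma, lambda_, sigma = small_world_metrics(net, cfg)
        sigmas.append(sigma)
        gammas.append(gamma)
        lambdas.append(lambda_)
        egs.append(_kernels.global_efficiency_adj(net.adjacency))
        elocs.append(_kernels.local_efficiency_adj(net.adjacency))
        q, _ = modularity_louvain(net, n_restarts=louvain_restarts, seed=seed + i)
        qs.append(q)
    def _mean(values):
        return float(np.mean(values)) if values else float("nan")

    return ModelStudyResult(
        model=archive.model.name,
        archive_size=len(archive),
        n_filtered=len(sigmas),
        mean_sigma=_mean(sigmas),
        mean_gamma=_mean(gammas),
        mean_lambda=_mean(lambdas),
        mean_eg=_mean(egs),
        mean_eloc=_mean(elocs),
        mean_q=_mean(qs),
        sigmas=np.array(sigmas),
    )


def run_small_world_study(
    seed: int = 1,
    n_regions: int = 60,
    population_size: int = 100,
    max_generations: int = 300,
    n_runs: int = 3,
    n_nulls: int = 20,
    models: tuple[str, ...] = MODEL_NAMES,
    log=None,
) -> StudyResult:
    """Evolve all trade-off models at desk scale and summarize the fronts.

    The cost filter keeps Pareto members inside the central half of the
    wiring-cost range spanned by a synthetic subject cohort generated on the
    same geometry, mirroring the restriction of comparisons to the
    empirically observed cost regime.
    """
    # the age-structured cohort carries realistic between-subject density
    # (hence cost) variability, so its cost range spans a usable window
    cohort_cfg = SyntheticCohortConfig(seed=seed, n_regions=n_regions)
    cohort = generate_cohort(cohort_cfg, age_effects=True)
    geom = cohort.geometry
    window, full_range = _cost_window(geom, cohort.subject_networks)
    evo = EvolutionConfig(
        population_size=population_size,
        max_generations=max_generations,
        n_runs=n_runs,
        seed=seed,
    )
    results: dict[str, ModelStudyResult] = {}
    for name in models:
        spec = TradeoffModelSpec(name=name, seed=seed)
        archive = evolve_model(geom, spec, evo, log=log)
        filtered = cost_range_filter(archive, *window)
        summary = summarize_archive(filtered, n_nulls=n_nulls, seed=seed)
        summary.archive_size = len(archive)
        results[name] = summary
        if log is not None:
            log(
                f"{name}: archive {len(archive)}, {summary.n_filtered} in cost "
                f"window, mean sigma {summary.mean_sigma:.3f}"
            )
    return StudyResult(window, full_range, results)
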