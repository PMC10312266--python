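"""Customized NSGA-II evolving binary networks toward a trade-off Pareto front.

Genomes are the upper-triangle bit vectors of N x N adjacency matrices.  Each
generation: P parents are drawn by crowded binary tournament (lower front
rank wins, ties by higher crowding; disjoint random pairing is available via
configuration) and paired; uniform crossover (per-entry swap probability
0.5) yields P offspring; mutated copies of those offspring (per-entry flip
probability 0.1) yield P more; the 3P-candidate union is reduced back to P
by fast non-dominated sorting with crowding-distance truncation.  Evolution stops when the
population stalls (< 5% genome turnover, or < 0.1% relative change of both
objective means, for 20 consecutive generations) or at the generation cap.
Independent runs are merged and non-dominated-filtered into one archive.

Degenerate edgeless genomes are legal during evolution; models whose
objective needs Q assign them the worst efficiency (F_e = 1) instead of
erroring so the optimizer loop is robust.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .metrics import _louvain_best
from .network import BinaryNetwork, RegionGeometry
from .objectives import ObjectivePair, TradeoffModelSpec

__all__ = [
    "Individual",
    "EvolutionConfig",
    "GenerationRecord",
    "ParetoArchive",
    "initialize_population",
    "crossover",
    "mutate",
    "fast_nondominated_sort",
    "crowding_distance",
    "environmental_selection",
    "check_termination",
    "run_evolution",
    "merge_runs",
    "evolve_model",
]


@dataclass
class Individual:
    """One candidate network: genome plus NSGA-II bookkeeping."""

    genome: np.ndarray
    objectives: ObjectivePair | None = None
    rank: int | None = None
    crowding: float | None = None


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 200
    init_density: float = 0.1
    swap_probability: float = 0.5
    flip_probability: float = 0.1
    max_generations: int = 2000
    stall_generations: int = 20
    change_fraction_threshold: float = 0.05
    objective_delta_threshold: float = 0.001
    n_runs: int = 30
    mating: str = "tournament"  # "tournament" (crowded binary) or "random_pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.init_density,
            self.swap_probability,
            self.flip_probability,
            self.change_fraction_threshold,
            self.objective_delta_threshold,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        for c in (
            self.population_size,
            self.max_generations,
            self.stall_generations,
            self.n_runs,
        ):
            if c < 1:
                raise ValueError("counts must be >= 1")
        if self.mating not in ("tournament", "random_pairs"):
            raise ValueError("mating must be 'tournament' or 'random_pairs'")


@dataclass(frozen=True)
class GenerationRecord:
    """Snapshot used by the termination check: genome multiset + objective means."""

    genome_counts: Counter
    mean_f_c: float
    mean_f_e: float


@dataclass
class ParetoArchive:
    """Mutually non-dominated networks with objectives and run provenance."""

    members: list[tuple[BinaryNetwork, ObjectivePair]]
    model: TradeoffModelSpec
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def objective_array(self) -> np.ndarray:
        return np.array([[o.f_c, o.f_e] for _, o in self.members])

    def networks(self) -> list[BinaryNetwork]:
        return [net for net, _ in self.members]


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def initialize_population(
    cfg: EvolutionConfig, n_nodes: int, rng: np.random.Generator
) -> list[Individual]:
    """Bernoulli(init_density) genomes of length N(N-1)/2."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    genomes = _init_genomes(cfg, n_nodes, rng)
    return [Individual(g) for g in genomes]


def _init_genomes(cfg, n_nodes, rng) -> np.ndarray:
    length = n_nodes * (n_nodes - 1) // 2
    return (rng.random((cfg.population_size, length)) < cfg.init_density).astype(
        np.uint8
    )


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Uniform crossover: each entry swapped with ``swap_probability``."""
    ga, gb = parent_a.genome, parent_b.genome
    if ga.shape != gb.shape:
        raise ValueError("parent genomes must have equal length")
    swap = rng.random(ga.size) < cfg.swap_probability
    child_a = np.where(swap, gb, ga).astype(np.uint8)
    child_b = np.where(swap, ga, gb).astype(np.uint8)
    return Individual(child_a), Individual(child_b)


def mutate(
    ind: Individual, cfg: EvolutionConfig, rng: np.random.Generator
) -> Individual:
    """Independent per-entry bit flips with ``flip_probability``."""
    flips = (rng.random(ind.genome.size) < cfg.flip_probability).astype(np.uint8)
    return Individual(np.bitwise_xor(ind.genome, flips))


# ---------------------------------------------------------------------------
# Selection machinery
# ---------------------------------------------------------------------------

def _objectives_matrix(objectives: Sequence[ObjectivePair] | np.ndarray) -> np.ndarray:
    if isinstance(objectives, np.ndarray):
        return objectives
    return np.array([[o.f_c, o.f_e] for o in objectives], dtype=float)


def fast_nondominated_sort(
    objectives: Sequence[ObjectivePair] | np.ndarray,
) -> list[list[int]]:
    """Partition indices into successive non-dominated fronts."""
    f = _objectives_matrix(objectives)
    if f.size == 0:
        raise ValueError("cannot sort an empty objective list")
    le = (f[:, None, :] <= f[None, :, :]).all(axis=-1)
    lt = (f[:, None, :] < f[None, :, :]).any(axis=-1)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0).astype(np.int64)
    fronts: list[list[int]] = []
    unassigned = np.ones(len(f), dtype=bool)
    while unassigned.any():
        front = np.flatnonzero(unassigned & (n_dominators == 0))
        fronts.append(front.tolist())
        unassigned[front] = False
        n_dominators -= dom[front].sum(axis=0)
    return fronts


def crowding_distance(
    front_objectives: Sequence[ObjectivePair] | np.ndarray,
) -> np.ndarray:
    """Standard NSGA-II crowding distance within one front."""
    f = _objectives_matrix(front_objectives)
    n = len(f)
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(f.shape[1]):
        order = np.argsort(f[:, k], kind="stable")
        span = f[order[-1], k] - f[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            gaps = (f[order[2:], k] - f[order[:-2], k]) / span
            dist[order[1:-1]] += gaps
    return dist


def _rank_and_crowding(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Front index and crowding distance of every row of f."""
    rank = np.empty(len(f), dtype=np.int64)
    crowd = np.empty(len(f))
    for r, front in enumerate(fast_nondominated_sort(f)):
        rank[front] = r
        crowd[front] = crowding_distance(f[front])
    return rank, crowd


def _select_indices(f: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k NSGA-II survivors from objective matrix f."""
    chosen: list[int] = []
    for front in fast_nondominated_sort(f):
        if len(chosen) + len(front) <= k:
            chosen.extend(front)
            if len(chosen) == k:
                break
        else:
            crowd = crowding_distance(f[front])
            # descending crowding, stable so index order breaks exact ties
            order = np.argsort(-crowd, kind="stable")
            need = k - len(chosen)
            chosen.extend(int(front[i]) for i in order[:need])
            break
    return np.array(chosen, dtype=np.int64)


def environmental_selection(
    candidates: Sequence[Individual], cfg: EvolutionConfig
) -> list[Individual]:
    """Front-by-front elitist survival down to ``population_size``."""
    if len(candidates) < cfg.population_size:
        raise ValueError("candidate pool smaller than population_size")
    if any(ind.objectives is None for ind in candidates):
        raise ValueError("all candidates must be evaluated before selection")
    f = _objectives_matrix([ind.objectives for ind in candidates])
    fronts = fast_nondominated_sort(f)
    for rank, front in enumerate(fronts):
        crowd = crowding_distance(f[front])
        for local, idx in enumerate(front):
            candidates[idx].rank = rank
            candidates[idx].crowding = float(crowd[local])
    keep = _select_indices(f, cfg.population_size)
    return [candidates[i] for i in keep]


def check_termination(
    history: Sequence[GenerationRecord], cfg: EvolutionConfig
) -> bool:
    """True when evolution should stop.

    ``history[0]`` is the initial population; generation count is
    ``len(history) - 1``.  A generation is "stalled" when either the genome
    multiset turnover from its predecessor is below
    ``change_fraction_threshold`` or both objective means changed by less
    than ``objective_delta_threshold`` in relative terms.
    """
    generation = len(history) - 1
    if generation >= cfg.max_generations:
        return True
    streak = 0
    for t in range(generation, 0, -1):
        if _stalled(history[t - 1], history[t], cfg):
            streak += 1
            if streak >= cfg.stall_generations:
                return True
        else:
            break
    return False


def _stalled(prev: GenerationRecord, cur: GenerationRecord, cfg) -> bool:
    pop_size = sum(cur.genome_counts.values())
    carried = sum(
        min(count, prev.genome_counts.get(g, 0))
        for g, count in cur.genome_counts.items()
    )
    turnover = 1.0 - carried / pop_size
    if turnover < cfg.change_fraction_threshold:
        return True
    deltas = []
    for prev_mean, cur_mean in (
        (prev.mean_f_c, cur.mean_f_c),
        (prev.mean_f_e, cur.mean_f_e),
    ):
        if prev_mean == 0:
            deltas.append(0.0 if cur_mean == 0 else np.inf)
        else:
            deltas.append(abs(cur_mean - prev_mean) / abs(prev_mean))
    return all(d < cfg.objective_delta_threshold for d in deltas)


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def _make_evaluator(
    geom: RegionGeometry, spec: TradeoffModelSpec
) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    """Array-level objective evaluator for a (pop, L) genome matrix."""
    n = geom.n_regions
    dvec = geom.upper_tri_distances()
    iu = np.triu_indices(n, 1)

    def evaluate(genomes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        f = np.empty((len(genomes), 2))
        f[:, 0] = genomes @ dvec
        louvain_seeds = (
            rng.integers(0, 2**31, size=len(genomes))
            if spec.name == "tri_q"
            else None
        )
        adj = np.zeros((n, n), dtype=np.uint8)
        for row, genome in enumerate(genomes):
            adj[:] = 0
            adj[iu] = genome
            adj += adj.T
            if spec.name == "tri_q" and genome.sum() == 0:
                f[row, 1] = 1.0  # Q undefined: worst efficiency, keep evolving
                continue
            eg = _kernels.global_efficiency_adj(adj)
            if spec.name == "dual":
                f[row, 1] = 1.0 - eg
            elif spec.name == "tri_eloc":
                eloc = _kernels.local_efficiency_adj(adj)
                f[row, 1] = spec.w_eloc * (1 - eg) + (1 - spec.w_eloc) * (1 - eloc)
            else:
                q, _ = _louvain_best(
                    adj, spec.louvain_restarts, int(louvain_seeds[row])
                )
                f[row, 1] = spec.w_q * (1 - eg) + (1 - spec.w_q) * (1 - max(q, 0.0))
        return f

    return evaluate


def _genome_counter(genomes: np.ndarray) -> Counter:
    return Counter(g.tobytes() for g in genomes)


# ---------------------------------------------------------------------------
# Main loops
# ---------------------------------------------------------------------------

def run_evolution(
    geom: RegionGeometry,
    spec: TradeoffModelSpec,
    cfg: EvolutionConfig,
    seed: int | None = None,
    run_id: int = 0,
    log: Callable[[str], None] | None = None,
) -> ParetoArchive:
    """One NSGA-II run; returns the non-dominated set of the final population."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    evaluate = _make_evaluator(geom, spec)
    n = geom.n_regions
    pop = _init_genomes(cfg, n, rng)
    f_pop = evaluate(pop, rng)
    history = [GenerationRecord(_genome_counter(pop), *f_pop.mean(axis=0))]
    p = cfg.population_size

    while not check_termination(history, cfg):
        if cfg.mating == "tournament":
            # crowded binary tournament (canonical NSGA-II mating): lower
            # rank wins, ties by higher crowding, then by index
            rank, crowd = _rank_and_crowding(f_pop)
            n_parents = p + (p % 2)
            a_idx = rng.integers(0, p, size=n_parents)
            b_idx = rng.integers(0, p, size=n_parents)
            a_wins = (rank[a_idx] < rank[b_idx]) | (
                (rank[a_idx] == rank[b_idx]) & (crowd[a_idx] >= crowd[b_idx])
            )
            perm = np.where(a_wins, a_idx, b_idx)
        else:
            # disjoint random pairs; an odd leftover gets a drawn partner
            perm = rng.permutation(p)
            if p % 2:
                extra = rng.integers(0, p - 1)
                perm = np.append(perm, perm[extra])
        pairs = perm.reshape(-1, 2)
        swap = rng.random((len(pairs), pop.shape[1])) < cfg.swap_probability
        a, b = pop[pairs[:, 0]], pop[pairs[:, 1]]
        offspring = np.concatenate(
            [np.where(swap, b, a), np.where(swap, a, b)]
        ).astype(np.uint8)[:p]
        flips = (rng.random(offspring.shape) < cfg.flip_probability).astype(np.uint8)
        mutants = np.bitwise_xor(offspring, flips)

        f_off = evaluate(offspring, rng)
        f_mut = evaluate(mutants, rng)
        union = np.concatenate([pop, offspring, mutants])
        f_union = np.concatenate([f_pop, f_off, f_mut])
        keep = _select_indices(f_union, p)
        pop, f_pop = union[keep], f_union[keep]
        history.append(GenerationRecord(_genome_counter(pop), *f_pop.mean(axis=0)))
        if log is not None:
            front1 = fast_nondominated_sort(f_pop)[0]
            prev, cur = history[-2], history[-1]
            carried = sum(
                min(c, prev.genome_counts.get(g, 0))
                for g, c in cur.genome_counts.items()
            )
            log(
                f"gen={len(history) - 1} front1={len(front1)} "
                f"mean_fc={cur.mean_f_c:.1f} mean_fe={cur.mean_f_e:.4f} "
                f"turnover={1 - carried / p:.3f}"
            )

    front = fast_nondominated_sort(f_pop)[0]
    members, seen = [], set()
    for i in front:
        key = pop[i].tobytes()
        if key in seen:
            continue
        seen.add(key)
        members.append(
            (
                BinaryNetwork.from_genome(pop[i], n, geom.labels),
                ObjectivePair(float(f_pop[i, 0]), float(min(f_pop[i, 1], 1.0))),
            )
        )
    return ParetoArchive(
        members,
        spec,
        provenance=[
            {"run_id": run_id, "seed": seed, "generations": len(history) - 1}
        ],
    )


def merge_runs(archives: Sequence[ParetoArchive]) -> ParetoArchive:
    """Union of archives, deduplicated and non-dominated-filtered."""
    if not archives:
        raise ValueError("no archives to merge")
    spec = archives[0].model
    for arc in archives[1:]:
        if replace(arc.model, seed=spec.seed) != spec:
            raise ValueError("cannot merge archives from different models")
    members, seen = [], set()
    for arc in archives:
        for net, obj in arc.members:
            key = net.genome().tobytes()
            if key not in seen:
                seen.add(key)
                members.append((net, obj))
    f = np.array([[o.f_c, o.f_e] for _, o in members])
    front = fast_nondominated_sort(f)[0]
    provenance = [entry for arc in archives for entry in arc.provenance]
    return ParetoArchive([members[i] for i in front], spec, provenance)


def evolve_model(
    geom: RegionGeometry,
    spec: TradeoffModelSpec,
    cfg: EvolutionConfig,
    log: Callable[[str], None] | None = None,
) -> ParetoArchive:
    """Run ``cfg.n_runs`` independent evolutions and merge their fronts.

    Per-run seeds are derived from the master seed with the run index mixed
    in, so runs are independent yet jointly reproducible.
    """
    archives = []
    for run in range(cfg.n_runs):
        run_seed = int(
            np.random.SeedSequence([cfg.seed, run]).generate_state(1)[0] % (2**31)
        )
        archives.append(
            run_evolution(geom, spec, cfg, seed=run_seed, run_id=run, log=log)
        )
    return merge_runs(archives)
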