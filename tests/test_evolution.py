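"""NSGA-II machinery against brute-force oracles and its determinism contract."""

from collections import Counter

import numpy as np
import pytest

from connectomorph import (
    EvolutionConfig,
    Individual,
    ObjectivePair,
    RegionGeometry,
    TradeoffModelSpec,
    check_termination,
    crossover,
    crowding_distance,
    dominates,
    environmental_selection,
    fast_nondominated_sort,
    initialize_population,
    merge_runs,
    mutate,
    run_evolution,
)
from connectomorph.evolution import GenerationRecord


def brute_force_fronts(points: np.ndarray) -> list[list[int]]:
    """O(n^2)-per-front peeling using pairwise dominance only."""
    remaining = set(range(len(points)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                dominates(ObjectivePair(*points[j]), ObjectivePair(*points[i]))
                for j in remaining
                if j != i
            )
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestVariationOperators:
    def test_initialization_density_and_support(self, rng):
        cfg = EvolutionConfig(population_size=200, init_density=0.1)
        pop = initialize_population(cfg, 90, rng)
        genomes = np.array([ind.genome for ind in pop])
        assert genomes.shape == (200, 4005)
        assert set(np.unique(genomes)) <= {0, 1}
        assert genomes.mean() == pytest.approx(0.1, abs=0.01)

    def test_initialization_zero_density(self, rng):
        cfg = EvolutionConfig(population_size=5, init_density=0.0)
        pop = initialize_population(cfg, 10, rng)
        assert all(ind.genome.sum() == 0 for ind in pop)

    def test_crossover_identical_parents(self, rng):
        g = rng.integers(0, 2, 50).astype(np.uint8)
        a, b = crossover(Individual(g), Individual(g.copy()), EvolutionConfig(), rng)
        assert np.array_equal(a.genome, g) and np.array_equal(b.genome, g)

    def test_crossover_full_swap(self, rng):
        ga = rng.integers(0, 2, 50).astype(np.uint8)
        gb = rng.integers(0, 2, 50).astype(np.uint8)
        cfg = EvolutionConfig(swap_probability=1.0)
        a, b = crossover(Individual(ga), Individual(gb), cfg, rng)
        assert np.array_equal(a.genome, gb) and np.array_equal(b.genome, ga)

    def test_crossover_children_inherit_positionwise(self, rng):
        cfg = EvolutionConfig(swap_probability=0.5)
        for _ in range(10):
            ga = rng.integers(0, 2, 40).astype(np.uint8)
            gb = rng.integers(0, 2, 40).astype(np.uint8)
            a, b = crossover(Individual(ga), Individual(gb), cfg, rng)
            ok_a = (a.genome == ga) | (a.genome == gb)
            ok_b = (b.genome == ga) | (b.genome == gb)
            assert ok_a.all() and ok_b.all()
            # the two children are complementary: together they carry both
            # parental values at every position
            assert np.array_equal(
                np.sort(np.stack([a.genome, b.genome]), axis=0),
                np.sort(np.stack([ga, gb]), axis=0),
            )

    def test_mutation_extremes(self, rng):
        g = rng.integers(0, 2, 60).astype(np.uint8)
        same = mutate(Individual(g), EvolutionConfig(flip_probability=0.0), rng)
        flipped = mutate(Individual(g), EvolutionConfig(flip_probability=1.0), rng)
        assert np.array_equal(same.genome, g)
        assert np.array_equal(flipped.genome, 1 - g)

    def test_mutation_flip_count_binomial(self, rng):
        cfg = EvolutionConfig(flip_probability=0.1)
        g = np.zeros(1000, dtype=np.uint8)
        flips = [
            mutate(Individual(g), cfg, rng).genome.sum() for _ in range(200)
        ]
        assert np.mean(flips) == pytest.approx(100, rel=0.05)


class TestSorting:
    def test_worked_example(self):
        # the grid {(1,1),(1,2),(2,1),(2,2)} scaled into the objective domain
        pts = [
            ObjectivePair(1, 0.1),
            ObjectivePair(1, 0.2),
            ObjectivePair(2, 0.1),
            ObjectivePair(2, 0.2),
        ]
        assert fast_nondominated_sort(pts) == [[0], [1, 2], [3]]

    def test_single_point(self):
        assert fast_nondominated_sort([ObjectivePair(1, 0.5)]) == [[0]]

    def test_identical_points_share_a_front(self):
        pts = [ObjectivePair(1, 1)] * 4
        assert fast_nondominated_sort(pts) == [[0, 1, 2, 3]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fast_nondominated_sort(np.empty((0, 2)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 51))
            pts = np.round(rng.random((n, 2)) * 4) / 4  # force ties
            assert [
                sorted(f) for f in fast_nondominated_sort(pts)
            ] == brute_force_fronts(pts)


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([ObjectivePair(1, 0.2)])))
        assert np.all(
            np.isinf(crowding_distance([ObjectivePair(1, 0.2), ObjectivePair(2, 0.1)]))
        )

    def test_evenly_spaced_collinear_points(self):
        pts = [ObjectivePair(0, 0.0), ObjectivePair(1, 0.5), ObjectivePair(2, 1.0)]
        dist = crowding_distance(pts)
        assert dist[1] == pytest.approx(2.0)  # one normalized gap per objective
        assert np.isinf(dist[0]) and np.isinf(dist[2])

    def test_duplicated_interior_point_gets_zero(self):
        # standard crowding spans the i-1/i+1 neighbors, so a point whose
        # sorted neighbors are both its duplicates has zero gap
        pts = [
            ObjectivePair(0, 0.0),
            ObjectivePair(1, 0.1),
            ObjectivePair(1, 0.1),
            ObjectivePair(1, 0.1),
            ObjectivePair(3, 0.3),
        ]
        dist = crowding_distance(pts)
        assert dist[2] == 0.0


def brute_force_selection(candidates, k):
    """Independent NSGA-II survival reimplementation for small pools."""
    pts = np.array([[c.objectives.f_c, c.objectives.f_e] for c in candidates])
    fronts = brute_force_fronts(pts)
    chosen = []
    for front in fronts:
        if len(chosen) + len(front) <= k:
            chosen.extend(front)
        else:
            crowd = crowding_distance(pts[front])
            order = np.argsort(-crowd, kind="stable")
            chosen.extend(front[i] for i in order[: k - len(chosen)])
            break
    return sorted(chosen)


class TestEnvironmentalSelection:
    def _pool(self, rng, n):
        return [
            Individual(
                rng.integers(0, 2, 10).astype(np.uint8),
                objectives=ObjectivePair(
                    float(np.round(rng.random() * 4) / 4),
                    float(np.round(rng.random() * 4) / 4),
                ),
            )
            for _ in range(n)
        ]

    def test_full_front_returned_unchanged(self, rng):
        # mutually non-dominated staircase of exactly k points
        pool = [
            Individual(np.zeros(3, np.uint8), objectives=ObjectivePair(i, (10 - i) / 10))
            for i in range(10)
        ]
        cfg = EvolutionConfig(population_size=10)
        assert len(environmental_selection(pool, cfg)) == 10

    def test_dominant_candidate_always_survives(self, rng):
        pool = self._pool(rng, 25)
        for ind in pool:  # keep the planted optimum strictly dominant
            ind.objectives = ObjectivePair(
                ind.objectives.f_c + 1, min(ind.objectives.f_e + 0.1, 1.0)
            )
        best = Individual(np.zeros(10, np.uint8), objectives=ObjectivePair(0.0, 0.0))
        pool.append(best)
        survivors = environmental_selection(pool, EvolutionConfig(population_size=5))
        assert best in survivors

    def test_matches_brute_force_on_small_pools(self, rng):
        for _ in range(25):
            pool = self._pool(rng, int(rng.integers(8, 31)))
            k = int(rng.integers(1, len(pool)))
            cfg = EvolutionConfig(population_size=k)
            survivors = environmental_selection(pool, cfg)
            expected = brute_force_selection(pool, k)
            ids = {id(c): i for i, c in enumerate(pool)}
            assert sorted(ids[id(s)] for s in survivors) == expected

    def test_small_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            environmental_selection(self._pool(rng, 3), EvolutionConfig(population_size=5))


def _record(genomes, fc, fe):
    return GenerationRecord(Counter(g.tobytes() for g in genomes), fc, fe)


class TestTermination:
    def test_generation_cap(self):
        cfg = EvolutionConfig(max_generations=5, stall_generations=20)
        g = [np.zeros(4, np.uint8)]
        history = [_record(g, 1.0, 1.0) for _ in range(6)]
        assert check_termination(history, cfg)

    def test_identical_populations_trigger_stall(self):
        cfg = EvolutionConfig(stall_generations=20)
        g = [np.ones(4, np.uint8) * i for i in range(3)]
        history = [_record(g, 1.0 + 0.5 * t, 1.0) for t in range(21)]
        assert check_termination(history, cfg)

    def test_streak_resets_on_change(self):
        cfg = EvolutionConfig(stall_generations=20)
        g = [np.ones(4, np.uint8)]
        history = [_record(g, 1.0 + 0.5 * t, 1.0) for t in range(20)]
        # large change in the final generation resets the streak
        history.append(_record([np.zeros(4, np.uint8)], 99.0, 1.0))
        assert not check_termination(history, cfg)

    def test_objective_stability_triggers_stall(self):
        cfg = EvolutionConfig(stall_generations=3)
        history = [
            _record([np.ones(4, np.uint8) * t], 100.0 + 1e-5 * t, 0.5) for t in range(4)
        ]
        assert check_termination(history, cfg)


def hypervolume(points: np.ndarray, ref: tuple[float, float]) -> float:
    """2-D hypervolume of the non-dominated set w.r.t. a reference point."""
    front = points[np.lexsort((points[:, 1], points[:, 0]))]
    hv, prev_fe = 0.0, ref[1]
    for fc, fe in front:
        if fe < prev_fe:
            hv += (ref[0] - fc) * (prev_fe - fe)
            prev_fe = fe
    return hv


@pytest.fixture(scope="module")
def toy_geometry():
    rng = np.random.default_rng(7)
    return RegionGeometry(rng.uniform(0, 60, size=(10, 3)))


@pytest.fixture(scope="module")
def toy_archive(toy_geometry):
    cfg = EvolutionConfig(
        population_size=20, max_generations=50, stall_generations=50, seed=3
    )
    return run_evolution(toy_geometry, TradeoffModelSpec("dual"), cfg, seed=3)


class TestRunEvolution:
    def test_archive_mutually_nondominated(self, toy_archive):
        objs = toy_archive.objective_array()
        for i in range(len(objs)):
            for j in range(len(objs)):
                if i != j:
                    assert not dominates(
                        ObjectivePair(*objs[i]), ObjectivePair(*objs[j])
                    )

    def test_bit_identical_reproducibility(self, toy_geometry, toy_archive):
        cfg = EvolutionConfig(
            population_size=20, max_generations=50, stall_generations=50, seed=3
        )
        again = run_evolution(toy_geometry, TradeoffModelSpec("dual"), cfg, seed=3)
        assert len(again) == len(toy_archive)
        for (n1, o1), (n2, o2) in zip(again.members, toy_archive.members):
            assert np.array_equal(n1.adjacency, n2.adjacency)
            assert (o1.f_c, o1.f_e) == (o2.f_c, o2.f_e)

    def test_front_improves_on_initial_population(self, toy_geometry, toy_archive, rng):
        from connectomorph.evolution import _init_genomes, _make_evaluator

        cfg = EvolutionConfig(population_size=20, seed=3)
        spec = TradeoffModelSpec("dual")
        init_rng = np.random.default_rng(np.random.SeedSequence([3]))
        genomes = _init_genomes(cfg, 10, init_rng)
        f_init = _make_evaluator(toy_geometry, spec)(genomes, init_rng)
        ref = (f_init[:, 0].max() * 2 + 1, 1.1)
        assert hypervolume(toy_archive.objective_array(), ref) >= hypervolume(
            f_init, ref
        )

    def test_population_objectives_within_bounds(self, toy_archive):
        objs = toy_archive.objective_array()
        assert (objs[:, 0] >= 0).all()
        assert ((objs[:, 1] >= 0) & (objs[:, 1] <= 1)).all()


class TestMergeRuns:
    def _archive(self, nets_objs, model):
        from connectomorph.evolution import ParetoArchive

        return ParetoArchive(nets_objs, model)

    def test_self_merge_is_idempotent(self, toy_members=None):
        from connectomorph import BinaryNetwork

        model = TradeoffModelSpec("dual")
        members = [
            (
                BinaryNetwork.from_genome(np.array([1, 0, 0], np.uint8), 3),
                ObjectivePair(1.0, 0.5),
            ),
            (
                BinaryNetwork.from_genome(np.array([0, 1, 1], np.uint8), 3),
                ObjectivePair(2.0, 0.2),
            ),
        ]
        arc = self._archive(members, model)
        merged = merge_runs([arc, arc])
        assert len(merged) == 2

    def test_dominating_archive_wins(self):
        from connectomorph import BinaryNetwork

        model = TradeoffModelSpec("dual")
        good = self._archive(
            [
                (
                    BinaryNetwork.from_genome(np.array([1, 0, 0], np.uint8), 3),
                    ObjectivePair(1.0, 0.1),
                )
            ],
            model,
        )
        bad = self._archive(
            [
                (
                    BinaryNetwork.from_genome(np.array([0, 1, 0], np.uint8), 3),
                    ObjectivePair(2.0, 0.2),
                )
            ],
            model,
        )
        merged = merge_runs([good, bad])
        assert len(merged) == 1
        assert merged.members[0][1].f_c == 1.0

    def test_mixed_models_rejected(self):
        from connectomorph import BinaryNetwork

        member = (
            BinaryNetwork.from_genome(np.array([1, 0, 0], np.uint8), 3),
            ObjectivePair(1.0, 0.5),
        )
        a = self._archive([member], TradeoffModelSpec("dual"))
        b = self._archive([member], TradeoffModelSpec("tri_q"))
        with pytest.raises(ValueError):
            merge_runs([a, b])

    def test_merge_equals_brute_force_filter(self, rng):
        from connectomorph import BinaryNetwork

        model = TradeoffModelSpec("dual")
        archives = []
        all_members = []
        for _ in range(3):
            members = []
            for _ in range(8):
                genome = rng.integers(0, 2, 6).astype(np.uint8)
                obj = ObjectivePair(float(rng.integers(0, 5)), float(rng.integers(0, 5)) / 5)
                members.append((BinaryNetwork.from_genome(genome, 4), obj))
            all_members.extend(members)
            archives.append(self._archive(members, model))
        merged = merge_runs(archives)
        # oracle: dedup genomes then keep non-dominated
        seen, unique = set(), []
        for net, obj in all_members:
            key = net.genome().tobytes()
            if key not in seen:
                seen.add(key)
                unique.append((net, obj))
        pts = np.array([[o.f_c, o.f_e] for _, o in unique])
        expected = brute_force_fronts(pts)[0]
        assert len(merged) == len(expected)
        merged_keys = {net.genome().tobytes() for net, _ in merged.members}
        assert merged_keys == {unique[i][0].genome().tobytes() for i in expected}
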