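"""Evolve a small Pareto front of cost/efficiency-optimal networks.

Runs the customized NSGA-II on a 30-region synthetic geometry under the
modularity trade-off model (cost vs. 0.8*(1-Eg) + 0.2*(1-Q)) and prints the
extremes of the resulting front.  Scaled far below the full study so it
finishes in under a minute.
"""

from connectomorph import (
    EvolutionConfig,
    SyntheticCohortConfig,
    TradeoffModelSpec,
    evolve_model,
    generate_geometry,
)

geom, _ = generate_geometry(SyntheticCohortConfig(seed=2, n_regions=30))
spec = TradeoffModelSpec(name="tri_q", seed=2)
cfg = EvolutionConfig(
    population_size=60, max_generations=60, n_runs=2, seed=2
)

archive = evolve_model(geom, spec, cfg)
objs = archive.objective_array()
order = objs[:, 0].argsort()
print(f"merged Pareto archive: {len(archive)} mutually non-dominated networks")
cheap, costly = order[0], order[-1]
print(
    f"cheapest network : F_c = {objs[cheap, 0]:8.1f} mm, "
    f"efficiency index = {1 - objs[cheap, 1]:.3f}"
)
print(
    f"costliest network: F_c = {objs[costly, 0]:8.1f} mm, "
    f"efficiency index = {1 - objs[costly, 1]:.3f}"
)
# Moving along the front trades wiring cost against communication efficiency;
# no member is better than another on both objectives at once.
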