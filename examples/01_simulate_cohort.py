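"""Generate a synthetic cohort and inspect its group network.

Builds 50 subject-level binary brain networks on a 90-region mirrored
geometry, forms the group network (edges present in more than half the
cohort), and prints its density and modular structure.
"""

import numpy as np

from connectomorph import (
    SyntheticCohortConfig,
    generate_cohort,
    modularity_louvain,
    partition_kappa,
)

cfg = SyntheticCohortConfig(seed=1)
cohort = generate_cohort(cfg, age_effects=False)
group = cohort.group_network()

q, partition = modularity_louvain(group, n_restarts=50, seed=0)
membership = np.array([partition[lab] for lab in group.node_labels])
kappa = partition_kappa(cohort.module_truth, membership).kappa

print(f"subjects: {cfg.n_subjects}, regions: {cfg.n_regions}")
print(f"mean subject density: {np.mean([n.density for n in cohort.subject_networks]):.3f}")
print(f"group network density: {group.density:.3f}  (edges kept in > 50% of subjects)")
print(f"group modularity Q = {q:.3f} with {len(set(partition.values()))} modules")
print(f"kappa vs planted module truth = {kappa:.3f}")
# Density ~0.11 and Q ~0.5-0.6 mirror group-level human connectomes built on
# a 90-region parcellation; kappa ~1 says Louvain recovers the planted modules.
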