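"""Recover population substructure from genome-wide allele sharing.

Simulates two Balding–Nichols subpopulations (Fst = 0.1), computes the
pairwise IBS distance matrix over 1000 markers and cuts a Ward tree into
K = 2 clusters.  Prints the fraction of individuals assigned to their true
source population (under the best label permutation).
"""

import itertools

import numpy as np

from capl import ibs_distance_matrix, ward_cluster
from capl.simgen import SimConfig, SubpopCounts, simulate_dataset

cfg = SimConfig(counts=[SubpopCounts(controls=100), SubpopCounts(controls=100)],
                n_markers=1000, fst=0.1, seed=3)
ds = simulate_dataset(cfg)

dist = ibs_distance_matrix(ds.genotypes)
assignment = ward_cluster(dist, 2)

acc = max(
    (np.array([perm[t] for t in ds.true_labels]) == assignment.labels).mean()
    for perm in itertools.permutations([1, 2])
)
between = dist.d[ds.true_labels == 0][:, ds.true_labels == 1].mean()
within = dist.d[ds.true_labels == 0][:, ds.true_labels == 0].mean()

print(f"mean within-population distance:  {within:.4f}")
print(f"mean between-population distance: {between:.4f}")
print(f"clustering accuracy (K=2):        {acc:.1%}")
print()
print("The small distance gap per pair is amplified by 1000 markers, which")
print("is why Ward clustering on the full panel separates the populations.")
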