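"""Estimate affected-sib-pair IBD sharing at a linked vs an unlinked marker.

500 multiplex families (two parents, two affected siblings) are ascertained
under a multiplicative GRR = 4 disease model.  When the tested marker *is*
the disease locus, affected sibs share more alleles identical by descent
than the null (z0, z1, z2) = (1/4, 1/2, 1/4); at an unlinked marker the
estimates return to the null.  The per-marker EM recovers this from
genotypes alone.
"""

import numpy as np

from capl import run_em
from capl.pedio import build_family_units
from capl.simgen import SimConfig, SubpopCounts, simulate_dataset

for linked in (True, False):
    cfg = SimConfig(counts=[SubpopCounts(multiplex=500)], n_markers=1,
                    fst=0.0, freq_range=(0.3, 0.3), grr=4.0,
                    baseline_penetrance=0.05, linked=linked, seed=11)
    ds = simulate_dataset(cfg)
    units, _ = build_family_units(ds.individuals)
    col = ds.genotypes.values[:, 0]
    model, _, _ = run_em(units, col, np.ones((len(units), 1)), K=1,
                         individuals=ds.individuals)
    truth = np.array(list(ds.multiplex_ibd.values()))
    label = "linked  " if linked else "unlinked"
    print(f"{label}: z-hat = ({model.z[0]:.3f}, {model.z[1]:.3f}, "
          f"{model.z[2]:.3f}); generator's true IBD-2 share = "
          f"{(truth == 2).mean():.3f}")

print()
print("z2-hat > 0.25 flags excess sharing (linkage); the unlinked marker")
print("stays near the null (0.25, 0.50, 0.25) up to sampling noise.")
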