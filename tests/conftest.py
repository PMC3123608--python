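"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities from first principles
(exhaustive enumeration, greedy recomputation) rather than calling the
implementation paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from capl.pedio import build_family_units
from capl.simgen import SimConfig, SubpopCounts, simulate_dataset

# ---------------------------------------------------------------------------
# probability-kernel oracles

_ALLELES = {0: (0, 0), 1: (1, 0), 2: (1, 1)}


def sibpair_oracle(g1: int, g2: int, m: tuple[int, int], j: int) -> float:
    """P(g1, g2 | mating type, IBD=j) by enumerating the 16 labelled-gamete
    outcomes of two meioses and conditioning on the number of label matches."""
    fa, mo = _ALLELES[m[0]], _ALLELES[m[1]]
    num = den = 0
    for f1, m1, f2, m2 in itertools.product((0, 1), repeat=4):
        ibd = (f1 == f2) + (m1 == m2)
        if ibd != j:
            continue
        den += 1
        if fa[f1] + mo[m1] == g1 and fa[f2] + mo[m2] == g2:
            num += 1
    return num / den


def fullsib_joint_oracle(g1: int, g2: int, m: tuple[int, int]) -> float:
    """Unconditional P(g1, g2 | mating type): two independent meioses."""
    fa, mo = _ALLELES[m[0]], _ALLELES[m[1]]
    total = 0
    for f1, m1, f2, m2 in itertools.product((0, 1), repeat=4):
        if fa[f1] + mo[m1] == g1 and fa[f2] + mo[m2] == g2:
            total += 1
    return total / 16.0


# ---------------------------------------------------------------------------
# Ward clustering oracle

def ward_oracle_labels(points: np.ndarray, K: int) -> np.ndarray:
    """Greedy Ward agglomeration recomputing the objective from scratch.

    At every step merges the pair of clusters whose union minimizes the
    increase in total within-cluster sum of squares, computed directly from
    the points; ties break on the smallest (i, j) pair.  Returns labels
    (arbitrary numbering) at K clusters.
    """
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    while len(clusters) > K:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pa, pb = points[clusters[a]], points[clusters[b]]
                na, nb = len(pa), len(pb)
                delta = (
                    na * nb / (na + nb)
                    * float(((pa.mean(0) - pb.mean(0)) ** 2).sum())
                )
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=np.int64)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label vectors induce the same partition."""
    a, b = np.asarray(a), np.asarray(b)
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


def best_label_accuracy(truth: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Fraction of agreement under the best permutation of cluster labels.

    ``truth`` is 0-based, ``labels`` 1-based."""
    best = 0.0
    for perm in itertools.permutations(range(1, K + 1)):
        mapped = np.array([perm[t] for t in truth])
        best = max(best, float((mapped == labels).mean()))
    return best


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_stratified():
    """Two drifted subpopulations with every unit design represented."""
    cfg = SimConfig(
        counts=[
            SubpopCounts(cases=15, controls=10, triads=8, multiplex=7),
            SubpopCounts(cases=10, controls=15, triads=7, multiplex=8),
        ],
        n_markers=60, fst=0.1, grr=1.0, seed=11,
    )
    ds = simulate_dataset(cfg)
    units, _ = build_family_units(ds.individuals)
    return ds, units


@pytest.fixture(scope="session")
def triad_dataset():
    """One population of complete triads with a moderate-risk linked locus."""
    cfg = SimConfig(
        counts=[SubpopCounts(triads=120)],
        n_markers=5, fst=0.0, grr=2.0, baseline_penetrance=0.05,
        linked=True, seed=23,
    )
    ds = simulate_dataset(cfg)
    units, _ = build_family_units(ds.individuals)
    return ds, units
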