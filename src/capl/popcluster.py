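"""Population substructure: IBS distances, Ward clustering, origin priors.

The distance between two individuals is allele-sharing distance
``d(i,j) = 1 - IBS(i,j) / (2 M_ij)`` computed over all markers non-missing
in both (IBS at one marker = ``2 - |g_i - g_j|``).  Ward's agglomerative
clustering (Lance–Williams recurrence on squared distances, the "Ward.D2"
convention) cuts the tree into a user-chosen number K of subpopulations, and
cluster labels of a family's members are smoothed into a per-family prior
probability of origin.

The distance matrix is computed once on the full sample; bootstrap
replicates index into it and never recompute entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .pedio import FamilyUnit

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "ibs_distance_matrix",
    "ward_cluster",
    "family_origin_priors",
]


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distances in [0, 1] plus per-pair marker counts."""

    d: np.ndarray            # (N, N) float64
    pair_counts: np.ndarray  # (N, N) int64


@dataclass
class ClusterAssignment:
    """Per-individual subpopulation labels in 1..K."""

    labels: np.ndarray  # (N,) int
    K: int


def ibs_distance_matrix(genotypes) -> DistanceMatrix:
    """Genome-wide pairwise allele-sharing distance matrix.

    ``genotypes`` is a GenotypeMatrix or an (N, M) array with entries in
    {-1, 0, 1, 2}.  A pair of individuals with no overlapping non-missing
    marker raises ``ValueError`` naming the pair.

    The sums are assembled from three matrix products using the identity
    |a-b| = (a-b)^2 - 2*[{a,b} = {0,2}] for a, b in {0, 1, 2}, so runtime is
    BLAS-bound even with missing data.
    """
    values = np.asarray(getattr(genotypes, "values", genotypes))
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("need a 2-D genotype matrix with at least one marker")
    nonmiss = (values >= 0)
    x = np.where(nonmiss, values, 0).astype(np.float32)
    m = nonmiss.astype(np.float32)
    x2 = x * x
    cnt = m @ m.T
    sqdiff = x2 @ m.T + m @ x2.T - 2.0 * (x @ x.T)
    i0 = ((values == 0)).astype(np.float32)
    i2 = ((values == 2)).astype(np.float32)
    opp = i0 @ i2.T + i2 @ i0.T
    absdiff = sqdiff - 2.0 * opp

    cnt_int = np.rint(cnt).astype(np.int64)
    off_diag = ~np.eye(values.shape[0], dtype=bool)
    if np.any((cnt_int == 0) & off_diag):
        i, j = np.argwhere((cnt_int == 0) & off_diag)[0]
        raise ValueError(
            f"individuals {i} and {j} share no non-missing marker; "
            "cannot compute their distance"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = absdiff.astype(np.float64) / (2.0 * cnt_int)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, pair_counts=cnt_int)


def ward_cluster(dist, K: int) -> ClusterAssignment:
    """Cut a Ward's-method agglomeration of the distance matrix into K clusters.

    ``dist`` is a DistanceMatrix or a square symmetric array.  Uses the
    Lance–Williams recurrence on squared input distances (Ward.D2), as
    implemented by scipy's ``linkage(method="ward")``.
    """
    d = np.asarray(getattr(dist, "d", dist), dtype=np.float64)
    n = d.shape[0]
    if K < 1 or K > n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    if K == 1:
        return ClusterAssignment(labels=np.ones(n, dtype=np.int64), K=1)
    if K == n:
        return ClusterAssignment(labels=np.arange(1, n + 1, dtype=np.int64), K=K)
    condensed = squareform(d, checks=False)
    return ClusterAssignment(labels=ward_labels_condensed(condensed, K), K=K)


def ward_labels_condensed(condensed: np.ndarray, K: int) -> np.ndarray:
    """Ward.D2 labels from a condensed distance vector (shared fast path)."""
    tree = linkage(np.asarray(condensed, dtype=np.float64), method="ward")
    return fcluster(tree, t=K, criterion="maxclust").astype(np.int64)


def family_origin_priors(
    assignment: ClusterAssignment,
    units: Sequence[FamilyUnit],
    epsilon: float = 0.01,
) -> np.ndarray:
    """Smoothed per-family prior probabilities of subpopulation origin.

    ``pi_ik = (c_ik + eps) / (c_i + K*eps)`` where ``c_ik`` counts the unit's
    members assigned to cluster k.  Returns an (n_units, K) row-stochastic
    array; a unit with no members gets a uniform prior with a warning.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    K = assignment.K
    labels = np.asarray(assignment.labels)
    out = np.empty((len(units), K), dtype=np.float64)
    for i, unit in enumerate(units):
        members = unit.members
        if not members:
            logger.warning("unit %d has no members; uniform origin prior", i)
            out[i] = 1.0 / K
            continue
        counts = np.bincount(labels[members] - 1, minlength=K).astype(float)
        out[i] = (counts + epsilon) / (counts.sum() + K * epsilon)
    return out
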