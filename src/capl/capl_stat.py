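"""The per-marker association statistic and its bootstrap variance.

Each family contributes the difference between the observed number of
counted-allele copies carried by its affected siblings and the posterior
expectation of that number under Mendelian transmission,

    c_i = X_i - sum_{k,m,j} w_i(k,m,j) * n_i * e(m),

where ``e(m) = (g1+g2)/2`` is the null-expected copies per offspring and the
weights come from the converged per-marker EM.  The marker statistic is
``T = sum_i c_i``; its standard error is estimated by a nonparametric
bootstrap that resamples whole family units with replacement and, per
replicate, re-runs Ward clustering (on the precomputed distance matrix,
indexed by the resampled individuals), rebuilds origin priors, and re-runs
the EM.  ``z = T / sd(T*)`` is referred to the standard normal, two-sided.

Per-marker bootstrap seeds are a pure function of (global seed, marker
index), so results do not depend on worker count or marker order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .em import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    FamilyPosterior,
    MarkerFamilyData,
    PreparedUnits,
    batched_em,
    build_marker_data,
    prepare_units,
    run_em,
)
from .genetics_core import EXPECTED_OFFSPRING
from .pedio import FamilyUnit, GenotypeMatrix, Individual, MISSING
from .popcluster import (
    ClusterAssignment,
    DistanceMatrix,
    family_origin_priors,
    ward_labels_condensed,
)
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CaplResult",
    "AnalysisContext",
    "family_contribution",
    "capl_T",
    "bootstrap_variance",
    "capl_test",
    "marker_seed",
]

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_UNTESTABLE = "untestable"
STATUS_DEGENERATE = "degenerate_variance"

MAX_FAILED_FRACTION = 0.2


@dataclass
class CaplResult:
    marker_id: str
    T: float | None = None
    boot_sd: float | None = None
    z_score: float | None = None
    p_value: float | None = None
    B_used: int = 0
    n_families_used: int = 0
    p_hat: np.ndarray | None = None
    z_hat: np.ndarray | None = None
    em_iterations: int = 0
    status: str = STATUS_UNTESTABLE


@dataclass
class AnalysisContext:
    """Everything marker analyses share: units, genotypes, distances, priors."""

    units: Sequence[FamilyUnit]
    genotypes: GenotypeMatrix
    distances: DistanceMatrix | None
    assignment: ClusterAssignment
    K: int
    epsilon: float = 0.01
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    individuals: Sequence[Individual] | None = None
    prepared: PreparedUnits = field(init=False)
    priors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.prepared = prepare_units(self.units, self.individuals)
        self.priors = family_origin_priors(self.assignment, self.units,
                                           self.epsilon)
        # float32 copy for bootstrap submatrix gathers (entries reused, never
        # recomputed; 1e-7 relative rounding is far below any merge gap)
        self._d32 = (
            self.distances.d.astype(np.float32)
            if self.distances is not None else None
        )


def marker_seed(global_seed: int, marker_index: int) -> np.random.SeedSequence:
    """Deterministic per-marker seed, independent of scheduling."""
    return np.random.SeedSequence(entropy=(int(global_seed), int(marker_index)))


def family_contribution(unit_or_stats, posterior: FamilyPosterior,
                        marker_genotypes: np.ndarray | None = None) -> float:
    """Observed-minus-expected counted-allele copies for one family.

    ``unit_or_stats`` is a FamilyUnit (with ``marker_genotypes`` supplied) or
    a precomputed ``(X_i, n_i)`` pair.  Control singletons have no affected
    sibs, hence contribute 0.
    """
    if isinstance(unit_or_stats, FamilyUnit):
        g = np.asarray(marker_genotypes)
        x = n = 0.0
        for i in unit_or_stats.affected_sibs[:2]:
            if g[i] != MISSING:
                x += float(g[i])
                n += 1.0
    else:
        x, n = map(float, unit_or_stats)
    spec = "kmj,m->" if posterior.w.ndim == 3 else "km,m->"
    exp_e = float(np.einsum(spec, posterior.w, EXPECTED_OFFSPRING))
    return x - n * exp_e


def capl_T(
    units: Sequence[FamilyUnit],
    posteriors: dict[int, FamilyPosterior],
    marker_genotypes: np.ndarray,
) -> float:
    """Sum of family contributions over the units included at this marker."""
    total = 0.0
    for f, post in posteriors.items():
        total += family_contribution(units[f], post, marker_genotypes)
    return total


def _batch_T(md: MarkerFamilyData, res, cnt1, cnt2) -> np.ndarray:
    c1 = res.valid1 * (md.X1[None, :] - md.n1[None, :] * res.exp_parent_mean1)
    c2 = res.valid2 * (md.X2[None, :] - md.n2[None, :] * res.exp_parent_mean2)
    return (cnt1 * c1).sum(axis=1) + (cnt2 * c2).sum(axis=1)


def _replicate_inputs(ctx: AnalysisContext, col: np.ndarray, draws: np.ndarray):
    """Cluster, re-prior and re-initialize every bootstrap replicate.

    ``draws`` is (B, F) unit indices.  Returns priors (B, F, K), counts
    (B, F) and initial frequencies (B, K).  Distance entries are reused from
    the precomputed full-sample matrix, never recomputed.
    """
    B, F = draws.shape
    K = ctx.K
    members = ctx.prepared.members
    lengths = np.array([m.size for m in members], dtype=np.int64)
    flat_members = (
        np.concatenate(members) if members else np.empty(0, dtype=np.int64)
    )
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    counts = np.stack([np.bincount(draws[b], minlength=F) for b in range(B)])
    counts = counts.astype(np.float64)
    obs = col >= 0
    overall = col[obs].mean() / 2.0 if obs.any() else 0.5

    if K == 1:
        # no clustering: uniform priors; p0 = allele frequency of the
        # resampled individuals, computable from per-unit genotype sums
        unit_sum = np.array(
            [col[m][col[m] >= 0].sum() for m in members], dtype=np.float64
        )
        unit_cnt = np.array([(col[m] >= 0).sum() for m in members],
                            dtype=np.float64)
        num = counts @ unit_sum
        den = 2.0 * counts @ unit_cnt
        p0 = np.where(den > 0, num / np.where(den > 0, den, 1.0), overall)
        return np.ones((B, F, 1)), counts, p0[:, None]

    priors = np.full((B, F, K), 1.0 / K)
    p0 = np.empty((B, K))
    eps = ctx.epsilon
    d_full = ctx._d32

    for b in range(B):
        drawn = draws[b]
        ln = lengths[drawn]
        total = int(ln.sum())
        # flat gather of every drawn unit's member indices, duplicates kept
        ends = np.cumsum(ln)
        pos = np.arange(total) - np.repeat(ends - ln, ln)
        ind_idx = flat_members[np.repeat(starts[drawn], ln) + pos]
        sub = d_full[ind_idx][:, ind_idx]
        labels = ward_labels_condensed(squareform(sub, checks=False), K)
        # per-instance label counts; duplicate instances of a unit are the
        # same individuals and land in the same cluster, so the first
        # instance's counts serve for all copies
        instance = np.repeat(np.arange(F), ln)
        c_pos = np.bincount(instance * K + (labels - 1),
                            minlength=F * K).reshape(F, K).astype(np.float64)
        first_pos = np.full(F, -1, dtype=np.int64)
        first_pos[drawn[::-1]] = np.arange(F - 1, -1, -1)
        u_idx = np.flatnonzero(first_pos >= 0)
        cu = c_pos[first_pos[u_idx]]
        priors[b, u_idx] = (cu + eps) / (cu.sum(axis=1, keepdims=True) + K * eps)
        g_rep = col[ind_idx]
        rep_obs = g_rep >= 0
        lab0 = labels - 1
        sums = np.bincount(lab0[rep_obs], weights=g_rep[rep_obs], minlength=K)
        cnts = np.bincount(lab0[rep_obs], minlength=K)
        p0[b] = np.where(cnts > 0, sums / np.where(cnts > 0, 2.0 * cnts, 1.0),
                         overall)
    return priors, counts, p0


def bootstrap_variance(
    ctx: AnalysisContext,
    marker_index: int,
    B: int = 200,
    seed: int | np.random.SeedSequence = 0,
    marker_data: MarkerFamilyData | None = None,
):
    """Bootstrap standard error of T with per-replicate re-clustering.

    Returns ``(boot_sd, replicates_used, n_failed)``.  Replicates whose EM
    fails (no usable family) are dropped and counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    col = ctx.genotypes.values[:, marker_index]
    md = marker_data if marker_data is not None else build_marker_data(
        ctx.prepared, col
    )
    F = len(ctx.units)
    seq = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(seq)
    draws = rng.integers(0, F, size=(B, F))
    priors, counts, p0 = _replicate_inputs(ctx, col, draws)
    res = batched_em(md, priors, counts, p0, tol=ctx.tol, max_iter=ctx.max_iter)
    t_star = _batch_T(md, res, counts[:, md.unit_idx1], counts[:, md.unit_idx2])
    ok = ~res.failed
    n_failed = int((~ok).sum())
    used = int(ok.sum())
    if used < 2:
        return 0.0, used, n_failed
    sd = float(np.std(t_star[ok], ddof=1))
    return sd, used, n_failed


def _is_monomorphic(col: np.ndarray) -> bool:
    obs = col[col >= 0]
    return obs.size == 0 or (obs == obs[0]).all()


def capl_test(
    ctx: AnalysisContext,
    marker_index: int,
    marker_id: str | None = None,
    B: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> CaplResult:
    """Full per-marker analysis: EM fit, statistic, bootstrap SD, p-value."""
    col = ctx.genotypes.values[:, marker_index]
    mid = marker_id if marker_id is not None else str(marker_index)
    if _is_monomorphic(col):
        return CaplResult(marker_id=mid, status=STATUS_MONOMORPHIC)

    md = build_marker_data(ctx.prepared, col)
    if md.n_included == 0:
        return CaplResult(marker_id=mid, status=STATUS_UNTESTABLE)

    model, posteriors, _ = run_em(
        ctx.units, col, ctx.priors, K=ctx.K, tol=ctx.tol,
        max_iter=ctx.max_iter, init_labels=ctx.assignment.labels,
        prepared=ctx.prepared, marker_data=md,
    )
    t_obs = float(
        sum(
            family_contribution((md.X1[i], md.n1[i]), posteriors[int(f)])
            for i, f in enumerate(md.unit_idx1) if int(f) in posteriors
        )
        + sum(
            family_contribution((md.X2[i], md.n2[i]), posteriors[int(f)])
            for i, f in enumerate(md.unit_idx2) if int(f) in posteriors
        )
    )
    sd, used, n_failed = bootstrap_variance(
        ctx, marker_index, B=B, seed=seed, marker_data=md
    )
    result = CaplResult(
        marker_id=mid,
        T=t_obs,
        boot_sd=sd,
        B_used=used,
        n_families_used=md.n_included,
        p_hat=model.p,
        z_hat=model.z,
        em_iterations=model.n_iterations,
    )
    if sd <= 0.0 or n_failed > MAX_FAILED_FRACTION * (used + n_failed):
        result.status = STATUS_DEGENERATE
        return result
    result.z_score = t_obs / sd
    result.p_value = float(2.0 * norm.sf(abs(result.z_score)))
    result.status = STATUS_OK
    return result
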