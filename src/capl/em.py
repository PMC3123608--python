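"""Per-marker EM over missing parental mating types.

For each marker the model has K subpopulation allele frequencies ``p_k``,
one set of affected-sib-pair IBD parameters ``z = (z0, z1, z2)`` shared
across subpopulations, and per-family posterior weights over
(subpopulation k, parental mating type m, IBD state j).  The complete-data
likelihood of one family is

    pi_ik * P(m | p_k) * 1{m compatible with observed parents} * L_sibs

with ``L_sibs = P(g | m)`` for a single modelled offspring and
``z_j * P(g1, g2 | m, j)`` for two affected sibs.  The E-step normalizes
these weights; the M-step re-estimates ``p_k`` from the expected parental
allele counts (four parental allele slots per family) and ``z`` from the
expected IBD-state occupancy of two-affected-sib families.  Origin priors
``pi_ik`` come from genome-wide clustering and are held fixed; the marginal
of the posterior over k is the family's probability of origin.

Implementation note: the module is written "batched" — the same E/M code
runs B independent weighted copies of the dataset at once (shape ``(B,
n_families, ...)`` tensors), which is what makes per-marker bootstrap
resampling affordable.  ``run_em`` is the B = 1 case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetics_core import (
    EXPECTED_OFFSPRING,
    MATING_TYPES,
    NULL_IBD,
    OFFSPRING_TABLE,
    PARENT_ALLELE_COUNT,
    SIBPAIR_TABLE,
    _COMPAT_LUT,
    mating_type_probs,
)
from .pedio import FamilyUnit, Individual, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerModel",
    "FamilyPosterior",
    "PreparedUnits",
    "MarkerFamilyData",
    "prepare_units",
    "build_marker_data",
    "family_weights",
    "e_step",
    "m_step",
    "run_em",
    "batched_em",
]

FREQ_CLAMP = 1e-6
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 50

# offspring table extended with a "missing genotype" column of ones
_O_EXT = np.concatenate([OFFSPRING_TABLE, np.ones((6, 1))], axis=1)

# sib-pair table extended so index 3 on either genotype axis marginalizes it
_S_EXT = np.ones((6, 3, 4, 4))
_S_EXT[:, :, :3, :3] = SIBPAIR_TABLE
_S_EXT[:, :, 3, :3] = OFFSPRING_TABLE[:, None, :]
_S_EXT[:, :, :3, 3] = OFFSPRING_TABLE[:, None, :]


@dataclass
class MarkerModel:
    """Converged (or capped) per-marker EM estimates."""

    p: np.ndarray            # (K,) subpopulation counted-allele frequencies
    z: np.ndarray            # (3,) IBD parameters
    n_iterations: int
    converged: bool
    loglik: float


@dataclass
class FamilyPosterior:
    """Posterior weights of one family over (k, m[, j]); sums to 1."""

    w: np.ndarray            # (K, 6) or (K, 6, 3)
    origin: np.ndarray       # (K,) marginal probability of origin
    has_ibd: bool


@dataclass
class PreparedUnits:
    """Marker-independent unit structure shared by every marker and replicate."""

    units: Sequence[FamilyUnit]
    father: np.ndarray       # (F,) int, -1 absent
    mother: np.ndarray
    sib1: np.ndarray         # likelihood sib slots, -1 empty
    sib2: np.ndarray
    sib1_affected: np.ndarray  # bool
    sib2_affected: np.ndarray
    extra_children: list[np.ndarray]   # children outside the likelihood slots
    members: list[np.ndarray]          # all member indices per unit

    @property
    def n_units(self) -> int:
        return self.father.size


def prepare_units(
    units: Sequence[FamilyUnit],
    individuals: Sequence[Individual] | None = None,
) -> PreparedUnits:
    """Resolve each unit's likelihood structure once.

    At most two affected siblings enter the likelihood; in sibships with
    more, the two with lexicographically smallest individual IDs are kept
    and the rest are ignored with a warning.  A control singleton's genotype
    enters as a single offspring term; unaffected siblings of multi-member
    families are used only for the Mendelian consistency check.
    """
    F = len(units)
    father = np.full(F, -1, dtype=np.int64)
    mother = np.full(F, -1, dtype=np.int64)
    sib1 = np.full(F, -1, dtype=np.int64)
    sib2 = np.full(F, -1, dtype=np.int64)
    s1aff = np.zeros(F, dtype=bool)
    s2aff = np.zeros(F, dtype=bool)
    extras: list[np.ndarray] = []
    members: list[np.ndarray] = []

    for f, unit in enumerate(units):
        if unit.father is not None:
            father[f] = unit.father
        if unit.mother is not None:
            mother[f] = unit.mother
        aff = list(unit.affected_sibs)
        if len(aff) > 2:
            if individuals is not None:
                aff = sorted(aff, key=lambda i: individuals[i].individual_id)
            logger.warning(
                "unit %s has %d affected sibs; only the first two are modelled",
                unit.family_id, len(aff),
            )
        selected = aff[:2]
        dropped = aff[2:]
        if selected:
            sib1[f] = selected[0]
            s1aff[f] = True
        if len(selected) == 2:
            sib2[f] = selected[1]
            s2aff[f] = True
        if not selected and unit.design_tag == "control_singleton":
            sib1[f] = unit.unaffected_sibs[0]
        extra = list(dropped)
        if unit.design_tag != "control_singleton":
            extra += list(unit.unaffected_sibs)
        extras.append(np.asarray(extra, dtype=np.int64))
        members.append(np.asarray(unit.members, dtype=np.int64))

    return PreparedUnits(units, father, mother, sib1, sib2, s1aff, s2aff,
                         extras, members)


@dataclass
class MarkerFamilyData:
    """Per-marker likelihood tables, split into single-offspring and
    two-affected-sib blocks, each indexed back to the original unit list."""

    n_units: int
    unit_idx1: np.ndarray    # (F1,)
    lik1: np.ndarray         # (F1, 6) compatibility already applied
    X1: np.ndarray           # observed affected-sib allele count
    n1: np.ndarray           # number of counted affected sibs
    unit_idx2: np.ndarray    # (F2,)
    lik2: np.ndarray         # (F2, 6, 3)
    X2: np.ndarray
    n2: np.ndarray
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return self.unit_idx1.size + self.unit_idx2.size


def _genotypes_at(col: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.full(idx.shape, MISSING, dtype=np.int64)
    ok = idx >= 0
    out[ok] = col[idx[ok]]
    return out


def build_marker_data(prep: PreparedUnits, col: np.ndarray) -> MarkerFamilyData:
    """Assemble likelihood tables for one marker column.

    Families failing the Mendelian consistency check at this marker are
    excluded here (marker-local; they stay in play at other markers).
    """
    col = np.asarray(col)
    F = prep.n_units
    gf = _genotypes_at(col, prep.father)
    gm = _genotypes_at(col, prep.mother)
    g1 = _genotypes_at(col, prep.sib1)
    g2 = _genotypes_at(col, prep.sib2)

    compat = _COMPAT_LUT[gf + 1, gm + 1]          # (F, 6)
    producible = compat.copy()
    for g in (g1, g2):
        obs = g >= 0
        producible[obs] &= OFFSPRING_TABLE[:, g[obs]].T > 0
    for f in range(F):
        extra = prep.extra_children[f]
        if extra.size == 0:
            continue
        for gc in col[extra]:
            if gc >= 0:
                producible[f] &= OFFSPRING_TABLE[:, gc] > 0
    consistent = producible.any(axis=1)

    is_pair = prep.sib2 >= 0
    keep = consistent
    excluded = [(int(f), "mendel inconsistent") for f in np.flatnonzero(~keep)]

    idx1 = np.flatnonzero(keep & ~is_pair)
    idx2 = np.flatnonzero(keep & is_pair)

    g1e = np.where(g1 < 0, 3, g1)
    g2e = np.where(g2 < 0, 3, g2)

    lik1 = _O_EXT[:, g1e[idx1]].T * compat[idx1]
    lik2 = (
        np.moveaxis(_S_EXT[:, :, g1e[idx2], g2e[idx2]], 2, 0)
        * compat[idx2][:, :, None]
    )

    def stat(idx):
        x = np.zeros(idx.size)
        n = np.zeros(idx.size)
        for g, aff_sel in ((g1, prep.sib1_affected), (g2, prep.sib2_affected)):
            use = aff_sel[idx] & (g[idx] >= 0)
            x[use] += g[idx][use]
            n[use] += 1
        return x, n

    X1, n1 = stat(idx1)
    X2, n2 = stat(idx2)
    return MarkerFamilyData(
        n_units=F,
        unit_idx1=idx1, lik1=lik1, X1=X1, n1=n1,
        unit_idx2=idx2, lik2=lik2, X2=X2, n2=n2,
        excluded=excluded,
    )


@dataclass
class BatchedEMResult:
    p: np.ndarray            # (B, K)
    z: np.ndarray            # (B, 3)
    n_iter: np.ndarray       # (B,)
    converged: np.ndarray    # (B,) bool
    loglik: np.ndarray       # (B,)
    failed: np.ndarray       # (B,) bool — no usable family
    w1: np.ndarray           # (B, F1, K, 6) final posteriors
    w2: np.ndarray           # (B, F2, K, 6, 3)
    valid1: np.ndarray       # (B, F1) bool — positive total weight
    valid2: np.ndarray
    exp_parent_mean1: np.ndarray  # (B, F1) posterior E[e(m)]
    exp_parent_mean2: np.ndarray
    loglik_path: np.ndarray | None = None


def _e_step_core(md: MarkerFamilyData, pri1, cnt1, pri2, cnt2, p, z,
                 want_posteriors: bool = False):
    """One E-step over B weighted dataset copies.

    Returns sufficient statistics and the log-likelihood; the full posterior
    tensors and per-family expected parental means are materialized only
    when ``want_posteriors`` is set (the final iteration).
    """
    mt = mating_type_probs(p)                       # (B, K, 6)
    a = PARENT_ALLELE_COUNT
    e = EXPECTED_OFFSPRING

    u1 = pri1[:, :, :, None] * mt[:, None, :, :]
    u1 *= md.lik1[None, :, None, :]
    tot1 = u1.sum(axis=(2, 3))
    valid1 = tot1 > 0.0
    scale1 = np.divide(cnt1, tot1, where=valid1, out=np.zeros_like(tot1))

    u2 = pri2[:, :, :, None, None] * (mt[:, None, :, :, None] * z[:, None, None, None, :])
    u2 *= md.lik2[None, :, None, :, :]
    tot2 = u2.sum(axis=(2, 3, 4))
    valid2 = tot2 > 0.0
    scale2 = np.divide(cnt2, tot2, where=valid2, out=np.zeros_like(tot2))

    # count-weighted posteriors, reduced over families then mating types
    v1_km = np.einsum("bfkm,bf->bkm", u1, scale1)
    v2_kmj = np.einsum("bfkmj,bf->bkmj", u2, scale2)
    v2_km = v2_kmj.sum(axis=3)
    s_p = (v1_km + v2_km) @ a
    n_k = v1_km.sum(axis=2) + v2_km.sum(axis=2)
    s_z = v2_kmj.sum(axis=(1, 2))

    with np.errstate(divide="ignore"):
        ll = (
            np.where(valid1 & (cnt1 > 0), cnt1 * np.log(np.where(valid1, tot1, 1.0)), 0.0).sum(axis=1)
            + np.where(valid2 & (cnt2 > 0), cnt2 * np.log(np.where(valid2, tot2, 1.0)), 0.0).sum(axis=1)
        )
    if not want_posteriors:
        return None, None, valid1, valid2, s_p, n_k, s_z, ll, None, None
    w1 = np.divide(u1, tot1[:, :, None, None], where=valid1[:, :, None, None],
                   out=np.zeros_like(u1))
    w2 = np.divide(u2, tot2[:, :, None, None, None],
                   where=valid2[:, :, None, None, None], out=np.zeros_like(u2))
    exp_e1 = np.einsum("bfkm,m->bf", w1, e)
    exp_e2 = np.einsum("bfkmj,m->bf", w2, e)
    return w1, w2, valid1, valid2, s_p, n_k, s_z, ll, exp_e1, exp_e2


def _batched_e_step(md: MarkerFamilyData, pri1, cnt1, pri2, cnt2, p, z):
    """E-step with full posteriors (compatibility wrapper)."""
    return _e_step_core(md, pri1, cnt1, pri2, cnt2, p, z, want_posteriors=True)


def batched_em(
    md: MarkerFamilyData,
    priors: np.ndarray,       # (B, F, K)
    counts: np.ndarray,       # (B, F) unit multiplicities (bootstrap weights)
    p0: np.ndarray,           # (B, K)
    z0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_loglik: bool = False,
) -> BatchedEMResult:
    """Run B independent EMs on weighted copies of the same marker data."""
    B, F, K = priors.shape
    if counts.shape != (B, F):
        raise ValueError("counts shape mismatch")
    pri1 = priors[:, md.unit_idx1, :]
    cnt1 = counts[:, md.unit_idx1].astype(np.float64)
    pri2 = priors[:, md.unit_idx2, :]
    cnt2 = counts[:, md.unit_idx2].astype(np.float64)

    p = np.clip(np.asarray(p0, dtype=np.float64).copy(), FREQ_CLAMP, 1 - FREQ_CLAMP)
    z = np.tile(NULL_IBD if z0 is None else np.asarray(z0, dtype=float), (B, 1))

    n_iter = np.zeros(B, dtype=np.int64)
    converged = np.zeros(B, dtype=bool)
    path = [] if track_loglik else None

    failed = (cnt1.sum(axis=1) + cnt2.sum(axis=1)) == 0
    for it in range(1, max_iter + 1):
        out = _e_step_core(md, pri1, cnt1, pri2, cnt2, p, z)
        _, _, valid1, valid2, s_p, n_k, s_z, ll, _, _ = out
        if track_loglik:
            path.append(ll.copy())

        denom = 4.0 * n_k
        p_new = np.where(denom > 0, s_p / np.where(denom > 0, denom, 1.0), p)
        p_new = np.clip(p_new, FREQ_CLAMP, 1 - FREQ_CLAMP)
        sz_tot = s_z.sum(axis=1, keepdims=True)
        z_new = np.where(sz_tot > 0, s_z / np.where(sz_tot > 0, sz_tot, 1.0), z)

        delta = np.maximum(
            np.abs(p_new - p).max(axis=1), np.abs(z_new - z).max(axis=1)
        )
        newly = (~converged) & (delta < tol) & (~failed)
        converged |= newly
        n_iter[~converged & ~failed] = it
        n_iter[newly] = it
        p, z = p_new, z_new
        if (converged | failed).all():
            break

    # final pass at the converged parameters: posteriors, expected means,
    # and the log-likelihood actually attained
    out = _e_step_core(md, pri1, cnt1, pri2, cnt2, p, z, want_posteriors=True)
    w1, w2, valid1, valid2, s_p, n_k, s_z, ll, e1, e2 = out
    if track_loglik:
        path.append(ll.copy())
    failed |= ~np.isfinite(ll)
    effective = (cnt1 * valid1).sum(axis=1) + (cnt2 * valid2).sum(axis=1)
    failed |= effective == 0
    return BatchedEMResult(
        p=p, z=z, n_iter=n_iter, converged=converged, loglik=ll, failed=failed,
        w1=w1, w2=w2, valid1=valid1, valid2=valid2,
        exp_parent_mean1=e1, exp_parent_mean2=e2,
        loglik_path=np.array(path) if track_loglik else None,
    )


def _initial_freq(col: np.ndarray, labels: np.ndarray | None, K: int) -> np.ndarray:
    """p_k(0): allele frequency among individuals hard-assigned to cluster k,
    falling back to the overall frequency (then 0.5) where a cluster is empty."""
    col = np.asarray(col)
    obs = col >= 0
    overall = col[obs].mean() / 2.0 if obs.any() else 0.5
    p0 = np.full(K, overall)
    if labels is not None:
        labels = np.asarray(labels)
        for k in range(K):
            sel = obs & (labels == k + 1)
            if sel.any():
                p0[k] = col[sel].mean() / 2.0
    return np.clip(p0, FREQ_CLAMP, 1 - FREQ_CLAMP)


def _posteriors_from_batch(md: MarkerFamilyData, res: BatchedEMResult):
    """Unpack the B = 1 posterior tensors into per-family records."""
    posteriors: dict[int, FamilyPosterior] = {}
    for pos, f in enumerate(md.unit_idx1):
        if not res.valid1[0, pos]:
            continue
        w = res.w1[0, pos]
        posteriors[int(f)] = FamilyPosterior(
            w=w, origin=w.sum(axis=1), has_ibd=False
        )
    for pos, f in enumerate(md.unit_idx2):
        if not res.valid2[0, pos]:
            continue
        w = res.w2[0, pos]
        posteriors[int(f)] = FamilyPosterior(
            w=w, origin=w.sum(axis=(1, 2)), has_ibd=True
        )
    return posteriors


def family_weights(
    unit: FamilyUnit,
    marker_genotypes: np.ndarray,
    prior: np.ndarray,
    p: np.ndarray,
    z: np.ndarray | None = None,
    individuals: Sequence[Individual] | None = None,
) -> FamilyPosterior:
    """Posterior weights of one family over (k, m[, j]) at fixed parameters."""
    prior = np.atleast_1d(np.asarray(prior, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    K = p.size
    z = NULL_IBD if z is None else np.asarray(z, dtype=float)
    prep = prepare_units([unit], individuals)
    md = build_marker_data(prep, marker_genotypes)
    if md.n_included == 0:
        raise ValueError("family is Mendelian-inconsistent at this marker")
    res = batched_em(
        md, prior[None, None, :], np.ones((1, 1)), p[None, :], z,
        max_iter=0,
    )
    post = _posteriors_from_batch(md, res)
    if not post:
        raise ValueError("family has zero total weight at this marker")
    return post[0]


def e_step(
    prep_or_md,
    marker_genotypes: np.ndarray | None,
    priors: np.ndarray,
    p: np.ndarray,
    z: np.ndarray,
):
    """Expected sufficient statistics at fixed parameters.

    Returns ``(posteriors, stats, loglik)`` where stats is a dict with
    ``S_p`` (K,), ``N_k`` (K,) and ``S_z`` (3, or None without sib pairs).
    Accepts either a PreparedUnits plus a marker column, or a prebuilt
    MarkerFamilyData (pass ``marker_genotypes=None``).
    """
    md = (
        prep_or_md
        if isinstance(prep_or_md, MarkerFamilyData)
        else build_marker_data(prep_or_md, marker_genotypes)
    )
    priors = np.asarray(priors, dtype=float)
    F, K = priors.shape
    p = np.atleast_1d(np.asarray(p, dtype=float))
    z = np.asarray(z, dtype=float)
    out = _batched_e_step(
        md,
        priors[None, md.unit_idx1, :], np.ones((1, md.unit_idx1.size)),
        priors[None, md.unit_idx2, :], np.ones((1, md.unit_idx2.size)),
        p[None, :], z[None, :],
    )
    w1, w2, valid1, valid2, s_p, n_k, s_z, ll, e1, e2 = out
    res = BatchedEMResult(
        p=p[None, :], z=z[None, :], n_iter=np.zeros(1, int),
        converged=np.zeros(1, bool), loglik=ll, failed=np.zeros(1, bool),
        w1=w1, w2=w2, valid1=valid1, valid2=valid2,
        exp_parent_mean1=e1, exp_parent_mean2=e2,
    )
    stats = {
        "S_p": s_p[0],
        "N_k": n_k[0],
        "S_z": s_z[0] if md.unit_idx2.size else None,
    }
    return _posteriors_from_batch(md, res), stats, float(ll[0])


def m_step(stats: dict, p_old: np.ndarray, z_old: np.ndarray):
    """Closed-form parameter update from expected sufficient statistics."""
    s_p, n_k = np.asarray(stats["S_p"], float), np.asarray(stats["N_k"], float)
    p_old = np.atleast_1d(np.asarray(p_old, float))
    p_new = p_old.copy()
    pos = n_k > 0
    if not pos.any():
        raise ValueError("no subpopulation has positive expected membership")
    if not pos.all():
        logger.warning("subpopulation(s) %s empty; frequency unchanged",
                       np.flatnonzero(~pos))
    p_new[pos] = np.clip(s_p[pos] / (4.0 * n_k[pos]), FREQ_CLAMP, 1 - FREQ_CLAMP)
    s_z = stats.get("S_z")
    if s_z is not None and np.asarray(s_z).sum() > 0:
        z_new = np.asarray(s_z, float) / np.asarray(s_z, float).sum()
    else:
        z_new = np.asarray(z_old, float).copy()
    return p_new, z_new


def run_em(
    units: Sequence[FamilyUnit],
    marker_genotypes: np.ndarray,
    priors: np.ndarray,
    K: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    individuals: Sequence[Individual] | None = None,
    init_labels: np.ndarray | None = None,
    prepared: PreparedUnits | None = None,
    marker_data: MarkerFamilyData | None = None,
    track_loglik: bool = False,
):
    """Fit the per-marker model; returns ``(MarkerModel, posteriors, data)``.

    ``posteriors`` maps unit index -> FamilyPosterior for every family
    included at this marker.  Iterates E/M from the deterministic
    initialization (cluster-wise allele frequencies, null IBD) until the
    largest absolute parameter change drops below ``tol`` or ``max_iter``
    is reached.
    """
    priors = np.asarray(priors, dtype=float)
    if K is None:
        K = priors.shape[1]
    prep = prepared if prepared is not None else prepare_units(units, individuals)
    md = (
        marker_data
        if marker_data is not None
        else build_marker_data(prep, marker_genotypes)
    )
    if md.n_included == 0:
        raise ValueError("no includable family at this marker")
    p0 = _initial_freq(np.asarray(marker_genotypes), init_labels, K)
    res = batched_em(
        md, priors[None, :, :], np.ones((1, md.n_units)), p0[None, :],
        tol=tol, max_iter=max_iter, track_loglik=track_loglik,
    )
    model = MarkerModel(
        p=res.p[0], z=res.z[0], n_iterations=int(res.n_iter[0]),
        converged=bool(res.converged[0]), loglik=float(res.loglik[0]),
    )
    if track_loglik:
        model.loglik_path = res.loglik_path[:, 0]  # type: ignore[attr-defined]
    return model, _posteriors_from_batch(md, res), md
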