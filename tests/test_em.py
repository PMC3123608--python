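"""EM checks: enumeration oracles, closed-form fixed points, monotonicity."""

import itertools

import numpy as np
import pytest

from capl.em import (
    build_marker_data,
    e_step,
    family_weights,
    m_step,
    prepare_units,
    run_em,
)
from capl.genetics_core import (
    MATING_TYPES,
    NULL_IBD,
    mating_type_prob,
    offspring_prob,
    sibpair_prob,
)
from capl.pedio import AFFECTED, FamilyUnit, MISSING, UNAFFECTED, build_family_units
from capl.simgen import SimConfig, SubpopCounts, simulate_dataset


def _weights_oracle(gf, gm, sibs, prior, p, z):
    """Loop-based re-derivation of the family posterior over (k, m[, j])."""
    K = len(p)
    has_pair = len(sibs) == 2
    shape = (K, 6, 3) if has_pair else (K, 6)
    w = np.zeros(shape)
    for k in range(K):
        for mi, m in enumerate(MATING_TYPES):
            if gf >= 0 and gm >= 0 and tuple(sorted((gf, gm))) != m:
                continue
            if gf >= 0 and gm < 0 and gf not in m:
                continue
            if gm >= 0 and gf < 0 and gm not in m:
                continue
            base = prior[k] * mating_type_prob(m, p[k])
            if has_pair:
                g1, g2 = sibs
                for j in range(3):
                    if g1 < 0 and g2 < 0:
                        lik = 1.0
                    elif g1 < 0:
                        lik = offspring_prob(g2, m)
                    elif g2 < 0:
                        lik = offspring_prob(g1, m)
                    else:
                        lik = sibpair_prob(g1, g2, m, j)
                    w[k, mi, j] = base * z[j] * lik
            else:
                lik = 1.0 if not sibs or sibs[0] < 0 else offspring_prob(sibs[0], m)
                w[k, mi] = base * lik
    return w / w.sum()


def test_family_weights_degenerate_with_observed_parents():
    unit = FamilyUnit("F", 0, 1, affected_sibs=[2])
    post = family_weights(unit, np.array([1, 2, 2]), [1.0], [0.4])
    assert post.w.shape == (1, 6)
    nz = np.flatnonzero(post.w[0])
    assert len(nz) == 1 and MATING_TYPES[nz[0]] == (1, 2)
    assert post.origin[0] == pytest.approx(1.0)


@pytest.mark.parametrize("g", [0, 1, 2])
def test_case_singleton_weights_match_enumeration(g):
    unit = FamilyUnit("F", None, None, affected_sibs=[0],
                      design_tag="case_singleton")
    post = family_weights(unit, np.array([g]), [1.0], [0.5])
    ref = _weights_oracle(-1, -1, [g], [1.0], [0.5], NULL_IBD)
    np.testing.assert_allclose(post.w, ref, atol=1e-12)


def test_control_singleton_missing_genotype_is_prior_only():
    from capl.genetics_core import mating_type_probs
    unit = FamilyUnit("F", None, None, unaffected_sibs=[0],
                      design_tag="control_singleton")
    post = family_weights(unit, np.array([MISSING]), [0.3, 0.7], [0.2, 0.8])
    expected = np.array([0.3, 0.7])[:, None] * mating_type_probs(
        np.array([0.2, 0.8])
    )
    expected /= expected.sum()
    np.testing.assert_allclose(post.w, expected, atol=1e-12)
    np.testing.assert_allclose(post.origin.sum(), 1.0)


@pytest.mark.parametrize(
    "gf,gm,sibs,prior,p",
    [
        (1, -1, [2, 1], [0.6, 0.4], [0.3, 0.7]),
        (-1, -1, [0, 0], [0.5, 0.5], [0.2, 0.6]),
        (1, 1, [2, 2], [1.0], [0.5]),
        (-1, 2, [1], [0.25, 0.75], [0.4, 0.5]),
    ],
)
def test_family_weights_match_loop_oracle(gf, gm, sibs, prior, p):
    n = 2 + len(sibs)
    geno = np.array([gf, gm] + sibs)
    unit = FamilyUnit("F", 0, 1, affected_sibs=list(range(2, n)))
    z = np.array([0.2, 0.5, 0.3])
    post = family_weights(unit, geno, prior, p, z)
    ref = _weights_oracle(gf, gm, sibs, prior, p, z)
    np.testing.assert_allclose(post.w, ref, atol=1e-12)


def test_e_step_complete_triad_sufficient_stats():
    units = [FamilyUnit("F", 0, 1, affected_sibs=[2])]
    prep = prepare_units(units)
    geno = np.array([1, 2, 2])
    post, stats, ll = e_step(prep, geno, np.ones((1, 1)), [0.5], NULL_IBD)
    assert stats["S_p"][0] == pytest.approx(3.0)  # parents carry 1 + 2 copies
    assert stats["N_k"][0] == pytest.approx(1.0)
    assert stats["S_z"] is None                    # no two-affected-sib unit


def test_e_step_matches_enumeration_on_mixed_fixture():
    units = [
        FamilyUnit("A", 0, 1, affected_sibs=[2, 3]),
        FamilyUnit("B", None, None, affected_sibs=[4],
                   design_tag="case_singleton"),
        FamilyUnit("C", None, None, unaffected_sibs=[5],
                   design_tag="control_singleton"),
    ]
    geno = np.array([1, 1, 2, 1, 1, 0])
    priors = np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]])
    p = np.array([0.3, 0.6])
    z = np.array([0.2, 0.5, 0.3])
    prep = prepare_units(units)
    post, stats, ll = e_step(prep, geno, priors, p, z)

    s_p_ref = np.zeros(2)
    n_k_ref = np.zeros(2)
    s_z_ref = np.zeros(3)
    ll_ref = 0.0
    specs = [
        (1, 1, [2, 1], priors[0]),
        (-1, -1, [1], priors[1]),
        (-1, -1, [0], priors[2]),
    ]
    for gf, gm, sibs, pri in specs:
        w = _weights_oracle(gf, gm, sibs, pri, p, z)
        a = np.array([m[0] + m[1] for m in MATING_TYPES], dtype=float)
        if w.ndim == 3:
            s_p_ref += np.einsum("kmj,m->k", w, a)
            n_k_ref += w.sum(axis=(1, 2))
            s_z_ref += w.sum(axis=(0, 1))
        else:
            s_p_ref += np.einsum("km,m->k", w, a)
            n_k_ref += w.sum(axis=1)
    np.testing.assert_allclose(stats["S_p"], s_p_ref, atol=1e-12)
    np.testing.assert_allclose(stats["N_k"], n_k_ref, atol=1e-12)
    np.testing.assert_allclose(stats["S_z"], s_z_ref, atol=1e-12)


def test_m_step_closed_forms():
    p, z = m_step({"S_p": np.array([2.0]), "N_k": np.array([2.5]),
                   "S_z": np.array([25.0, 50.0, 25.0])},
                  [0.5], NULL_IBD)
    assert p[0] == pytest.approx(0.2)
    np.testing.assert_allclose(z, NULL_IBD)
    # empty S_z leaves z untouched
    _, z2 = m_step({"S_p": np.array([2.0]), "N_k": np.array([1.0]),
                    "S_z": None}, [0.5], [0.1, 0.2, 0.7])
    np.testing.assert_allclose(z2, [0.1, 0.2, 0.7])


def test_run_em_case_control_fixed_point():
    """K=1 unrelated case/control data: EM fixed point is the sample allele
    frequency (n2=10, n1=20, n0=70 -> 0.20)."""
    genos = [2] * 10 + [1] * 20 + [0] * 70
    units = []
    for i in range(100):
        tag = "case_singleton" if i % 2 == 0 else "control_singleton"
        if tag == "case_singleton":
            units.append(FamilyUnit("F%d" % i, None, None, affected_sibs=[i],
                                    design_tag=tag))
        else:
            units.append(FamilyUnit("F%d" % i, None, None, unaffected_sibs=[i],
                                    design_tag=tag))
    model, post, md = run_em(units, np.array(genos), np.ones((100, 1)), K=1,
                             track_loglik=True)
    assert model.p[0] == pytest.approx(0.20, abs=1e-6)
    assert model.converged and model.n_iterations <= 50
    assert np.all(np.diff(model.loglik_path) >= -1e-9)


def test_run_em_monomorphic_clamps_quickly():
    units = [FamilyUnit("F%d" % i, None, None, affected_sibs=[i],
                        design_tag="case_singleton") for i in range(20)]
    model, _, _ = run_em(units, np.full(20, 2), np.ones((20, 1)), K=1)
    assert model.p[0] == pytest.approx(1 - 1e-6)
    assert model.converged and model.n_iterations <= 2


def test_run_em_complete_parents_gives_parental_frequency(triad_dataset):
    ds, units = triad_dataset
    col = ds.genotypes.values[:, 1]  # a null marker
    model, post, md = run_em(units, col, np.ones((len(units), 1)), K=1,
                             individuals=ds.individuals)
    parents = np.array([g for u in units for g in
                        (col[u.father], col[u.mother])], dtype=float)
    assert model.p[0] == pytest.approx(parents.mean() / 2.0, abs=1e-6)
    # posteriors are degenerate: every family's origin is certain
    for fp in post.values():
        assert fp.origin[0] == pytest.approx(1.0)


def test_loglik_monotone_on_stratified_fixture(small_stratified):
    ds, units = small_stratified
    priors = np.full((len(units), 2), 0.5)
    model, _, _ = run_em(units, ds.genotypes.values[:, 3], priors, K=2,
                         individuals=ds.individuals, track_loglik=True)
    assert np.all(np.diff(model.loglik_path) >= -1e-8)


def test_label_equivariance(small_stratified):
    """Permuting the prior columns permutes the frequency estimates."""
    ds, units = small_stratified
    rng = np.random.default_rng(3)
    priors = rng.dirichlet([1.0, 1.0], size=len(units))
    col = ds.genotypes.values[:, 5]
    m1, _, _ = run_em(units, col, priors, K=2, individuals=ds.individuals)
    m2, _, _ = run_em(units, col, priors[:, ::-1], K=2,
                      individuals=ds.individuals)
    np.testing.assert_allclose(m1.p, m2.p[::-1], atol=1e-9)


def test_extra_affected_sibs_are_ignored_deterministically(caplog):
    """A sibship with three affected sibs models the two smallest IDs."""
    from capl.pedio import Individual
    inds = [
        Individual("F", "F", None, None, 1, 0),
        Individual("F", "M", None, None, 2, 0),
        Individual("F", "C3", "F", "M", 1, AFFECTED),
        Individual("F", "C1", "F", "M", 1, AFFECTED),
        Individual("F", "C2", "F", "M", 1, AFFECTED),
    ]
    units, _ = build_family_units(inds)
    with caplog.at_level("WARNING"):
        prep = prepare_units(units, inds)
    assert "affected sibs" in caplog.text
    # sibs C1 (idx 3) and C2 (idx 4) selected; C3 (idx 2) ignored
    assert prep.sib1[0] == 3 and prep.sib2[0] == 4
    assert 2 in prep.extra_children[0]


def test_zero_includable_families_raises():
    units = [FamilyUnit("F", 0, 1, affected_sibs=[2])]
    with pytest.raises(ValueError, match="no includable"):
        run_em(units, np.array([2, 2, 1]), np.ones((1, 1)), K=1)
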