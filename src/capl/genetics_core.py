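"""Closed-form probability kernel for a biallelic autosomal marker.

Everything downstream (the EM over missing parental mating types, the
observed-vs-expected allele-count statistic) is built from four small exact
tables defined here:

* Hardy–Weinberg genotype probabilities ``(1-p)^2, 2p(1-p), p^2``;
* mating-type probabilities for the six unordered parental genotype pairs;
* the Mendelian segregation table P(child genotype | mating type);
* the IBD-conditional affected-sib-pair table
  P(g1, g2 | mating type, number of alleles shared identical by descent).

Genotypes are coded 0/1/2 = copies of the *counted* allele.  Mating types are
unordered (no parent-of-origin effect is modelled), giving six states in the
canonical order ``(0,0),(0,1),(0,2),(1,1),(1,2),(2,2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MATING_TYPES",
    "MATING_TYPE_INDEX",
    "N_MATING_TYPES",
    "NULL_IBD",
    "OFFSPRING_TABLE",
    "SIBPAIR_TABLE",
    "EXPECTED_OFFSPRING",
    "PARENT_ALLELE_COUNT",
    "hwe_genotype_prob",
    "hwe_genotype_probs",
    "mating_type_prob",
    "mating_type_probs",
    "offspring_prob",
    "sibpair_prob",
    "sibpair_prob_mixture",
    "expected_offspring_count",
    "compatible_mating_types",
]

#: the six unordered parental genotype pairs, canonical (low, high) order
MATING_TYPES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2),
)
N_MATING_TYPES = len(MATING_TYPES)
MATING_TYPE_INDEX: dict[tuple[int, int], int] = {
    mt: i for i, mt in enumerate(MATING_TYPES)
}

#: affected-sib-pair IBD sharing probabilities under no linkage
NULL_IBD = np.array([0.25, 0.5, 0.25])

# P(transmit a copies of the counted allele | parent genotype g), a in {0,1}
_TRANSMIT = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])


def _build_offspring_table() -> np.ndarray:
    table = np.zeros((N_MATING_TYPES, 3))
    for i, (g1, g2) in enumerate(MATING_TYPES):
        for a in (0, 1):
            for b in (0, 1):
                table[i, a + b] += _TRANSMIT[g1, a] * _TRANSMIT[g2, b]
    return table


#: OFFSPRING_TABLE[m, g] = P(child genotype g | mating type m)
OFFSPRING_TABLE = _build_offspring_table()


def _build_sibpair_table() -> np.ndarray:
    # SIBPAIR_TABLE[m, j, g1, g2] = P(g1, g2 | mating type m, IBD = j):
    # the true meiosis conditional obtained by labelling each parent's two
    # alleles, letting each sib draw one labelled gamete per parent, and
    # conditioning on the number of label matches.  Conditioning matters:
    # given j = 0 the second sib receives the *complementary* label from
    # both parents (anti-correlated genotypes, not independent draws), and
    # given j = 1 the non-shared parent transmits its two distinct labels,
    # one to each sib.  Only this construction satisfies the identity
    # sum_j P(IBD = j) * table[m, j] = unconditional full-sib distribution.
    allele_values = {0: (0, 0), 1: (1, 0), 2: (1, 1)}
    table = np.zeros((N_MATING_TYPES, 3, 3, 3))
    counts = np.zeros((N_MATING_TYPES, 3))
    for i, (ga, gb) in enumerate(MATING_TYPES):
        fa, mo = allele_values[ga], allele_values[gb]
        for f1 in (0, 1):
            for m1 in (0, 1):
                for f2 in (0, 1):
                    for m2 in (0, 1):
                        j = (f1 == f2) + (m1 == m2)
                        g1 = fa[f1] + mo[m1]
                        g2 = fa[f2] + mo[m2]
                        table[i, j, g1, g2] += 1.0
                        counts[i, j] += 1.0
    return table / counts[:, :, None, None]


SIBPAIR_TABLE = _build_sibpair_table()

#: e(m) = null-expected counted-allele copies per offspring = (g1+g2)/2
EXPECTED_OFFSPRING = np.array([(g1 + g2) / 2.0 for g1, g2 in MATING_TYPES])

#: a(m) = total counted-allele copies carried by the parental pair = g1+g2
PARENT_ALLELE_COUNT = np.array([float(g1 + g2) for g1, g2 in MATING_TYPES])


def _canonical(m) -> int:
    """Return the index of an unordered mating type given as a pair or index."""
    if isinstance(m, (int, np.integer)):
        if not 0 <= int(m) < N_MATING_TYPES:
            raise ValueError(f"mating type index out of range: {m}")
        return int(m)
    g1, g2 = int(m[0]), int(m[1])
    key = (g1, g2) if g1 <= g2 else (g2, g1)
    try:
        return MATING_TYPE_INDEX[key]
    except KeyError:
        raise ValueError(f"invalid mating type {m!r}") from None


def hwe_genotype_prob(g: int, p) -> np.ndarray | float:
    """Hardy–Weinberg probability of genotype ``g`` at counted-allele frequency ``p``."""
    p = np.asarray(p, dtype=float)
    if g == 2:
        out = p * p
    elif g == 1:
        out = 2.0 * p * (1.0 - p)
    elif g == 0:
        out = (1.0 - p) ** 2
    else:
        raise ValueError(f"invalid genotype code {g!r}")
    return out if out.ndim else float(out)


def hwe_genotype_probs(p) -> np.ndarray:
    """HWE probabilities for g = 0, 1, 2 stacked on a trailing axis."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def mating_type_probs(p) -> np.ndarray:
    """Probabilities of the six unordered mating types under random HWE mating.

    ``p`` may be a scalar or an array of subpopulation frequencies; the result
    gains a trailing axis of length 6 and sums to 1 along it.
    """
    hw = hwe_genotype_probs(p)
    cols = []
    for g1, g2 in MATING_TYPES:
        prob = hw[..., g1] * hw[..., g2]
        if g1 != g2:
            prob = 2.0 * prob
        cols.append(prob)
    return np.stack(cols, axis=-1)


def mating_type_prob(m, p) -> float:
    """P(mating type ``m``) under HWE random mating at frequency ``p``."""
    return float(mating_type_probs(float(p))[_canonical(m)])


def offspring_prob(g: int, m) -> float:
    """Mendelian probability of child genotype ``g`` given mating type ``m``."""
    if g not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {g!r}")
    return float(OFFSPRING_TABLE[_canonical(m), g])


def sibpair_prob(g1: int, g2: int, m, j: int) -> float:
    """P(g1, g2 | mating type m, sibs share j alleles IBD)."""
    if j not in (0, 1, 2):
        raise ValueError(f"invalid IBD state {j!r}")
    return float(SIBPAIR_TABLE[_canonical(m), j, g1, g2])


def sibpair_prob_mixture(g1: int, g2: int, m, z) -> float:
    """P(g1, g2 | m) under the IBD mixture z = (z0, z1, z2)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (3,):
        raise ValueError("z must have shape (3,)")
    return float(z @ SIBPAIR_TABLE[_canonical(m), :, g1, g2])


def expected_offspring_count(m) -> float:
    """Null-expected counted-allele copies per offspring, e(m) = (g1+g2)/2."""
    return float(EXPECTED_OFFSPRING[_canonical(m)])


def _build_compat_lut() -> np.ndarray:
    # lut[gf+1, gm+1, m] — genotype code -1 means the parent is unobserved.
    # An observed parent's genotype must be one element of the unordered pair;
    # with both observed the mating type is fixed.
    lut = np.zeros((4, 4, N_MATING_TYPES), dtype=bool)
    for gf in (-1, 0, 1, 2):
        for gm in (-1, 0, 1, 2):
            for i, (a, b) in enumerate(MATING_TYPES):
                if gf >= 0 and gm >= 0:
                    ok = tuple(sorted((gf, gm))) == (a, b)
                elif gf >= 0:
                    ok = gf in (a, b)
                elif gm >= 0:
                    ok = gm in (a, b)
                else:
                    ok = True
                lut[gf + 1, gm + 1, i] = ok
    return lut


_COMPAT_LUT = _build_compat_lut()


def compatible_mating_types(gf: int, gm: int) -> np.ndarray:
    """Boolean mask over the six mating types compatible with observed parents.

    Genotype code -1 marks an unobserved parent and imposes no constraint.
    """
    return _COMPAT_LUT[int(gf) + 1, int(gm) + 1].copy()
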