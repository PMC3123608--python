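# Methods

## The model

`capl` implements a combined family and case-control association test for a
biallelic autosomal marker.  The analysis unit is the nuclear family: a
possibly-missing parent pair plus a sibship.  Unrelated affected cases and
unaffected controls are folded into the same framework as one-sib families
with two missing parents, so a single likelihood covers every design.

For family *i* with affected siblings carrying `X_i` copies of the counted
allele, the statistic at one marker is

    T = sum_i [ X_i - E(X_i | parental mating type, subpopulation) ]
      = sum_i [ X_i - sum_{k,m,j} w_i(k,m,j) * n_i * e(m) ],

where `e(m) = (g1+g2)/2` is the expected counted-allele dosage of an
offspring of mating type `m` (the unordered parental genotype pair, six
states), `n_i` is the number of affected sibs with observed genotypes
(capped at two), and `w_i(k,m,j)` is the family's posterior weight over
subpopulation `k`, mating type `m`, and — for two-affected-sib families —
IBD state `j`.  Under the null of no association and no linkage, `E[T] = 0`
conditional on parental genotypes, which is what makes the statistic valid
in ascertained family data.

The posterior weights are

    w_i(k,m,j) ∝ pi_ik * P(m | p_k) * 1{m compatible with observed parents}
                 * L_sibs(m, j),

with `P(m | p_k)` the Hardy–Weinberg random-mating probability at the
subpopulation allele frequency `p_k`, and `L_sibs` either the Mendelian
offspring probability (one modelled sib) or `z_j * P(g1, g2 | m, j)` for an
affected sib pair.  Marginalizing `w_i` over `(m, j)` gives the family's
*probability of origin* across subpopulations.

### IBD-conditional sib-pair probabilities

`P(g1, g2 | m, j)` is the exact meiosis conditional: label each parent's two
alleles, let each sib draw one labelled gamete per parent, and condition on
the number of label matches `j`.  Conditioning matters — given `j = 0` the
second sib receives the complementary label from both parents, so the sibs'
genotypes are anti-correlated rather than independent, and given `j = 1` the
non-shared parent sends its two distinct labels, one to each sib.  This
construction satisfies the identity

    (1/4) P(g1,g2|m,0) + (1/2) P(g1,g2|m,1) + (1/4) P(g1,g2|m,2)
        = P(g1|m) P(g2|m),

i.e. the null mixture reproduces two independent meioses.  A "both sibs
drawn independently given j = 0" variant (tempting, and occasionally seen)
makes the null mixture coincide with the j = 0 table *identically*, which
leaves z unidentified along an exact likelihood ridge from (1/4, 1/2, 1/4)
to (1, 0, 0); the EM then drifts to arbitrary estimates on null data.  The
enumeration-based tables remove the degeneracy, and the package's tests pin
them to a brute-force gamete enumeration at < 1e-12.

One `z = (z0, z1, z2)` is estimated per marker, shared across
subpopulations, unconstrained (no Holmans-triangle projection): raw
multinomial updates keep the EM's monotonicity guarantee.

## Population substructure

The pairwise distance is allele-sharing distance over all markers
non-missing in both individuals: `d(i,j) = 1 - IBS_ij / (2 M_ij)` with
per-marker IBS `2 - |g_i - g_j|`.  Ward's agglomerative clustering
(Lance–Williams recurrence on squared distances, the Ward.D2 convention, as
implemented by scipy) is cut at a *user-chosen* K; the package never
auto-selects K.  Cluster labels of a family's members are smoothed into an
origin prior `pi_ik = (c_ik + eps) / (c_i + K*eps)` with `eps = 0.01` —
large enough that a hard mis-assignment cannot zero out a subpopulation,
small enough to stay informative.

The N x N distance matrix is computed once per dataset from three BLAS
matrix products (using `|a-b| = (a-b)^2 - 2*1{opposite homozygotes}`), and
bootstrap replicates only *index* into it: resampled individuals have
unchanged pairwise distances.

## EM

Per marker, E and M steps iterate from a deterministic initialization
(`p_k(0)` = allele frequency among individuals hard-assigned to cluster k,
`z(0)` = null) until the largest absolute parameter change falls below
`tol = 1e-6` or `max_iter = 50` iterations.  M-step: `p_k' = S_pk / (4 N_k)`
(four parental allele slots per family, clamped to `[1e-6, 1-1e-6]`),
`z' = S_z / sum(S_z)` when two-affected-sib families exist, else frozen.
Origin priors are fixed inputs from genome-wide clustering and are not
updated within the EM — one marker carries negligible ancestry information
relative to the full panel.

In data with many complete families, `p` converges in a handful of
iterations.  The `z` direction is slower (it is informed only by het-parent
sib pairs) and converges geometrically at a rate around 0.85–0.9 per
iteration on affected-sib-pair data, so at `tol = 1e-6` the 50-iteration cap
often binds; the residual parameter motion at the cap is ~1e-5 and has no
visible effect on T or its bootstrap SD.  The log-likelihood is asserted
monotone at every iteration in the tests.

Implementation note: the E/M code is written batched — B weighted copies of
the marker's family table are processed as one `(B, families, K, 6[, 3])`
tensor program.  A bootstrap with B replicates is a single call; `run_em` is
the `B = 1` case.

## Bootstrap variance and the test

Family units (singletons included) are resampled with replacement, in one
pooled draw of `|units|` units per replicate.  Each replicate re-runs Ward
clustering on the sub-distance matrix of its resampled individuals, rebuilds
origin priors, re-runs the EM, and recomputes `T*`.  The reported SD uses
the `B - 1` denominator over surviving replicates; replicates whose EM has
no usable family are dropped, and more than 20% failures marks the marker
`degenerate_variance`.  The test statistic is `z = T / sd(T*)` without
bootstrap-mean centering (`E[T] = 0` under the null by construction),
referred two-sided to the standard normal.  Default `B = 200`.

Per-marker bootstrap streams derive from `SeedSequence((seed, marker
index))`, so results are independent of worker count and marker order; the
results TSV is byte-identical across `threads` settings.

## Synthetic data

The generator emulates stratified family/case-control studies:

* **Drift**: per-marker ancestral frequencies uniform on a configurable
  range (default 0.1–0.9); subpopulation frequencies Balding–Nichols
  `Beta(p0(1-F)/F, (1-p0)(1-F)/F)`, clamped to [0.01, 0.99].
* **Designs**: per subpopulation, configurable counts of unrelated cases,
  controls, triads (parents + one affected child) and multiplex families
  (parents + two affected sibs).
* **Disease model**: multiplicative genotype relative risk
  `f_g = f0 * GRR^g` at one causal locus; affection patterns enforced by
  rejection sampling (exact shortcut at GRR = 1, where affection is
  independent of genotype).  In `linked` mode the causal locus is a panel
  marker (complete linkage); in `unlinked` mode it is latent and all panel
  markers segregate independently of disease.
* **Truth**: subpopulation labels, true frequencies, and the gametic IBD
  state of every multiplex sib pair at the causal locus are exposed for
  parameter-recovery tests.

What the generator does **not** emulate: linkage disequilibrium between
markers, genotyping error, missing genotypes, age/covariate structure, or
realistic genome-scale marker counts.  Tests passing on these data show the
estimator and its calibration behave as designed under the model's own
assumptions — not that the method is robust to LD pruning choices or
genotyping artifacts in real data.

## Study scales used in the tests

Scales were chosen to exercise each claim on a single CPU:

* Clustering recovery: 2 x 100 individuals, 1000 markers, Fst 0.1, 20
  replicates (>= 90% best-permutation accuracy required each time).
* IBD recovery: 500 multiplex families, causal frequency 0.3, GRR 4,
  baseline penetrance 0.05, 10 replicate datasets per mode.
* Null calibration: 400 datasets of a two-population design with fully
  confounded sampling — population 1 contributes 100 case singletons + 100
  triads, population 2 contributes 100 control singletons + 100 multiplex
  families (N = 900, 400 units); 300-marker panel (enough for essentially
  perfect K = 2 recovery at Fst = 0.1); B = 100 bootstrap replicates.  The
  K = 2 type-I error at alpha = 0.05 must land in the exact binomial 95%
  envelope; the same data analysed with K = 1 must reject more often.
* Bootstrap-variance check: the bootstrap SD on one 200-triad dataset must
  fall within +/-25% of the Monte-Carlo SD of T over 500 independent
  datasets.

## Numerical and design choices

* Genotypes are dosages of the counted allele: A1 for binary input, the
  lexicographically smaller observed allele for text input (a .ped file
  declares no alleles; a marker whose counted allele is entirely unobserved
  is therefore coded against the other allele — an inherent text-format
  ambiguity that the binary format does not have).
* Families failing the Mendelian check are dropped at that marker only.
  The check is joint: some mating type compatible with the observed parents
  must be able to produce all non-missing children; for nuclear families
  this is equivalent to the per-child condition.
* Sibships with more than two affected sibs: the two with lexicographically
  smallest individual IDs are modelled; the rest are ignored entirely (both
  in the likelihood and in X_i), with a warning.
* Unaffected siblings of multi-member families enter only the Mendelian
  check; controls contribute their genotype as singleton offspring terms —
  necessary for the K = 1 case/control EM fixed point to equal the sample
  allele frequency.
* Parents' affection status is never used; parents condition the mating
  type only.
* Only two-generation pedigrees are accepted; an individual appearing as
  both child and parent raises an error rather than being silently split.
* Ties in Ward merges follow scipy's nearest-neighbor-chain order; exact
  agreement with the greedy reference is asserted on continuous random
  instances where ties have probability zero.

## Limitations

* The IBD model is exact only for affected sib *pairs*; larger sibships are
  truncated rather than modelled jointly.
* `z` estimates are unconstrained and can leave Holmans' possible triangle
  in small samples.
* The bootstrap includes clustering and EM variability but keeps the
  distance matrix fixed, per design; marker panels small enough that
  distance noise matters would understate variance.
* The normal reference for `z = T / sd(T*)` assumes B large enough that SD
  noise is second-order; B < 100 is not recommended.
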