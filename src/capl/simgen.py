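"""Synthetic stratified-pedigree data generator.

Emulates the study designs the combined family/case-control test is meant
for: one or more source subpopulations whose allele frequencies drift apart
under the Balding–Nichols model, and per-subpopulation samples of

* unrelated affected cases and unaffected controls,
* triad families (two parents + one affected child),
* multiplex families (two parents + two affected siblings),

all ascertained by rejection sampling on the affection pattern under a
multiplicative genotype-relative-risk disease model at a single causal
locus.  In ``linked`` mode the causal locus is itself one of the emitted
markers (complete linkage between the tested marker and disease); in
``unlinked`` mode the causal locus is latent and every emitted marker
segregates independently of disease.

The generator exposes the simulation truth — subpopulation labels, true
per-subpopulation frequencies, and the gametic IBD state of every multiplex
sib pair at the causal locus — for parameter-recovery tests, and writes
valid PLINK text or binary filesets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedio import (
    AFFECTED,
    GenotypeMatrix,
    Individual,
    Marker,
    PHENO_MISSING,
    SEX_FEMALE,
    SEX_MALE,
    UNAFFECTED,
    write_plink_binary_matrix,
)

__all__ = ["SubpopCounts", "SimConfig", "SimDataset", "draw_subpop_freqs",
           "simulate_family", "simulate_dataset", "write_plink"]


@dataclass
class SubpopCounts:
    """How many units of each design to draw from one subpopulation."""

    cases: int = 0
    controls: int = 0
    triads: int = 0
    multiplex: int = 0


@dataclass
class SimConfig:
    counts: list[SubpopCounts]
    n_markers: int = 200
    fst: float | list[float] = 0.1
    freq_range: tuple[float, float] = (0.1, 0.9)
    causal_index: int = 0
    grr: float = 1.0
    baseline_penetrance: float = 0.1
    linked: bool = True
    seed: int = 0
    max_rejection_rounds: int = 10_000

    def __post_init__(self) -> None:
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")
        f2 = self.baseline_penetrance * self.grr ** 2
        if not 0 < self.baseline_penetrance < 1 or f2 >= 1:
            raise ValueError("penetrances must lie in (0, 1)")
        if any(
            c < 0
            for sc in self.counts
            for c in (sc.cases, sc.controls, sc.triads, sc.multiplex)
        ):
            raise ValueError("unit counts must be non-negative")

    @property
    def n_subpops(self) -> int:
        return len(self.counts)

    def fst_for(self, k: int) -> float:
        if np.isscalar(self.fst):
            return float(self.fst)
        return float(self.fst[k])


@dataclass
class SimDataset:
    markers: list[Marker]
    individuals: list[Individual]
    genotypes: GenotypeMatrix
    true_labels: np.ndarray        # (N,) subpopulation index 0..K-1
    true_freqs: np.ndarray         # (K, M) counted-allele frequencies
    causal_index: int
    linked: bool
    causal_freqs: np.ndarray       # (K,) frequency at the causal locus
    multiplex_ibd: dict[str, int] = field(default_factory=dict)  # FID -> IBD at causal


def draw_subpop_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-marker, per-subpopulation counted-allele frequencies.

    Ancestral frequencies are uniform on ``freq_range``; each subpopulation
    drifts via the Balding–Nichols beta distribution with its Fst, clamped
    to [0.01, 0.99].  Fst -> 0 degenerates to no drift.
    """
    lo, hi = config.freq_range
    p0 = rng.uniform(lo, hi, size=config.n_markers)
    out = np.empty((config.n_subpops, config.n_markers))
    for k in range(config.n_subpops):
        f = config.fst_for(k)
        if f <= 0:
            out[k] = p0
        else:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            out[k] = rng.beta(a, b)
    return np.clip(out, 0.01, 0.99)


def _penetrance(g: np.ndarray, config: SimConfig) -> np.ndarray:
    return config.baseline_penetrance * config.grr ** g


_ALLELE_PAIRS = np.array([[0, 0], [1, 0], [1, 1]])  # genotype -> labelled alleles


def _ascertain_families(
    rng: np.random.Generator,
    p_causal: float,
    n_needed: int,
    n_affected_children: int,
    config: SimConfig,
):
    """Rejection-sample causal-locus genotypes for ascertained families.

    Returns (father_g, mother_g, child_g (n, c), ibd (n,) or None).  IBD is
    the number of parental gametes shared by the two children, tracked by
    the generator's own gamete labels.

    When GRR == 1 affection is independent of genotype, so ascertainment is
    a no-op on the genotype distribution and families are accepted directly.
    """
    c = n_affected_children
    got_f, got_m, got_ch, got_ibd = [], [], [], []
    total = 0
    rounds = 0
    while total < n_needed:
        rounds += 1
        if rounds > config.max_rejection_rounds:
            raise RuntimeError(
                "ascertainment failed to accept enough families; "
                "consider a larger baseline penetrance"
            )
        batch = max(256, 2 * (n_needed - total))
        gf = rng.binomial(2, p_causal, batch)
        gm = rng.binomial(2, p_causal, batch)
        # labelled gamete picks: which of the parent's two alleles transmits
        fi = rng.integers(0, 2, (batch, c))
        mi = rng.integers(0, 2, (batch, c))
        child = (
            _ALLELE_PAIRS[gf][np.arange(batch)[:, None], fi]
            + _ALLELE_PAIRS[gm][np.arange(batch)[:, None], mi]
        )
        if config.grr == 1.0:
            accept = np.ones(batch, dtype=bool)
        else:
            affected = rng.random((batch, c)) < _penetrance(child, config)
            accept = affected.all(axis=1)
        idx = np.flatnonzero(accept)[: n_needed - total]
        got_f.append(gf[idx])
        got_m.append(gm[idx])
        got_ch.append(child[idx])
        if c == 2:
            got_ibd.append(
                (fi[idx, 0] == fi[idx, 1]).astype(int)
                + (mi[idx, 0] == mi[idx, 1]).astype(int)
            )
        total += idx.size
    father = np.concatenate(got_f)
    mother = np.concatenate(got_m)
    children = np.concatenate(got_ch)
    ibd = np.concatenate(got_ibd) if c == 2 else None
    return father, mother, children, ibd


def _ascertain_singletons(
    rng: np.random.Generator,
    p_causal: float,
    n_needed: int,
    affected: bool,
    config: SimConfig,
) -> np.ndarray:
    """Causal genotypes of unrelated individuals ascertained on phenotype."""
    got, total, rounds = [], 0, 0
    while total < n_needed:
        rounds += 1
        if rounds > config.max_rejection_rounds:
            raise RuntimeError(
                "ascertainment failed to accept enough singletons; "
                "consider a larger baseline penetrance"
            )
        batch = max(256, 2 * (n_needed - total))
        g = rng.binomial(2, p_causal, batch)
        if config.grr == 1.0:
            accept = np.ones(batch, dtype=bool)
        else:
            aff = rng.random(batch) < _penetrance(g, config)
            accept = aff if affected else ~aff
        idx = np.flatnonzero(accept)[: n_needed - total]
        got.append(g[idx])
        total += idx.size
    return np.concatenate(got)


def _null_family_markers(
    rng: np.random.Generator, p: np.ndarray, n_fam: int, n_children: int
):
    """HWE parents + independent Mendelian transmissions at unlinked markers."""
    m = p.size
    gf = rng.binomial(2, p, (n_fam, m)).astype(np.int8)
    gm = rng.binomial(2, p, (n_fam, m)).astype(np.int8)
    kids = []
    for _ in range(n_children):
        tf = rng.random((n_fam, m)) < gf / 2.0
        tm = rng.random((n_fam, m)) < gm / 2.0
        kids.append((tf.astype(np.int8) + tm.astype(np.int8)))
    return gf, gm, kids


def simulate_family(
    design: str,
    subpop_freqs: np.ndarray,
    causal_freq: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict:
    """Draw one genotyped unit of the given design from one subpopulation.

    ``design`` is one of ``triad``, ``multiplex``, ``case_singleton``,
    ``control_singleton``.  Parents are HWE draws, offspring Mendelian
    transmissions, and the affection pattern of the design is enforced by
    rejection sampling at the causal locus (frequency ``causal_freq``).
    Returns a dict of genotype vectors over ``subpop_freqs`` markers
    (keys ``father``/``mother``/``children`` for families, ``individual``
    for singletons) plus ``ibd`` for multiplex sib pairs.  In linked mode
    the causal genotypes overwrite marker ``config.causal_index``.
    """
    p = np.asarray(subpop_freqs, dtype=float)
    if design in ("triad", "multiplex"):
        n_children = 1 if design == "triad" else 2
        gf_c, gm_c, ch_c, ibd = _ascertain_families(
            rng, causal_freq, 1, n_children, config
        )
        gf, gm, kids = _null_family_markers(rng, p, 1, n_children)
        if config.linked:
            gf[:, config.causal_index] = gf_c
            gm[:, config.causal_index] = gm_c
            for s in range(n_children):
                kids[s][:, config.causal_index] = ch_c[:, s]
        out = {
            "father": gf[0], "mother": gm[0],
            "children": [k[0] for k in kids],
        }
        if design == "multiplex":
            out["ibd"] = int(ibd[0])
        return out
    if design in ("case_singleton", "control_singleton"):
        g_c = _ascertain_singletons(
            rng, causal_freq, 1, design == "case_singleton", config
        )
        g = rng.binomial(2, p, (1, p.size)).astype(np.int8)
        if config.linked:
            g[:, config.causal_index] = g_c
        return {"individual": g[0]}
    raise ValueError(f"unknown design {design!r}")


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Draw a complete dataset under the configured study design."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    freqs = draw_subpop_freqs(config, rng)
    m = config.n_markers
    ci = config.causal_index
    if not 0 <= ci < m:
        raise ValueError("causal_index out of range")

    if config.linked:
        causal_freqs = freqs[:, ci].copy()
    else:
        # latent disease locus, drifted like any other marker
        lo, hi = config.freq_range
        p0 = rng.uniform(lo, hi)
        causal_freqs = np.empty(config.n_subpops)
        for k in range(config.n_subpops):
            f = config.fst_for(k)
            if f <= 0:
                causal_freqs[k] = p0
            else:
                causal_freqs[k] = rng.beta(
                    p0 * (1 - f) / f, (1 - p0) * (1 - f) / f
                )
        causal_freqs = np.clip(causal_freqs, 0.01, 0.99)

    markers = [
        Marker(id=f"rs{j}", chromosome="1", position=1000 * (j + 1),
               allele1="A", allele2="B")
        for j in range(m)
    ]

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    multiplex_ibd: dict[str, int] = {}

    def add(ind: Individual, genos: np.ndarray, k: int) -> None:
        individuals.append(ind)
        rows.append(genos.astype(np.int8))
        labels.append(k)

    for k, sc in enumerate(config.counts):
        p = freqs[k]
        pc = causal_freqs[k]

        for n_children, n_units, tag in (
            (1, sc.triads, "T"),
            (2, sc.multiplex, "X"),
        ):
            if n_units == 0:
                continue
            gf_c, gm_c, ch_c, ibd = _ascertain_families(
                rng, pc, n_units, n_children, config
            )
            gf, gm, kids = _null_family_markers(rng, p, n_units, n_children)
            if config.linked:
                gf[:, ci] = gf_c
                gm[:, ci] = gm_c
                for s in range(n_children):
                    kids[s][:, ci] = ch_c[:, s]
            for u in range(n_units):
                fid = f"S{k}{tag}{u}"
                add(Individual(fid, "F", None, None, SEX_MALE, PHENO_MISSING),
                    gf[u], k)
                add(Individual(fid, "M", None, None, SEX_FEMALE, PHENO_MISSING),
                    gm[u], k)
                for s in range(n_children):
                    add(
                        Individual(fid, f"C{s + 1}", "F", "M", SEX_MALE, AFFECTED),
                        kids[s][u], k,
                    )
                if n_children == 2:
                    multiplex_ibd[fid] = int(ibd[u])

        for n_units, affected, tag, pheno in (
            (sc.cases, True, "CA", AFFECTED),
            (sc.controls, False, "CO", UNAFFECTED),
        ):
            if n_units == 0:
                continue
            g_c = _ascertain_singletons(rng, pc, n_units, affected, config)
            g = rng.binomial(2, p, (n_units, m)).astype(np.int8)
            if config.linked:
                g[:, ci] = g_c
            for u in range(n_units):
                add(Individual(f"S{k}{tag}{u}", "I", None, None,
                               SEX_MALE, pheno), g[u], k)

    values = (
        np.stack(rows, axis=0)
        if rows
        else np.empty((0, m), dtype=np.int8)
    )
    return SimDataset(
        markers=markers,
        individuals=individuals,
        genotypes=GenotypeMatrix(values),
        true_labels=np.array(labels, dtype=np.int64),
        true_freqs=freqs,
        causal_index=ci,
        linked=config.linked,
        causal_freqs=causal_freqs,
        multiplex_ibd=multiplex_ibd,
    )


_GENO_TO_PAIR = {2: ("A", "A"), 1: ("A", "B"), 0: ("B", "B"), -1: ("0", "0")}


def write_plink(dataset: SimDataset, prefix: str | Path, binary: bool = False) -> None:
    """Write the dataset as a PLINK 1 fileset (``prefix``.ped/.map or .bed/.bim/.fam)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values = dataset.genotypes.values

    def six(ind: Individual) -> str:
        return "\t".join(
            [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                str(ind.sex),
                str(ind.phenotype) if ind.phenotype != PHENO_MISSING else "0",
            ]
        )

    if binary:
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for mk in dataset.markers:
                fh.write(
                    f"{mk.chromosome}\t{mk.id}\t0\t{mk.position}"
                    f"\t{mk.allele1}\t{mk.allele2}\n"
                )
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for ind in dataset.individuals:
                fh.write(six(ind) + "\n")
        prefix.with_suffix(".bed").write_bytes(write_plink_binary_matrix(values))
        return

    with open(prefix.with_suffix(".map"), "w") as fh:
        for mk in dataset.markers:
            fh.write(f"{mk.chromosome}\t{mk.id}\t0\t{mk.position}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(dataset.individuals):
            alleles = []
            for g in values[i]:
                a, b = _GENO_TO_PAIR[int(g)]
                alleles.append(a)
                alleles.append(b)
            fh.write(six(ind) + "\t" + "\t".join(alleles) + "\n")


def write_truth(dataset: SimDataset, prefix: str | Path) -> None:
    """Write sidecar TSVs with the simulation truth (labels, frequencies, IBD)."""
    prefix = Path(prefix)
    with open(str(prefix) + ".labels.tsv", "w") as fh:
        fh.write("FID\tIID\tSUBPOP\n")
        for ind, lab in zip(dataset.individuals, dataset.true_labels):
            fh.write(f"{ind.family_id}\t{ind.individual_id}\t{lab}\n")
    with open(str(prefix) + ".freqs.tsv", "w") as fh:
        K = dataset.true_freqs.shape[0]
        fh.write("SNP\t" + "\t".join(f"FREQ_{k}" for k in range(K)) + "\n")
        for j, mk in enumerate(dataset.markers):
            vals = "\t".join(f"{dataset.true_freqs[k, j]:.6f}" for k in range(K))
            fh.write(f"{mk.id}\t{vals}\n")
    with open(str(prefix) + ".truth.tsv", "w") as fh:
        fh.write("KEY\tVALUE\n")
        fh.write(f"causal_marker\t{dataset.markers[dataset.causal_index].id}\n")
        fh.write(f"linked\t{int(dataset.linked)}\n")
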