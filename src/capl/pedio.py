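"""PLINK 1 text/binary input and nuclear-family construction.

Reads .ped/.map or .bed/.bim/.fam datasets into a single genotype matrix
(individuals x markers, entries 0/1/2 counting copies of the counted allele,
-1 = missing), validates the pedigree columns, and folds everyone into
nuclear :class:`FamilyUnit` records: sibships with their (possibly missing)
parents, and unrelated cases/controls as singleton pseudo-families with two
missing parents.

Counted-allele convention: for binary input the counted allele defaults to
the .bim A1 allele; for text input it is the lexicographically smaller
observed allele (PLINK .ped carries no allele declaration).  Both can be
overridden per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genetics_core import OFFSPRING_TABLE, compatible_mating_types

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "Individual",
    "GenotypeMatrix",
    "FamilyUnit",
    "PlinkFormatError",
    "PedigreeError",
    "MISSING",
    "AFFECTED",
    "UNAFFECTED",
    "PHENO_MISSING",
    "read_plink_text",
    "read_plink_binary",
    "build_family_units",
    "mendel_consistent",
]

#: genotype code for a missing call
MISSING = -1

# phenotype codes (PLINK column-6 dialect)
AFFECTED = 2
UNAFFECTED = 1
PHENO_MISSING = 0

SEX_MALE, SEX_FEMALE, SEX_UNKNOWN = 1, 2, 0


class PlinkFormatError(ValueError):
    """Malformed PLINK input (row length, magic bytes, truncation...)."""


class PedigreeError(ValueError):
    """Unresolvable or cyclic pedigree structure."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker; ``allele1`` is the counted allele."""

    id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int
    phenotype: int


@dataclass
class GenotypeMatrix:
    """Individuals x markers counted-allele dosages; -1 marks missing calls."""

    values: np.ndarray  # int8, shape (N, M)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        bad = ~np.isin(self.values, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class FamilyUnit:
    """A nuclear analysis unit: optional parents plus a sibship.

    Unrelated cases/controls appear as singleton units (one sib, both
    parents absent).  Indices refer to positions in the individual list /
    genotype-matrix rows.
    """

    family_id: str
    father: int | None
    mother: int | None
    affected_sibs: list[int] = field(default_factory=list)
    unaffected_sibs: list[int] = field(default_factory=list)
    design_tag: str = "other"

    @property
    def members(self) -> list[int]:
        out = [i for i in (self.father, self.mother) if i is not None]
        return out + list(self.affected_sibs) + list(self.unaffected_sibs)


def _parse_phenotype(tok: str, where: str) -> int:
    if tok == "2":
        return AFFECTED
    if tok == "1":
        return UNAFFECTED
    if tok in ("0", "-9"):
        return PHENO_MISSING
    raise PlinkFormatError(f"{where}: unrecognized phenotype code {tok!r}")


def _parse_sex(tok: str) -> int:
    return {"1": SEX_MALE, "2": SEX_FEMALE}.get(tok, SEX_UNKNOWN)


def _parse_six(tokens: Sequence[str], where: str) -> Individual:
    fid, iid, pat, mat, sex, pheno = tokens
    return Individual(
        family_id=fid,
        individual_id=iid,
        father_id=None if pat == "0" else pat,
        mother_id=None if mat == "0" else mat,
        sex=_parse_sex(sex),
        phenotype=_parse_phenotype(pheno, where),
    )


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{ln}: expected 4 columns (CHR SNP CM BP), got {len(toks)}"
                )
            chrom, snp, _cm, bp = toks
            rows.append((chrom, snp, int(bp)))
    return rows


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    counted_allele: Mapping[str, str] | None = None,
) -> tuple[list[Marker], list[Individual], GenotypeMatrix]:
    """Read a PLINK 1 .ped/.map pair.

    Genotypes are recoded as counts of the counted allele — by default the
    lexicographically smaller allele observed at the marker, overridable per
    marker id via ``counted_allele``.  An allele code "0" on either side
    makes the whole genotype missing.  Markers with more than two observed
    alleles are excluded with a warning, as are markers with no observed
    alleles at all.
    """
    map_rows = _read_map(map_path)
    n_markers = len(map_rows)
    individuals: list[Individual] = []
    allele_rows: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            expected = 6 + 2 * n_markers
            if len(toks) != expected:
                raise PlinkFormatError(
                    f"{ped_path}:{ln}: expected {expected} fields "
                    f"(6 + 2 x {n_markers} markers), got {len(toks)}"
                )
            individuals.append(_parse_six(toks[:6], f"{ped_path}:{ln}"))
            pairs = list(zip(toks[6::2], toks[7::2]))
            allele_rows.append(pairs)

    n = len(individuals)
    markers: list[Marker] = []
    cols: list[np.ndarray] = []
    for j, (chrom, snp, bp) in enumerate(map_rows):
        observed: set[str] = set()
        for row in allele_rows:
            a, b = row[j]
            if a != "0":
                observed.add(a)
            if b != "0":
                observed.add(b)
        if len(observed) > 2:
            logger.warning("marker %s has >2 alleles; excluded as multiallelic", snp)
            continue
        if not observed:
            logger.warning("marker %s has no observed alleles; excluded", snp)
            continue
        ordered = sorted(observed)
        a1 = ordered[0]
        if counted_allele and snp in counted_allele:
            a1 = counted_allele[snp]
            if a1 not in observed and len(observed) == 2:
                raise PlinkFormatError(
                    f"counted allele {a1!r} for marker {snp} not observed in data"
                )
        a2 = next((a for a in ordered if a != a1), "0")
        col = np.empty(n, dtype=np.int8)
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0" or b == "0":
                col[i] = MISSING
            else:
                col[i] = (a == a1) + (b == a1)
        markers.append(Marker(snp, chrom, bp, a1, a2))
        cols.append(col)

    values = (
        np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype=np.int8)
    )
    return markers, individuals, GenotypeMatrix(values)


# 2-bit PLINK codes -> dosage of A1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_LUT = np.empty((256, 4), dtype=np.int8)
for _byte in range(256):
    for _i in range(4):
        _BED_LUT[_byte, _i] = _BED_CODE[(_byte >> (2 * _i)) & 0b11]

_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink_binary(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    counted_allele: Mapping[str, str] | None = None,
) -> tuple[list[Marker], list[Individual], GenotypeMatrix]:
    """Read a PLINK 1 binary .bed/.bim/.fam triple (SNP-major mode only).

    The counted allele defaults to the .bim A1 allele; a ``counted_allele``
    override naming the A2 allele flips the dosage for that marker.
    """
    individuals: list[Individual] = []
    with open(fam_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6:
                raise PlinkFormatError(
                    f"{fam_path}:{ln}: expected 6 columns, got {len(toks)}"
                )
            individuals.append(_parse_six(toks, f"{fam_path}:{ln}"))

    markers: list[Marker] = []
    flip = []
    with open(bim_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6:
                raise PlinkFormatError(
                    f"{bim_path}:{ln}: expected 6 columns, got {len(toks)}"
                )
            chrom, snp, _cm, bp, a1, a2 = toks
            do_flip = False
            if counted_allele and snp in counted_allele:
                want = counted_allele[snp]
                if want == a2:
                    a1, a2 = a2, a1
                    do_flip = True
                elif want != a1:
                    raise PlinkFormatError(
                        f"counted allele {want!r} for marker {snp} matches neither "
                        f"bim allele ({a1!r}/{a2!r})"
                    )
            markers.append(Marker(snp, chrom, int(bp), a1, a2))
            flip.append(do_flip)

    n, m = len(individuals), len(markers)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise PlinkFormatError(f"{bed_path}: missing PLINK .bed magic bytes")
    if raw[2] != 0x01:
        raise PlinkFormatError(
            f"{bed_path}: only SNP-major mode (0x01) is supported, got {raw[2]:#04x}"
        )
    bpm = (n + 3) // 4  # bytes per marker
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bpm * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bpm * m} data bytes for N={n}, M={m}; "
            f"found {body.size}"
        )
    if m == 0:
        values = np.empty((n, 0), dtype=np.int8)
    else:
        decoded = _BED_LUT[body.reshape(m, bpm)].reshape(m, bpm * 4)[:, :n]
        values = np.ascontiguousarray(decoded.T)
        for j, do_flip in enumerate(flip):
            if do_flip:
                col = values[:, j]
                nz = col != MISSING
                col[nz] = 2 - col[nz]
    return markers, individuals, GenotypeMatrix(values)


def write_plink_binary_matrix(values: np.ndarray) -> bytes:
    """Encode an (N, M) dosage matrix as a SNP-major .bed byte payload."""
    n, m = values.shape
    bpm = (n + 3) // 4
    padded = np.full((m, bpm * 4), 0, dtype=np.uint8)
    codes = np.empty_like(values, dtype=np.uint8)
    for dosage, bits in _BED_ENCODE.items():
        codes[values == dosage] = bits
    padded[:, :n] = codes.T
    shifted = padded.reshape(m, bpm, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    body = shifted.sum(axis=2, dtype=np.uint8)
    return b"\x6c\x1b\x01" + body.tobytes()


def build_family_units(
    individuals: Sequence[Individual],
) -> tuple[list[FamilyUnit], list[tuple[int, str]]]:
    """Partition individuals into nuclear family units.

    Returns ``(units, exclusions)`` where each exclusion is ``(index,
    reason)``.  Sibships sharing the same (possibly absent) parent pair form
    one unit; childless founders become case/control singletons according to
    phenotype, or are excluded if the phenotype is missing.
    """
    index: dict[tuple[str, str], int] = {}
    for i, ind in enumerate(individuals):
        key = (ind.family_id, ind.individual_id)
        if key in index:
            raise PedigreeError(f"duplicate individual {key}")
        index[key] = i

    def resolve(fid: str, pid: str | None, child: Individual) -> int | None:
        if pid is None:
            return None
        idx = index.get((fid, pid))
        if idx is None:
            raise PedigreeError(
                f"parent {pid!r} of {child.individual_id!r} not found in family {fid!r}"
            )
        return idx

    child_of: dict[int, tuple[int | None, int | None]] = {}
    referenced_parents: set[int] = set()
    for i, ind in enumerate(individuals):
        if ind.father_id is None and ind.mother_id is None:
            continue
        if ind.father_id == ind.individual_id or ind.mother_id == ind.individual_id:
            raise PedigreeError(
                f"individual {ind.individual_id!r} listed as its own ancestor"
            )
        fa = resolve(ind.family_id, ind.father_id, ind)
        mo = resolve(ind.family_id, ind.mother_id, ind)
        child_of[i] = (fa, mo)
        for p in (fa, mo):
            if p is not None:
                referenced_parents.add(p)

    both = referenced_parents & set(child_of)
    if both:
        i = sorted(both)[0]
        raise PedigreeError(
            f"individual {individuals[i].individual_id!r} is both a child and a "
            "parent; only two-generation nuclear pedigrees are supported"
        )

    units: list[FamilyUnit] = []
    exclusions: list[tuple[int, str]] = []

    sibships: dict[tuple[str, int | None, int | None], list[int]] = {}
    for i, (fa, mo) in sorted(child_of.items()):
        sibships.setdefault((individuals[i].family_id, fa, mo), []).append(i)

    for (fid, fa, mo), kids in sibships.items():
        unit = FamilyUnit(family_id=fid, father=fa, mother=mo)
        for i in kids:
            pheno = individuals[i].phenotype
            if pheno == AFFECTED:
                unit.affected_sibs.append(i)
            elif pheno == UNAFFECTED:
                unit.unaffected_sibs.append(i)
            else:
                logger.warning(
                    "sibling %s/%s has missing phenotype; excluded from unit",
                    fid, individuals[i].individual_id,
                )
                exclusions.append((i, "missing phenotype"))
        if not unit.affected_sibs and not unit.unaffected_sibs:
            # every child lost to missing phenotype; parents have no unit
            for p in (fa, mo):
                if p is not None:
                    exclusions.append((p, "no classifiable offspring"))
            continue
        n_aff, n_un = len(unit.affected_sibs), len(unit.unaffected_sibs)
        if fa is not None and mo is not None and n_un == 0 and n_aff == 1:
            unit.design_tag = "triad"
        elif fa is not None and mo is not None and n_un == 0 and n_aff == 2:
            unit.design_tag = "multiplex"
        units.append(unit)

    for i, ind in enumerate(individuals):
        if i in child_of or i in referenced_parents:
            continue
        if ind.phenotype == AFFECTED:
            units.append(
                FamilyUnit(ind.family_id, None, None, affected_sibs=[i],
                           design_tag="case_singleton")
            )
        elif ind.phenotype == UNAFFECTED:
            units.append(
                FamilyUnit(ind.family_id, None, None, unaffected_sibs=[i],
                           design_tag="control_singleton")
            )
        else:
            logger.warning(
                "founder %s/%s has missing phenotype; excluded",
                ind.family_id, ind.individual_id,
            )
            exclusions.append((i, "missing phenotype"))
    return units, exclusions


def mendel_consistent(unit: FamilyUnit, marker_genotypes: np.ndarray) -> bool:
    """True iff some mating type compatible with the observed parents can
    produce every non-missing child genotype by Mendelian transmission.

    Missing genotypes never create an inconsistency.
    """
    g = np.asarray(marker_genotypes)
    gf = int(g[unit.father]) if unit.father is not None else MISSING
    gm = int(g[unit.mother]) if unit.mother is not None else MISSING
    mask = compatible_mating_types(gf, gm)
    for i in list(unit.affected_sibs) + list(unit.unaffected_sibs):
        gc = int(g[i])
        if gc == MISSING:
            continue
        mask &= OFFSPRING_TABLE[:, gc] > 0
    return bool(mask.any())
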