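"""PLINK input, pedigree construction, Mendelian screening."""

import numpy as np
import pytest

from capl.pedio import (
    AFFECTED,
    MISSING,
    PedigreeError,
    PlinkFormatError,
    UNAFFECTED,
    build_family_units,
    mendel_consistent,
    read_plink_binary,
    read_plink_text,
)
from capl.simgen import SimConfig, SubpopCounts, simulate_dataset, write_plink


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_read_text_single_homozygote(tmp_path):
    ped = _write(tmp_path, "a.ped", "F1 I1 0 0 1 2 A A\n")
    mp = _write(tmp_path, "a.map", "1 rs1 0 100\n")
    markers, individuals, gm = read_plink_text(ped, mp)
    assert markers[0].allele1 == "A"
    assert gm.values[0, 0] == 2
    assert individuals[0].phenotype == AFFECTED


def test_read_text_missing_and_half_missing(tmp_path):
    ped = _write(
        tmp_path, "a.ped",
        "F1 I1 0 0 1 2 0 0 A G\nF1 I2 0 0 2 1 A 0 G G\n",
    )
    mp = _write(tmp_path, "a.map", "1 rs1 0 100\n1 rs2 0 200\n")
    _, _, gm = read_plink_text(ped, mp)
    assert gm.values[0, 0] == MISSING
    assert gm.values[1, 0] == MISSING  # half-missing call -> whole call missing
    assert gm.values[0, 1] == 1
    assert gm.values[1, 1] == 0  # G counted against lexicographically smaller A


def test_read_text_bad_row_length_reports_line(tmp_path):
    ped = _write(tmp_path, "a.ped", "F1 I1 0 0 1 2 A A\nF1 I2 0 0 1 2 A\n")
    mp = _write(tmp_path, "a.map", "1 rs1 0 100\n")
    with pytest.raises(PlinkFormatError, match=r":2"):
        read_plink_text(ped, mp)


def test_read_text_multiallelic_excluded(tmp_path, caplog):
    ped = _write(
        tmp_path, "a.ped",
        "F1 I1 0 0 1 2 A C A A\nF1 I2 0 0 1 1 G T A A\n",
    )
    mp = _write(tmp_path, "a.map", "1 rs1 0 100\n1 rs2 0 200\n")
    with caplog.at_level("WARNING"):
        markers, _, gm = read_plink_text(ped, mp)
    assert [m.id for m in markers] == ["rs2"]
    assert "multiallelic" in caplog.text


def test_text_binary_equivalence_roundtrip(tmp_path, small_stratified):
    """Text and binary emissions of one dataset read back identically and
    reproduce the generator's matrix exactly."""
    ds, _ = small_stratified
    write_plink(ds, tmp_path / "d", binary=False)
    write_plink(ds, tmp_path / "d", binary=True)
    mk_t, ind_t, gm_t = read_plink_text(tmp_path / "d.ped", tmp_path / "d.map")
    mk_b, ind_b, gm_b = read_plink_binary(
        tmp_path / "d.bed", tmp_path / "d.bim", tmp_path / "d.fam"
    )
    np.testing.assert_array_equal(gm_t.values, ds.genotypes.values)
    np.testing.assert_array_equal(gm_b.values, ds.genotypes.values)
    assert [m.id for m in mk_t] == [m.id for m in mk_b]
    assert [(i.family_id, i.individual_id, i.phenotype) for i in ind_t] == [
        (i.family_id, i.individual_id, i.phenotype) for i in ind_b
    ]


def test_binary_rejects_individual_major_and_bad_magic(tmp_path):
    (tmp_path / "x.bim").write_text("1 rs1 0 100 A B\n")
    (tmp_path / "x.fam").write_text("F1 I1 0 0 1 2\n")
    (tmp_path / "x.bed").write_bytes(b"\x6c\x1b\x00\x00")
    with pytest.raises(PlinkFormatError, match="SNP-major"):
        read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
    (tmp_path / "x.bed").write_bytes(b"\x00\x00\x01\x00")
    with pytest.raises(PlinkFormatError, match="magic"):
        read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")


def test_binary_truncation_and_empty(tmp_path):
    (tmp_path / "x.bim").write_text("1 rs1 0 100 A B\n1 rs2 0 200 A B\n")
    (tmp_path / "x.fam").write_text("F1 I1 0 0 1 2\n")
    (tmp_path / "x.bed").write_bytes(b"\x6c\x1b\x01\x00")  # 1 byte, need 2
    with pytest.raises(PlinkFormatError, match="bytes"):
        read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
    # zero markers: empty body is valid
    (tmp_path / "y.bim").write_text("")
    (tmp_path / "y.fam").write_text("F1 I1 0 0 1 2\n")
    (tmp_path / "y.bed").write_bytes(b"\x6c\x1b\x01")
    markers, individuals, gm = read_plink_binary(
        tmp_path / "y.bed", tmp_path / "y.bim", tmp_path / "y.fam"
    )
    assert markers == [] and gm.values.shape == (1, 0)


# ---------------------------------------------------------------------------
# family units

def _ind(fid, iid, pat=None, mat=None, pheno=UNAFFECTED):
    from capl.pedio import Individual
    return Individual(fid, iid, pat, mat, 1, pheno)


def test_unit_design_tags():
    inds = [
        _ind("F1", "F"), _ind("F1", "M"),
        _ind("F1", "C1", "F", "M", AFFECTED), _ind("F1", "C2", "F", "M", AFFECTED),
        _ind("F2", "F"), _ind("F2", "M"), _ind("F2", "C1", "F", "M", AFFECTED),
        _ind("F3", "I", pheno=AFFECTED),
        _ind("F4", "I", pheno=UNAFFECTED),
    ]
    units, exclusions = build_family_units(inds)
    tags = sorted(u.design_tag for u in units)
    assert tags == ["case_singleton", "control_singleton", "multiplex", "triad"]
    assert not exclusions
    multiplex = next(u for u in units if u.design_tag == "multiplex")
    assert multiplex.father is not None and len(multiplex.affected_sibs) == 2
    singleton = next(u for u in units if u.design_tag == "case_singleton")
    assert singleton.father is None and singleton.mother is None


def test_every_individual_in_exactly_one_unit_or_excluded(small_stratified):
    ds, units = small_stratified
    units, exclusions = build_family_units(ds.individuals)
    seen = []
    for u in units:
        seen.extend(u.members)
    seen.extend(i for i, _ in exclusions)
    assert sorted(seen) == list(range(len(ds.individuals)))


def test_missing_phenotype_founder_excluded(caplog):
    inds = [_ind("F1", "I", pheno=0)]
    with caplog.at_level("WARNING"):
        units, exclusions = build_family_units(inds)
    assert units == [] and exclusions == [(0, "missing phenotype")]


def test_self_parent_raises_cycle_error():
    inds = [_ind("F1", "I", pat="I", pheno=AFFECTED)]
    with pytest.raises(PedigreeError, match="ancestor"):
        build_family_units(inds)


def test_multigeneration_rejected():
    inds = [
        _ind("F1", "GF"), _ind("F1", "GM"),
        _ind("F1", "F", "GF", "GM"),
        _ind("F1", "M"),
        _ind("F1", "C", "F", "M", AFFECTED),
    ]
    with pytest.raises(PedigreeError, match="nuclear"):
        build_family_units(inds)


def test_unresolvable_parent_raises():
    inds = [_ind("F1", "C", "NOPE", None, AFFECTED)]
    with pytest.raises(PedigreeError, match="not found"):
        build_family_units(inds)


# ---------------------------------------------------------------------------
# Mendelian consistency

@pytest.mark.parametrize(
    "gf,gm,children,expected",
    [
        (2, 2, [1], False),          # AA x AA cannot produce Aa
        (1, 1, [0], True), (1, 1, [1], True), (1, 1, [2], True),
        (2, MISSING, [0], False),    # AA father must transmit A
        (2, MISSING, [1], True),
        (MISSING, MISSING, [0, 2], True),   # het x het completion exists
        (0, MISSING, [1, 2], False),        # child 2 impossible with a 0 parent
        (1, 1, [MISSING], True),     # missing genotypes never inconsistent
    ],
)
def test_mendel_consistency_cases(gf, gm, children, expected):
    from capl.pedio import FamilyUnit
    geno = [gf, gm] + children
    unit = FamilyUnit(
        "F", 0, 1, affected_sibs=list(range(2, 2 + len(children)))
    )
    assert mendel_consistent(unit, np.array(geno)) is expected
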