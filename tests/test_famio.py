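"""PLINK text/binary round-trips, SNP-set parsing, and results output."""
import numpy as np
import pytest

from optpdt import famio
from optpdt.famio import (
    MISSING,
    FormatError,
    ParseError,
    read_plink_binary,
    read_plink_text,
    read_snp_sets,
    sets_from_intervals,
    write_plink_binary,
    write_plink_text,
    write_results,
)
from optpdt.pdt_core import build_d_matrix
from optpdt.simulate import SimulationConfig, simulate_study

from conftest import make_markers


PED_TRIO = """\
F1 dad 0 0 1 1 1 1
F1 mom 0 0 2 1 1 2
F1 kid dad mom 1 2 1 1
"""
MAP_ONE = "1 rs1 0 1000\n"


def test_ped_trio_field_mapping(tmp_path):
    (tmp_path / "s.ped").write_text(PED_TRIO)
    (tmp_path / "s.map").write_text(MAP_ONE)
    study = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    assert study.n_families == 1 and study.n_markers == 1
    marker = study.markers[0]
    # allele "2" appears once of six -> minor -> counted
    assert marker.counted_allele == "2"
    fam = study.families[0]
    assert fam.father.tolist() == [0]
    assert fam.mother.tolist() == [1]
    child = fam.children[0]
    assert child.affected and child.genotypes.tolist() == [0]


def test_ped_missing_alleles_and_counts(tmp_path):
    ped = (
        "F1 dad 0 0 1 1 A A\n"
        "F1 mom 0 0 2 1 0 0\n"
        "F1 kid dad mom 1 2 A C\n"
    )
    (tmp_path / "s.ped").write_text(ped)
    (tmp_path / "s.map").write_text(MAP_ONE)
    study = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    fam = study.families[0]
    assert fam.mother.tolist() == [MISSING]
    assert study.missing_genotype_count() == 1


def test_ped_two_sibs_one_family(tmp_path):
    ped = (
        "F1 dad 0 0 1 1 A A\n"
        "F1 mom 0 0 2 1 A C\n"
        "F1 kid1 dad mom 1 2 A A\n"
        "F1 kid2 dad mom 2 1 A C\n"
    )
    (tmp_path / "s.ped").write_text(ped)
    (tmp_path / "s.map").write_text(MAP_ONE)
    study = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    assert study.n_families == 1
    fam = study.families[0]
    assert [c.id for c in fam.children] == ["kid1", "kid2"]
    assert [c.affected for c in fam.children] == [True, False]


def test_ped_malformed_row_names_line(tmp_path):
    (tmp_path / "s.ped").write_text("F1 kid dad mom 1 2 A\n")
    (tmp_path / "s.map").write_text(MAP_ONE)
    with pytest.raises(ParseError, match="line 1"):
        read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")


def test_ped_triallelic_marker_rejected(tmp_path):
    ped = "F1 dad 0 0 1 1 A C\nF1 mom 0 0 2 1 A G\nF1 kid dad mom 1 2 A A\n"
    (tmp_path / "s.ped").write_text(ped)
    (tmp_path / "s.map").write_text(MAP_ONE)
    with pytest.raises(ParseError, match="rs1"):
        read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")


def test_ped_three_generations_rejected(tmp_path):
    ped = (
        "F1 gp 0 0 1 1 A A\n"
        "F1 dad gp 0 1 1 A C\n"
        "F1 kid dad mom 1 2 A A\n"
    )
    (tmp_path / "s.ped").write_text(ped)
    (tmp_path / "s.map").write_text(MAP_ONE)
    with pytest.raises(ParseError, match="two generations|parent pairs"):
        read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")


def test_bed_byte_decoding(tmp_path):
    """One SNP, 4 individuals packed as 0b11100100: codes 00,01,10,11 from the
    LSB map to 2 copies of A1, missing, het, and 0 copies."""
    (tmp_path / "s.bim").write_text("1\trs1\t0\t1000\tA\tG\n")
    (tmp_path / "s.fam").write_text(
        "F1 dad 0 0 1 1\nF1 mom 0 0 2 1\nF1 kid1 dad mom 1 2\nF1 kid2 dad mom 2 1\n"
    )
    (tmp_path / "s.bed").write_bytes(b"\x6c\x1b\x01" + bytes([0b11100100]))
    study = read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
    fam = study.families[0]
    assert fam.father.tolist() == [2]
    assert fam.mother.tolist() == [MISSING]
    assert fam.children[0].genotypes.tolist() == [1]
    assert fam.children[1].genotypes.tolist() == [0]
    assert study.markers[0].counted_allele == "A"


def test_bed_bad_magic_and_truncation(tmp_path):
    (tmp_path / "s.bim").write_text("1\trs1\t0\t1000\tA\tG\n")
    (tmp_path / "s.fam").write_text("F1 kid dad mom 1 2\n")
    (tmp_path / "s.bed").write_bytes(b"\x00\x00\x01\x00")
    with pytest.raises(FormatError, match="magic"):
        read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
    (tmp_path / "s.bed").write_bytes(b"\x6c\x1b\x01")  # payload missing entirely
    with pytest.raises(FormatError, match="truncated|corrupt"):
        read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")


def _studies_equal(a, b):
    assert [m.id for m in a.markers] == [m.id for m in b.markers]
    assert a.n_families == b.n_families
    for fa, fb in zip(a.families, b.families):
        assert fa.family_id == fb.family_id
        for va, vb in ((fa.father, fb.father), (fa.mother, fb.mother)):
            assert (va is None) == (vb is None)
            if va is not None:
                np.testing.assert_array_equal(va, vb)
        assert len(fa.children) == len(fb.children)
        for ca, cb in zip(fa.children, fb.children):
            assert ca.affected == cb.affected
            np.testing.assert_array_equal(ca.genotypes, cb.genotypes)


@pytest.mark.parametrize("structure", ["nuclear", "triad", "discordant_sibship"])
def test_text_and_binary_readers_agree_on_simulated_study(tmp_path, structure):
    """Write PED/MAP and BED/BIM/FAM from one simulated study; both readers
    must reconstruct identical StudyData (and the same D matrix)."""
    config = SimulationConfig(
        n_families=30, structure=structure, n_markers=8, n_haplotypes=400,
        maf_low=0.1, maf_high=0.35, seed=5,
    )
    study, _ = simulate_study(config)
    write_plink_text(study, tmp_path / "s.ped", tmp_path / "s.map")
    write_plink_binary(study, tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
    from_text = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    from_bin = read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
    _studies_equal(from_text, from_bin)
    np.testing.assert_allclose(
        build_d_matrix(from_text).values, build_d_matrix(from_bin).values
    )
    # planted missingness: discordant sibships have both parents ungenotyped
    if structure == "discordant_sibship":
        assert all(f.father is None and f.mother is None for f in from_text.families)


def test_reading_is_idempotent_and_order_preserving(tmp_path):
    config = SimulationConfig(n_families=10, structure="triad", n_markers=4,
                              n_haplotypes=200, seed=9)
    study, _ = simulate_study(config)
    write_plink_text(study, tmp_path / "s.ped", tmp_path / "s.map")
    first = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    second = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
    _studies_equal(first, second)
    assert [f.family_id for f in first.families] == [f.family_id for f in study.families]
    assert [m.id for m in first.markers] == [m.id for m in study.markers]


class TestSnpSets:
    def test_plink_dialect_with_filtering(self, tmp_path):
        (tmp_path / "g.set").write_text("G1\nrs1\nrs2\nrs9\nEND\nG2\nrs3\nEND\n")
        sets = read_snp_sets(tmp_path / "g.set", make_markers(3))
        assert [s.name for s in sets] == ["G1", "G2"]
        assert sets[0].marker_ids == ["rs1", "rs2"]  # rs9 not in data

    def test_empty_set_dropped(self, tmp_path):
        (tmp_path / "g.set").write_text("G1\nrs9\nEND\nG2\nrs1\nEND\n")
        sets = read_snp_sets(tmp_path / "g.set", make_markers(2))
        assert [s.name for s in sets] == ["G2"]

    def test_unterminated_block(self, tmp_path):
        (tmp_path / "g.set").write_text("G1\nrs1\nrs2\n")
        with pytest.raises(ParseError, match="END"):
            read_snp_sets(tmp_path / "g.set", make_markers(2), set_format="plink")

    def test_duplicate_names(self, tmp_path):
        (tmp_path / "g.set").write_text("G1\nrs1\nEND\nG1\nrs2\nEND\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_snp_sets(tmp_path / "g.set", make_markers(2))

    def test_tsv_autodetected(self, tmp_path):
        (tmp_path / "g.tsv").write_text("G1\trs1\nG1\trs2\nG2\trs2\n")
        sets = read_snp_sets(tmp_path / "g.tsv", make_markers(2))
        assert [(s.name, s.marker_ids) for s in sets] == [
            ("G1", ["rs1", "rs2"]),
            ("G2", ["rs2"]),
        ]

    def test_interval_assignment(self):
        # markers at 1000, 2000, ..., 5000 (conftest spacing); closed 1-based intervals
        markers = make_markers(5)
        sets = sets_from_intervals(
            [("G1", "1", 1000, 2999), ("G2", "1", 3000, 5000)], markers
        )
        assert sets[0].marker_ids == ["rs1", "rs2"]
        assert sets[1].marker_ids == ["rs3", "rs4", "rs5"]
        padded = sets_from_intervals([("G1", "1", 1500, 2999)], markers, padding=500)
        assert padded[0].marker_ids == ["rs1", "rs2", "rs3"]


class TestWriteResults:
    def test_empty_results_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_results([], out, thresholds=(0.05,))
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("SET\t")

    def test_one_row_with_zero_p_sentinel(self, tmp_path):
        from optpdt.engine import OPTPDTResult

        res = OPTPDTResult(
            set_name="G1", thresholds=(0.05,), n_markers=3, n_informative_families=10,
            selected={0.05: ["rs1"]}, Y={0.05: 5.0}, mu_hat={0.05: 1.0},
            sigma_hat={0.05: 0.5}, z_scores={0.05: 8.0}, M=8.0, best_threshold=0.05,
            m=1000, exceedances=0, p=0.0, min_attainable_p=1e-3,
        )
        out = tmp_path / "r.tsv"
        write_results([res], out)
        header, row = out.read_text().splitlines()
        cells = dict(zip(header.split("\t"), row.split("\t")))
        assert cells["SET"] == "G1"
        assert cells["P"] == "0.000000e+00"
        assert cells["P_DISPLAY"].startswith("<")
        assert float(cells["MIN_P"]) == pytest.approx(1e-3)
        assert cells["Z_0.05"] == "8"
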