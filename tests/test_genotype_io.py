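"""PLINK I/O, the HWE exact test and quality control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.genotype_io import (MISSING, PhenotypeSchema,
                                 PlinkFormatError, QCParams,
                                 align_counted_alleles, apply_qc,
                                 hwe_exact_test, read_phenotypes,
                                 read_plink_binary, read_plink_text,
                                 write_phenotypes, write_plink_binary,
                                 write_plink_text)

from conftest import make_panel, random_panel
from oracles import hwe_enumeration


# ---------------------------------------------------------------------------
# text reader
# ---------------------------------------------------------------------------

def write_files(tmp_path, map_lines, ped_lines):
    (tmp_path / "x.map").write_text("\n".join(map_lines) + "\n")
    (tmp_path / "x.ped").write_text("\n".join(ped_lines) + "\n")
    return tmp_path / "x.ped", tmp_path / "x.map"


def test_ped_direct_encoding_counts_first_observed_allele(tmp_path):
    ped, mp = write_files(tmp_path,
                          ["1 snp1 0 100", "1 snp2 0 200"],
                          ["F1 ind1 0 0 0 -9 A A G T"])
    g = read_plink_text(ped, mp)
    assert g.codes.tolist() == [[2, 1]]
    assert list(g.snps.table["a1"]) == ["A", "G"]


def test_ped_zero_alleles_are_missing(tmp_path):
    ped, mp = write_files(tmp_path,
                          ["1 snp1 0 100", "1 snp2 0 200"],
                          ["F1 ind1 0 0 0 -9 0 0 C C"])
    g = read_plink_text(ped, mp)
    assert g.codes[0, 0] == MISSING and g.codes[0, 1] == 2


def test_ped_malformed_row_names_line(tmp_path):
    ped, mp = write_files(tmp_path, ["1 snp1 0 100"],
                          ["F1 ind1 0 0 0 -9 A A", "F2 ind2 0 0 0 -9 A"])
    with pytest.raises(PlinkFormatError, match="2"):
        read_plink_text(ped, mp)


def test_text_round_trip_reproduces_codes(tmp_path):
    rng = np.random.default_rng(11)
    g = random_panel(rng, n_ind=10, n_snps=50)
    write_plink_text(g, tmp_path / "rt.ped", tmp_path / "rt.map")
    g2 = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
    g2 = align_counted_alleles(g2, g)
    np.testing.assert_array_equal(g.codes, g2.codes)
    assert g2.individuals == g.individuals


# ---------------------------------------------------------------------------
# binary reader
# ---------------------------------------------------------------------------

def test_binary_and_text_load_identically(tmp_path):
    rng = np.random.default_rng(5)
    g = random_panel(rng, n_ind=5, n_snps=20)
    write_plink_text(g, tmp_path / "p.ped", tmp_path / "p.map")
    write_plink_binary(g, tmp_path / "p.bed", tmp_path / "p.bim", tmp_path / "p.fam")
    gt = align_counted_alleles(read_plink_text(tmp_path / "p.ped", tmp_path / "p.map"), g)
    gb = read_plink_binary(tmp_path / "p.bed", tmp_path / "p.bim", tmp_path / "p.fam")
    np.testing.assert_array_equal(gt.codes, gb.codes)
    assert gt.individuals == gb.individuals
    assert list(gt.snps.table["pos"]) == list(gb.snps.table["pos"])


def test_all_missing_snp_round_trips_as_missing_column(tmp_path):
    codes = np.array([[1, MISSING], [0, MISSING], [2, MISSING]])
    g = make_panel(codes)
    write_plink_binary(g, tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
    gb = read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
    assert (gb.codes[:, 1] == MISSING).all()


def test_bed_bad_magic_rejected(tmp_path):
    g = make_panel(np.array([[0, 1], [2, 1]]))
    write_plink_binary(g, tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
    raw = (tmp_path / "b.bed").read_bytes()
    (tmp_path / "b.bed").write_bytes(b"\x00\x00" + raw[2:])
    with pytest.raises(PlinkFormatError, match="magic"):
        read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")


def test_bed_individual_major_unsupported(tmp_path):
    g = make_panel(np.array([[0, 1], [2, 1]]))
    write_plink_binary(g, tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
    raw = (tmp_path / "b.bed").read_bytes()
    (tmp_path / "b.bed").write_bytes(raw[:2] + b"\x00" + raw[3:])
    with pytest.raises(PlinkFormatError, match="individual-major"):
        read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")


def test_bed_truncated_payload_errors(tmp_path):
    g = make_panel(np.tile([0, 1, 2], (5, 4)))
    write_plink_binary(g, tmp_path / "t.bed", tmp_path / "t.bim", tmp_path / "t.fam")
    raw = (tmp_path / "t.bed").read_bytes()
    (tmp_path / "t.bed").write_bytes(raw[:-1])
    with pytest.raises(PlinkFormatError, match="payload"):
        read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim", tmp_path / "t.fam")


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("triple,expected", [
    ((100, 0, 0), 1.0),     # monomorphic: single configuration
    ((25, 50, 25), 1.0),    # exactly at HW proportions
])
def test_hwe_exact_known_values(triple, expected):
    assert hwe_exact_test(*triple) == pytest.approx(expected, abs=1e-12)


def test_hwe_all_het_fails_qc_threshold():
    assert hwe_exact_test(0, 100, 0) < 1e-6
    assert hwe_exact_test(0, 100, 0) == pytest.approx(hwe_enumeration(0, 100, 0),
                                                      abs=1e-12)


def test_hwe_zero_individuals_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
def test_hwe_matches_enumeration_oracle(a, b, c):
    if a + b + c == 0 or a + b + c > 200:
        return
    assert hwe_exact_test(a, b, c) == pytest.approx(hwe_enumeration(a, b, c),
                                                    abs=1e-12)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_violating_column(n):
    """All-het column: the strongest possible HWE violation."""
    return np.ones(n, dtype=np.int8)


def test_qc_engineered_panel_step_counts():
    """Panel built so the four steps remove 2 SNPs, 1 individual, 3 SNPs, 1 SNP."""
    rng = np.random.default_rng(3)
    n_ind, n_auto = 40, 20
    codes = rng.binomial(2, 0.5, size=(n_ind, n_auto + 2)).astype(np.int8)
    # steps target: 2 sex-chromosome SNPs (last two columns)
    chroms = ["1"] * n_auto + ["X", "Y"]
    # 1 individual with low call rate
    codes[0, : n_auto // 2] = MISSING
    # 3 autosomal SNPs with low call rate; missing cells spread over different
    # individuals so no further individual falls under its call-rate threshold
    for k, rows in ((2, slice(1, 5)), (5, slice(5, 9)), (9, slice(9, 13))):
        codes[rows, k] = MISSING
    # 1 autosomal SNP violating HWE
    codes[:, 15] = hwe_violating_column(n_ind)
    g = make_panel(codes, chroms=chroms,
                   positions=list(range(10_000, 10_000 * (n_auto + 1), 10_000)) + [5_000, 6_000])
    out, report = apply_qc(g, QCParams())
    assert report.sex_chrom_snps_removed == 2
    assert report.individuals_removed == 1
    assert report.low_call_snps_removed == 3
    assert report.hwe_snps_removed == 1
    assert report.n_snps_in - report.n_snps_out == 2 + 3 + 1
    assert report.n_individuals_in - report.n_individuals_out == 1
    assert out.n_snps == report.n_snps_out and out.n_individuals == report.n_individuals_out


def test_qc_removes_clean_sex_chromosome_snp():
    codes = np.tile([0, 2], (10, 1))
    g = make_panel(codes, chroms=["1", "X"], positions=[100, 100])
    out, report = apply_qc(g)
    assert report.sex_chrom_snps_removed == 1
    assert list(out.snps.table["chrom"]) == ["1"]


def test_qc_idempotent(small_panel):
    params = QCParams(min_snp_call_rate=0.9, min_individual_call_rate=0.5)
    once, _ = apply_qc(small_panel, params)
    twice, report = apply_qc(once, params)
    np.testing.assert_array_equal(once.codes, twice.codes)
    assert report.n_snps_in == report.n_snps_out
    assert report.n_individuals_in == report.n_individuals_out


def test_qc_everything_removed_is_an_error():
    g = make_panel(np.full((5, 3), MISSING, dtype=np.int8))
    with pytest.raises(ValueError):
        apply_qc(g)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def pheno_frame(n=6):
    rng = np.random.default_rng(0)
    schema = PhenotypeSchema()
    return pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "farm": rng.choice(schema.factor_levels["farm"], n),
        "sex": rng.choice(schema.factor_levels["sex"], n),
        "color_type": rng.choice(schema.factor_levels["color_type"], n),
        "row_year": rng.choice(schema.factor_levels["row_year"], n),
        "age_days": rng.integers(184, 230, n),
        "FBW": rng.normal(size=n),
    })


def test_phenotype_round_trip(tmp_path):
    df = pheno_frame()
    df.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
    table = read_phenotypes(tmp_path / "p.tsv")
    write_phenotypes(table, tmp_path / "p2.tsv")
    again = read_phenotypes(tmp_path / "p2.tsv")
    pd.testing.assert_frame_equal(table.data, again.data)


def test_phenotype_known_color_accepted_unknown_rejected(tmp_path):
    df = pheno_frame()
    df.loc[0, "color_type"] = "pastel"
    df.to_csv(tmp_path / "ok.tsv", sep="\t", index=False)
    assert read_phenotypes(tmp_path / "ok.tsv").data.loc[0, "color_type"] == "pastel"
    df.loc[0, "color_type"] = "white"
    df.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="white"):
        read_phenotypes(tmp_path / "bad.tsv")


def test_phenotype_missing_column_rejected(tmp_path):
    df = pheno_frame().drop(columns=["farm"])
    df.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="farm"):
        read_phenotypes(tmp_path / "p.tsv")


def test_phenotype_missing_trait_values_kept(tmp_path):
    df = pheno_frame()
    df.loc[2, "FBW"] = np.nan
    df.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
    table = read_phenotypes(tmp_path / "p.tsv")
    assert len(table.data) == len(df)
    assert table.data["FBW"].isna().sum() == 1
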