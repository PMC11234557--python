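"""Sliding-window ROH detection against brute-force oracles and hand fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.genotype_io import MISSING
from rohscan.roh import (ROHScanParams, assemble_segments, backsolve_heterozygosity,
                         classify_length, detect_roh, lencz_min_snps,
                         mean_heterozygosity, scan_windows, summarize_roh)

from conftest import make_panel, random_panel
from oracles import roh_brute_force


# ---------------------------------------------------------------------------
# Lencz minimum-SNP bound
# ---------------------------------------------------------------------------

def test_lencz_hand_value():
    # ln(0.05 / (100*1000)) / ln(0.5) = 20.93... -> ceil 21
    assert lencz_min_snps(0.05, 1000, 100, 0.5) == 21


def test_lencz_low_heterozygosity_needs_more_snps():
    assert lencz_min_snps(0.05, 1000, 100, 0.01) > lencz_min_snps(0.05, 1000, 100, 0.5)


def test_lencz_degenerate_heterozygosity_rejected():
    for het in (0.0, 1.0):
        with pytest.raises(ValueError):
            lencz_min_snps(0.05, 1000, 100, het)


@settings(derandomize=True, deadline=None, max_examples=250)
@given(st.floats(0.001, 0.5), st.integers(100, 100_000), st.integers(10, 5_000),
       st.floats(0.05, 0.95))
def test_lencz_monotonicity(alpha, ns, na, het):
    base = lencz_min_snps(alpha, ns, na, het)
    assert lencz_min_snps(alpha, ns * 2, na, het) >= base
    assert lencz_min_snps(alpha, ns, na * 2, het) >= base
    # higher heterozygosity makes chance homozygous runs rarer -> smaller bound
    assert lencz_min_snps(alpha, ns, na, min(het * 1.1, 0.96)) <= base
    assert lencz_min_snps(min(alpha * 2, 0.99), ns, na, het) <= base


def test_mean_heterozygosity_counts():
    g = make_panel(np.array([[0, 1], [1, 1], [2, MISSING]]))
    assert mean_heterozygosity(g) == pytest.approx(3 / 5)
    assert mean_heterozygosity(make_panel(np.ones((3, 4)))) == 1.0
    assert mean_heterozygosity(make_panel(np.zeros((3, 4)))) == 0.0


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def test_scan_all_homozygous_all_flagged():
    params = ROHScanParams()
    flags = scan_windows(np.zeros((1, 100), dtype=np.int8), params)
    assert flags.all()


def test_scan_all_het_none_flagged():
    params = ROHScanParams()
    flags = scan_windows(np.ones((1, 100), dtype=np.int8), params)
    assert not flags.any()


def test_scan_short_chromosome_yields_no_flags():
    params = ROHScanParams(window_snps=50)
    assert not scan_windows(np.zeros((2, 49), dtype=np.int8), params).any()


@pytest.mark.parametrize("seed", range(20))
def test_scan_matches_window_enumeration(seed):
    """Vectorised scan equals the explicit per-window enumeration."""
    rng = np.random.default_rng(seed)
    g = random_panel(rng, n_ind=3, n_snps=200, het_rate=rng.uniform(0, 0.2),
                     missing_rate=rng.uniform(0, 0.2))
    params = ROHScanParams(window_snps=20)
    flags = scan_windows(g.codes, params)
    for i in range(3):
        segs = roh_brute_force(g.codes[i], g.snps.table["pos"].to_numpy(),
                               window_snps=20, min_length_kb=0.001, min_snps=1,
                               max_density_kb_per_snp=1e12, max_gap_kb=1e12)
        oracle_flags = np.zeros(200, dtype=bool)
        pos = g.snps.table["pos"].to_numpy()
        for start, end, _ in segs:
            oracle_flags[(pos >= start) & (pos <= end)] = True
        np.testing.assert_array_equal(flags[i], oracle_flags)


# ---------------------------------------------------------------------------
# segment assembly
# ---------------------------------------------------------------------------

def test_assemble_simple_run():
    params = ROHScanParams(min_length_kb=1000)
    positions = np.arange(60) * 34_000 + 1  # ~2 Mb span
    flags = np.ones(60, dtype=bool)
    segs = assemble_segments(flags, positions, params, min_snps=57,
                             individual="a", chrom="1")
    assert len(segs) == 1
    assert segs[0].start_bp == positions[0] and segs[0].end_bp == positions[-1]
    assert segs[0].n_snps == 60


def test_assemble_gap_split_kills_short_halves():
    params = ROHScanParams()
    positions = np.concatenate([np.arange(30) * 34_000 + 1,
                                np.arange(30) * 34_000 + 2_520_001])  # 1.5 Mb gap
    flags = np.ones(60, dtype=bool)
    segs = assemble_segments(flags, positions, params, min_snps=57,
                             individual="a", chrom="1")
    assert segs == []


def test_assemble_min_length_rejects_short_span():
    params = ROHScanParams()
    positions = np.arange(60) * 15_000 + 1  # ~900 kb
    segs = assemble_segments(np.ones(60, bool), positions, params, min_snps=57,
                             individual="a", chrom="1")
    assert segs == []


def test_assemble_density_boundary_inclusive():
    # exactly 50 kb/SNP must be retained
    n = 60
    length_kb = 50.0 * n
    positions = np.linspace(1, length_kb * 1000, n).astype(int)
    params = ROHScanParams(max_gap_kb=1e9)
    segs = assemble_segments(np.ones(n, bool), positions, params, min_snps=1,
                             individual="a", chrom="1")
    assert len(segs) == 1
    assert (segs[0].length_bp / 1000) / segs[0].n_snps <= 50.0 + 1e-9


# ---------------------------------------------------------------------------
# full detection vs brute force
# ---------------------------------------------------------------------------

def run_oracle(g, params, min_snps):
    out = []
    chrom_col = g.snps.table["chrom"].to_numpy()
    pos_col = g.snps.table["pos"].to_numpy()
    for ind_idx, ind in enumerate(g.individuals):
        for chrom in g.snps.chromosomes:
            mask = chrom_col == chrom
            segs = roh_brute_force(
                g.codes[ind_idx, mask], pos_col[mask],
                window_snps=params.window_snps,
                window_max_het=params.window_max_het,
                window_max_missing=params.window_max_missing,
                window_hit_threshold=params.window_hit_threshold,
                min_length_kb=params.min_length_kb, min_snps=min_snps,
                max_density_kb_per_snp=params.max_density_kb_per_snp,
                max_gap_kb=params.max_gap_kb)
            out.extend((ind, chrom, s, e, n) for s, e, n in segs)
    return out


def test_detect_single_all_homozygous_chromosome():
    positions = np.arange(100) * 50_000 + 1  # 5 Mb
    g = make_panel(np.zeros((1, 100), dtype=np.int8), positions=positions)
    segs = detect_roh(g, ROHScanParams(min_snps=57))
    assert len(segs) == 1
    assert segs[0].n_snps == 100
    assert segs[0].start_bp == 1 and segs[0].end_bp == positions[-1]


def test_default_params_match_standard_configuration():
    p = ROHScanParams()
    assert (p.window_snps, p.window_max_het, p.window_max_missing) == (50, 1, 1)
    assert (p.min_length_kb, p.max_density_kb_per_snp, p.max_gap_kb) == (1000, 50, 1000)
    assert p.alpha == 0.05 and p.min_snps is None


@pytest.mark.parametrize("seed", range(12))
def test_detect_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    het = rng.uniform(0, 0.2)
    miss = rng.uniform(0, 0.2)
    g = random_panel(rng, n_ind=20, n_snps=300, het_rate=het, missing_rate=miss)
    params = ROHScanParams(window_snps=25, min_snps=20, min_length_kb=100,
                           max_gap_kb=500)
    got = [(s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps)
           for s in detect_roh(g, params)]
    expected = run_oracle(g, params, 20)
    assert sorted(got) == sorted(expected)


def test_threshold_monotonicity():
    """Stricter SNP-count/length filters never report more segments, and a
    stricter window vote never flags more SNPs (it can split runs, so the
    segment count itself is not monotone in the vote threshold)."""
    rng = np.random.default_rng(9)
    g = random_panel(rng, n_ind=10, n_snps=400, het_rate=0.05, missing_rate=0.05)
    base = ROHScanParams(window_snps=25, min_snps=10, min_length_kb=100)
    n_base = len(detect_roh(g, base))
    for stricter in (
        ROHScanParams(window_snps=25, min_snps=40, min_length_kb=100),
        ROHScanParams(window_snps=25, min_snps=10, min_length_kb=2000),
    ):
        assert len(detect_roh(g, stricter)) <= n_base
    loose_flags = scan_windows(g.codes, base)
    strict = ROHScanParams(window_snps=25, window_hit_threshold=0.5)
    assert scan_windows(g.codes, strict).sum() <= loose_flags.sum()


def test_planted_tract_recovered_with_tight_endpoints():
    rng = np.random.default_rng(21)
    n_snps = 400
    codes = np.ones((1, n_snps), dtype=np.int8)  # heterozygous background
    tract = slice(150, 250)
    codes[0, tract] = 2
    positions = np.cumsum(rng.integers(10_000, 30_000, size=n_snps))
    g = make_panel(codes, positions=positions)
    params = ROHScanParams(min_snps=57)
    segs = detect_roh(g, params)
    assert len(segs) == 1
    window_bp = 50 * 30_000
    assert abs(segs[0].start_bp - positions[150]) <= window_bp
    assert abs(segs[0].end_bp - positions[249]) <= window_bp


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mb,label", [
    (1.02, "1-2 Mb"), (55.44, "> 16 Mb"), (4.16, "4-8 Mb"),
    (2.0, "2-4 Mb"), (15.999999, "8-16 Mb"), (16.0, "> 16 Mb"),
])
def test_classify_length(mb, label):
    assert classify_length(int(mb * 1e6)) == label


def test_classify_below_minimum_is_error():
    with pytest.raises(ValueError):
        classify_length(900_000)


def test_summarize_counts_and_percentages():
    from rohscan.roh import ROHSegment

    segs = [ROHSegment("a", "1", 1, 5_000_000, 80),
            ROHSegment("a", "2", 1, 1_500_000, 60),
            ROHSegment("b", "1", 1, 3_000_000, 70)]
    summary = summarize_roh(segs, ["a", "b", "c"])
    per_ind = summary.per_individual.set_index("id")
    assert per_ind.loc["a", "n_roh"] == 2
    assert per_ind.loc["a", "total_length_bp"] == 5_000_000 + 1_500_000
    assert per_ind.loc["c", "n_roh"] == 0
    per_class = summary.per_class.set_index("class")
    assert per_class.loc["4-8 Mb", "count"] == 1
    assert per_class.loc["1-2 Mb", "count"] == 1
    assert per_class.loc["2-4 Mb", "count"] == 1
    assert summary.per_class["percent"].sum() == pytest.approx(100.0)


def test_backsolve_heterozygosity_inverts_formula():
    h = backsolve_heterozygosity(0.05, 49_268, 2_288, 57)
    assert lencz_min_snps(0.05, 49_268, 2_288, h) == 57
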