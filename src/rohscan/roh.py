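"""Sliding-window detection of runs of homozygosity (ROH).

A run of homozygosity is a contiguous chromosomal stretch where an individual
is homozygous at every (or almost every) SNP, the signature of two haplotypes
inherited from a common ancestor. Detection follows the PLINK sliding-window
scheme: windows of ``window_snps`` consecutive SNPs are classed as homozygous
hits when they contain at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls; a SNP is flagged when the fraction of
hit windows covering it reaches ``window_hit_threshold``; maximal flagged runs
are split at large inter-SNP gaps and filtered on SNP count, physical length
and SNP density.

The minimum SNP count defaults to the false-positive-rate bound of Lencz et
al.: the smallest run length whose genome-wide expected count of chance
homozygous runs, given the panel size and mean heterozygosity, is below a
chosen alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

#: Length-class bin edges in Mb (half-open bins, last bin unbounded).
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", "> 16 Mb")


@dataclass
class ROHScanParams:
    """Scan parameters; defaults are the standard 50-SNP-window configuration.

    ``min_snps=None`` means "compute from the data with the Lencz formula at
    ``alpha``" (see :func:`lencz_min_snps`).
    """

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 1
    window_hit_threshold: float = 0.05
    min_length_kb: float = 1000.0
    min_snps: int | None = None
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if self.min_length_kb <= 0 or self.max_gap_kb <= 0 or self.max_density_kb_per_snp <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one individual (1-based inclusive bp interval)."""

    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def lencz_min_snps(alpha: float, n_snps_genotyped: int, n_individuals: int,
                   mean_heterozygosity: float) -> int:
    """Minimum SNPs per ROH controlling the expected false-positive count.

    ceil( ln(alpha / (n_a * n_s)) / ln(1 - het) ): the run length at which the
    expected number of chance all-homozygous stretches across the whole panel
    drops below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_snps_genotyped < 1 or n_individuals < 1:
        raise ValueError("counts must be >= 1")
    if not 0 < mean_heterozygosity < 1:
        raise ValueError("mean heterozygosity must be in (0, 1)")
    value = math.log(alpha / (n_individuals * n_snps_genotyped)) / math.log(
        1.0 - mean_heterozygosity)
    return int(math.ceil(value))


def backsolve_heterozygosity(alpha: float, n_snps_genotyped: int, n_individuals: int,
                             min_snps: int) -> float:
    """Mean heterozygosity at which the Lencz bound equals ``min_snps`` exactly."""
    return 1.0 - math.exp(math.log(alpha / (n_individuals * n_snps_genotyped)) / min_snps)


def mean_heterozygosity(g: GenotypeMatrix) -> float:
    """Proportion of heterozygous calls among all non-missing calls."""
    observed = g.codes != MISSING
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("all genotype calls missing")
    return float((g.codes == 1).sum() / n_obs)


def scan_windows(codes: np.ndarray, params: ROHScanParams) -> np.ndarray:
    """Per-SNP homozygous flags from the sliding-window vote.

    ``codes`` is (n_individuals, n_snps) for one chromosome. Only windows
    wholly inside the chromosome are enumerated, so chromosomes shorter than
    the window yield all-false flags. Returns a boolean array of the same
    shape.
    """
    codes = np.atleast_2d(codes)
    n_ind, n_snps = codes.shape
    w = params.window_snps
    flags = np.zeros((n_ind, n_snps), dtype=bool)
    if n_snps < w:
        return flags
    het = (codes == 1).astype(np.int32)
    mis = (codes == MISSING).astype(np.int32)
    # rolling window sums via cumulative sums along SNPs
    chet = np.concatenate([np.zeros((n_ind, 1), np.int32), het.cumsum(axis=1)], axis=1)
    cmis = np.concatenate([np.zeros((n_ind, 1), np.int32), mis.cumsum(axis=1)], axis=1)
    win_het = chet[:, w:] - chet[:, :-w]   # (n_ind, n_windows)
    win_mis = cmis[:, w:] - cmis[:, :-w]
    hit = ((win_het <= params.window_max_het)
           & (win_mis <= params.window_max_missing)).astype(np.int32)
    n_win = n_snps - w + 1
    chit = np.concatenate([np.zeros((n_ind, 1), np.int32), hit.cumsum(axis=1)], axis=1)
    idx = np.arange(n_snps)
    lo = np.maximum(0, idx - w + 1)          # first window covering SNP i
    hi = np.minimum(idx, n_win - 1)          # last window covering SNP i
    covering = hi - lo + 1
    hits_at = chit[:, hi + 1] - chit[:, lo]
    score = hits_at / covering
    return score >= params.window_hit_threshold


def assemble_segments(flags: np.ndarray, positions: np.ndarray,
                      params: ROHScanParams, min_snps: int,
                      individual: str, chrom: str) -> list[ROHSegment]:
    """Turn per-SNP flags on one chromosome into filtered ROH segments.

    Maximal flagged runs are split where adjacent flagged SNPs are more than
    ``max_gap_kb`` apart; each candidate must satisfy the SNP-count, length
    and density (length_kb / n_snps <= max_density_kb_per_snp) filters.
    """
    flags = np.asarray(flags, bool)
    positions = np.asarray(positions)
    segments: list[ROHSegment] = []
    if not flags.any():
        return segments
    bounded = np.concatenate([[False], flags, [False]]).astype(np.int8)
    d = np.diff(bounded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    max_gap_bp = params.max_gap_kb * 1000.0
    for s, e in zip(starts, ends):
        run_pos = positions[s:e]
        gaps = np.diff(run_pos)
        cut_points = np.flatnonzero(gaps > max_gap_bp) + 1
        for piece in np.split(np.arange(s, e), cut_points):
            n = len(piece)
            start_bp = int(positions[piece[0]])
            end_bp = int(positions[piece[-1]])
            length_kb = (end_bp - start_bp + 1) / 1000.0
            if n < min_snps:
                continue
            if length_kb < params.min_length_kb:
                continue
            if length_kb / n > params.max_density_kb_per_snp:
                continue
            segments.append(ROHSegment(individual, chrom, start_bp, end_bp, n))
    return segments


def resolve_min_snps(g: GenotypeMatrix, params: ROHScanParams) -> int:
    """The effective minimum-SNP filter: explicit value or the Lencz bound."""
    if params.min_snps is not None:
        return params.min_snps
    het = mean_heterozygosity(g)
    return lencz_min_snps(params.alpha, g.n_snps, g.n_individuals, het)


def detect_roh(g: GenotypeMatrix, params: ROHScanParams | None = None) -> list[ROHSegment]:
    """Detect ROH in every individual on every chromosome.

    Output is sorted by individual (input order), chromosome (map order),
    then start position; deterministic given its inputs.
    """
    params = params or ROHScanParams()
    min_snps = resolve_min_snps(g, params)
    segments: list[ROHSegment] = []
    chrom_col = g.snps.table["chrom"].to_numpy()
    pos_col = g.snps.table["pos"].to_numpy()
    for chrom in g.snps.chromosomes:
        mask = chrom_col == chrom
        codes = g.codes[:, mask]
        positions = pos_col[mask]
        flags = scan_windows(codes, params)
        for i, individual in enumerate(g.individuals):
            segments.extend(
                assemble_segments(flags[i], positions, params, min_snps, individual, chrom)
            )
    order = {ind: i for i, ind in enumerate(g.individuals)}
    chrom_order = {c: i for i, c in enumerate(g.snps.chromosomes)}
    segments.sort(key=lambda s: (order[s.individual], chrom_order[s.chrom], s.start_bp))
    return segments


def classify_length(length_bp: int) -> str:
    """Length-class label over [1,2), [2,4), [4,8), [8,16), [16, inf) Mb."""
    mb = length_bp / 1e6
    if mb < LENGTH_CLASS_EDGES_MB[0]:
        raise ValueError(f"length {mb:.3f} Mb below the 1 Mb scan minimum")
    for edge, label in zip(LENGTH_CLASS_EDGES_MB[1:], LENGTH_CLASS_LABELS):
        if mb < edge:
            return label
    return LENGTH_CLASS_LABELS[-1]


@dataclass
class ROHSummary:
    """Per-individual and per-length-class descriptive statistics."""

    per_individual: pd.DataFrame  # id, n_roh, total_length_bp, mean_length_bp
    per_class: pd.DataFrame       # class, count, percent, mean_length_mb


def summarize_roh(segments: list[ROHSegment], individuals: list[str]) -> ROHSummary:
    """Summaries over a segment list; zero rows kept for ROH-free individuals."""
    seg_df = segments_to_frame(segments)
    per_ind = (
        seg_df.groupby("individual")["length_bp"].agg(n_roh="size", total_length_bp="sum",
                                                      mean_length_bp="mean")
        .reindex(individuals).fillna(0)
        .rename_axis("id").reset_index()
    )
    per_ind["n_roh"] = per_ind["n_roh"].astype(int)
    if len(seg_df):
        labels = seg_df["length_bp"].map(classify_length)
        counts = labels.value_counts().reindex(LENGTH_CLASS_LABELS).fillna(0).astype(int)
        mean_mb = (seg_df.groupby(labels)["length_bp"].mean() / 1e6).reindex(LENGTH_CLASS_LABELS)
        per_class = pd.DataFrame({
            "class": LENGTH_CLASS_LABELS,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(seg_df),
            "mean_length_mb": mean_mb.to_numpy(),
        })
    else:
        per_class = pd.DataFrame({"class": LENGTH_CLASS_LABELS, "count": 0,
                                  "percent": 0.0, "mean_length_mb": np.nan})
    return ROHSummary(per_ind, per_class)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment list as a .hom-style table (one row per segment)."""
    return pd.DataFrame(
        [(s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp)
         for s in segments],
        columns=["individual", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    return [ROHSegment(str(r.individual), str(r.chrom), int(r.start_bp),
                       int(r.end_bp), int(r.n_snps))
            for r in df.itertuples()]
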