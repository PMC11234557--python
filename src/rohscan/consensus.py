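"""Pooling of individual ROH into consensus regions and island selection.

Overlapping ROH segments from different individuals are grouped per
chromosome; the consensus region of a group is the interval common to every
member (max of starts to min of ends). Groups whose members do not all share
an interval are split greedily so every reported pool has a non-empty
consensus. Pools are then filtered to the association set (carrier frequency
strictly above 5% and at least five SNPs inside the consensus) and the island
set (frequency strictly above 80%), the latter marking putative selection
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genotype_io import SNPMap
from .roh import ROHSegment


@dataclass
class ROHPool:
    """A group of overlapping ROH segments sharing a consensus interval."""

    chrom: str
    members: list[ROHSegment]
    consensus_start_bp: int
    consensus_end_bp: int
    carrier_count: int
    frequency: float

    @property
    def carriers(self) -> list[str]:
        return sorted({m.individual for m in self.members})


@dataclass(frozen=True)
class ConsensusROH:
    """A selected consensus region, labelled for use as a fixed-effect name."""

    chrom: str
    start_bp: int
    end_bp: int
    frequency: float
    n_snps: int
    label: str
    carriers: tuple

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def _split_component(members: list[ROHSegment]) -> list[list[ROHSegment]]:
    """Split a linkage component into pools with non-empty consensus.

    Seed with the longest member, then add members in (start, end) order while
    the running intersection stays non-empty; recurse on the rest.
    """
    start = max(m.start_bp for m in members)
    end = min(m.end_bp for m in members)
    if start <= end:
        return [members]
    seed = max(members, key=lambda m: (m.length_bp, -m.start_bp))
    pool = [seed]
    cur_start, cur_end = seed.start_bp, seed.end_bp
    rest: list[ROHSegment] = []
    for m in sorted(members, key=lambda m: (m.start_bp, m.end_bp, m.individual)):
        if m is seed:
            continue
        if _overlaps(cur_start, cur_end, m.start_bp, m.end_bp):
            pool.append(m)
            cur_start = max(cur_start, m.start_bp)
            cur_end = min(cur_end, m.end_bp)
        else:
            rest.append(m)
    result = [pool]
    if rest:
        result.extend(_split_component(rest))
    return result


def pool_segments(segments: list[ROHSegment], n_individuals_total: int) -> list[ROHPool]:
    """Pool overlapping segments per chromosome (single-linkage) into consensus groups.

    Carrier frequency is the number of distinct individuals in the pool over
    ``n_individuals_total`` (all genotyped individuals surviving QC).
    """
    if n_individuals_total < 1:
        raise ValueError("n_individuals_total must be >= 1")
    pools: list[ROHPool] = []
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in by_chrom:
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp, s.individual))
        # single-linkage components: running max end while sweeping sorted starts
        component: list[ROHSegment] = []
        reach = -1
        components: list[list[ROHSegment]] = []
        for seg in segs:
            if component and seg.start_bp > reach:
                components.append(component)
                component = []
                reach = -1
            component.append(seg)
            reach = max(reach, seg.end_bp)
        if component:
            components.append(component)
        for comp in components:
            for pool_members in _split_component(comp):
                start = max(m.start_bp for m in pool_members)
                end = min(m.end_bp for m in pool_members)
                carriers = {m.individual for m in pool_members}
                pools.append(ROHPool(
                    chrom=chrom, members=pool_members,
                    consensus_start_bp=start, consensus_end_bp=end,
                    carrier_count=len(carriers),
                    frequency=len(carriers) / n_individuals_total,
                ))
    pools.sort(key=lambda p: (p.chrom, p.consensus_start_bp))
    return pools


def count_snps_in_interval(snp_map: SNPMap, chrom: str, start_bp: int, end_bp: int) -> int:
    """Number of mapped SNPs inside [start_bp, end_bp], endpoints inclusive."""
    t = snp_map.table
    on = t["chrom"] == chrom
    pos = t.loc[on, "pos"]
    return int(((pos >= start_bp) & (pos <= end_bp)).sum())


def select_consensus(pools: list[ROHPool], snp_map: SNPMap,
                     min_snps: int = 5, min_freq: float = 0.05) -> list[ConsensusROH]:
    """Association set: frequency strictly > min_freq and >= min_snps SNPs.

    Labels are stable ``chr:start-end`` strings, reused downstream as fixed
    effect names.
    """
    out: list[ConsensusROH] = []
    for pool in pools:
        if pool.frequency <= min_freq:
            continue
        n = count_snps_in_interval(snp_map, pool.chrom,
                                   pool.consensus_start_bp, pool.consensus_end_bp)
        if n < min_snps:
            continue
        out.append(ConsensusROH(
            chrom=pool.chrom, start_bp=pool.consensus_start_bp,
            end_bp=pool.consensus_end_bp, frequency=pool.frequency, n_snps=n,
            label=f"{pool.chrom}:{pool.consensus_start_bp}-{pool.consensus_end_bp}",
            carriers=tuple(pool.carriers),
        ))
    return out


def select_islands(consensus_list: list[ConsensusROH],
                   island_freq: float = 0.80) -> list[ConsensusROH]:
    """Islands: consensus regions with frequency strictly above ``island_freq``,
    sorted by frequency descending."""
    islands = [c for c in consensus_list if c.frequency > island_freq]
    islands.sort(key=lambda c: (-c.frequency, c.chrom, c.start_bp))
    return islands


def consensus_to_frame(regions: list[ConsensusROH]) -> pd.DataFrame:
    """Table shaped like the standard island report (Chr, Start, End, ...)."""
    return pd.DataFrame(
        [(c.chrom, c.start_bp, c.end_bp, c.length_bp, 100.0 * c.frequency,
          c.n_snps, c.label) for c in regions],
        columns=["chrom", "start_bp", "end_bp", "length_bp", "frequency_pct",
                 "n_snps", "label"],
    )


def write_bed(regions: list[ConsensusROH], path) -> None:
    """Export consensus intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in regions:
            fh.write(f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t{c.label}\n")


def carrier_matrix(consensus_list: list[ConsensusROH],
                   individuals: list[str]) -> pd.DataFrame:
    """0/1 indicator frame (individuals x consensus labels): carries a member
    segment of that pool or not."""
    data = {c.label: [1 if ind in set(c.carriers) else 0 for ind in individuals]
            for c in consensus_list}
    return pd.DataFrame(data, index=pd.Index(individuals, name="id"))
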