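"""Gene-overlap annotation of consensus ROH intervals.

Loads gene records from GFF3 (kept 1-based inclusive) or BED (converted from
0-based half-open), and intersects them with region intervals; two intervals
overlap when they share at least one base pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusROH

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: 1-based inclusive coordinates after import."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _gff3_attribute(attrs: str, keys=("Name", "gene_name", "ID", "gene_id")) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return attrs.strip()


def load_annotation(path, fmt: str) -> list[GeneRecord]:
    """Load gene records from a ``"gff3"`` or ``"bed"`` file.

    Only ``gene``-type GFF3 features are kept; BED start coordinates are
    shifted +1 into the 1-based inclusive convention (logged).
    """
    genes: list[GeneRecord] = []
    if fmt == "gff3":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9 or cols[2] != "gene":
                    continue
                genes.append(GeneRecord(
                    gene_id=_gff3_attribute(cols[8]), chrom=cols[0],
                    start_bp=int(cols[3]), end_bp=int(cols[4]), strand=cols[6],
                ))
    elif fmt == "bed":
        log.info("BED input: converting 0-based half-open to 1-based inclusive")
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split()
                name = cols[3] if len(cols) > 3 else f"{cols[0]}:{cols[1]}-{cols[2]}"
                strand = cols[5] if len(cols) > 5 else "."
                genes.append(GeneRecord(
                    gene_id=name, chrom=cols[0],
                    start_bp=int(cols[1]) + 1, end_bp=int(cols[2]), strand=strand,
                ))
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected 'gff3' or 'bed')")
    if not genes:
        warnings.warn(f"no gene records found in {path}", stacklevel=2)
    return genes


def intersect_genes(regions: list[ConsensusROH],
                    genes: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Map each region label to the genes sharing >= 1 bp with it.

    Genes per region are returned in gene-start order; regions with no
    overlapping gene map to an empty list. A complete chromosome-name
    mismatch between the two inputs raises a diagnostic error.
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        raise ValueError(
            "no shared chromosome names between regions and annotation: "
            f"regions use {sorted(region_chroms)}, annotation uses {sorted(gene_chroms)}"
        )
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, list[GeneRecord]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.start_bp, g.end_bp, g.gene_id))
        by_chrom[chrom] = glist
    for region in regions:
        glist = by_chrom.get(region.chrom, [])
        if not glist:
            out[region.label] = []
            continue
        starts = np.array([g.start_bp for g in glist])
        # genes starting after the region end cannot overlap; scan the rest
        hi = int(np.searchsorted(starts, region.end_bp, side="right"))
        out[region.label] = [
            g for g in glist[:hi] if g.end_bp >= region.start_bp
        ]
    return out


def annotation_table(regions: list[ConsensusROH],
                     genes: list[GeneRecord]) -> pd.DataFrame:
    """Island-report table: Chr, Start, End, Length, Frequency, SNPs, genes."""
    overlaps = intersect_genes(regions, genes)
    rows = []
    for r in regions:
        names = "; ".join(g.gene_id for g in overlaps[r.label]) or "-"
        rows.append((r.chrom, r.start_bp, r.end_bp, r.length_bp,
                     round(100.0 * r.frequency, 2), r.n_snps, names))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "length_bp",
                                       "frequency_pct", "n_snps", "annotated_genes"])
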