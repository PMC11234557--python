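"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible — nested loops, explicit
enumeration — and shares no code path with the package implementations it
checks.
"""

from __future__ import annotations

import math

MISSING = -1


# ---------------------------------------------------------------------------
# HWE exact test by full enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p-value by enumerating every heterozygote count outcome.

    Conditional on allele counts, P(het = h) is proportional to
    2^h / (hom_rare! * h! * hom_common!); the two-sided p sums outcomes no
    more probable than the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    probs = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp = (h * math.log(2.0) - math.lgamma(hom_r + 1)
                - math.lgamma(h + 1) - math.lgamma(hom_c + 1))
        probs[h] = logp
    mx = max(probs.values())
    dens = {h: math.exp(lp - mx) for h, lp in probs.items()}
    total = sum(dens.values())
    p_obs = dens[n_het] / total
    return min(1.0, sum(d / total for d in dens.values()
                        if d / total <= p_obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# ROH caller, brute force
# ---------------------------------------------------------------------------

def roh_brute_force(codes_row, positions, *, window_snps=50, window_max_het=1,
                    window_max_missing=1, window_hit_threshold=0.05,
                    min_length_kb=1000.0, min_snps=1,
                    max_density_kb_per_snp=50.0, max_gap_kb=1000.0):
    """Segments for one individual on one chromosome, by explicit enumeration.

    Returns a list of (start_bp, end_bp, n_snps) tuples.
    """
    codes = list(codes_row)
    n = len(codes)
    w = window_snps
    flags = [False] * n
    if n >= w:
        hits = []
        for s in range(n - w + 1):
            window = codes[s:s + w]
            hits.append(window.count(1) <= window_max_het
                        and window.count(MISSING) <= window_max_missing)
        for i in range(n):
            covering = [hits[s] for s in range(max(0, i - w + 1),
                                               min(i, n - w) + 1)]
            if sum(covering) / len(covering) >= window_hit_threshold:
                flags[i] = True
    # runs of flagged SNPs
    segments = []
    run = []
    for i in range(n + 1):
        if i < n and flags[i]:
            run.append(i)
        else:
            if run:
                # split at big gaps
                pieces = [[run[0]]]
                for a, b in zip(run, run[1:]):
                    if positions[b] - positions[a] > max_gap_kb * 1000.0:
                        pieces.append([])
                    pieces[-1].append(b)
                for piece in pieces:
                    start = positions[piece[0]]
                    end = positions[piece[-1]]
                    length_kb = (end - start + 1) / 1000.0
                    if (len(piece) >= min_snps and length_kb >= min_length_kb
                            and length_kb / len(piece) <= max_density_kb_per_snp):
                        segments.append((int(start), int(end), len(piece)))
            run = []
    return segments


# ---------------------------------------------------------------------------
# Interval intersection, all pairs
# ---------------------------------------------------------------------------

def intersect_all_pairs(regions, genes):
    """regions/genes: lists of (name, chrom, start, end); returns
    {region name: [gene names in start order]} with >=1 bp shared."""
    out = {}
    for rname, rchrom, rstart, rend in regions:
        found = []
        for gname, gchrom, gstart, gend in genes:
            if gchrom == rchrom and gstart <= rend and rstart <= gend:
                found.append((gstart, gend, gname))
        out[rname] = [name for _, _, name in sorted(found)]
    return out
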