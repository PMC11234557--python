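"""Synthetic genotype/phenotype generator with planted ROH structure.

Emulates a mink-style SNP-array study at desk scale: a set of autosomes with
roughly evenly spaced SNPs, background genotypes drawn independently per SNP
under Hardy-Weinberg proportions, and *planted tracts* — identical homozygous
haplotypes written over a chosen fraction of individuals — standing in for
autozygous segments shared through a common ancestor. Phenotypes are drawn
from the same animal model the association stage fits (polygenic effect with
GRM covariance, management fixed effects, age covariate, tract effects), so
every pipeline stage can be tested against known truth.

The default preset is desk-scale (300 individuals, 14 autosomes x 500 SNPs at
~25 kb spacing); a paper-scale preset (2,288 x 49,268) exists behind an
explicit constructor for scale tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, PhenotypeSchema,
                          PhenotypeTable, SNPMap)
from .grm import stabilize, vanraden_grm


@dataclass(frozen=True)
class PlantedTract:
    """A homozygous tract written into a fraction of individuals."""

    name: str
    chrom: str
    start_bp: int
    length_bp: int
    carrier_fraction: float

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length_bp - 1


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: tract effects in phenotypic SD units, h2, and
    fixed-effect magnitudes."""

    name: str
    tract_effects: dict = field(default_factory=dict)  # tract name -> effect (SD units)
    h2: float = 0.4
    fixed_effect_sd: float = 0.25  # SD of factor-level effects, phenotypic-SD units
    age_slope: float = 0.01       # per day, phenotypic-SD units


@dataclass
class SimSpec:
    """Simulation layout; defaults are the desk-scale study conditions."""

    n_individuals: int = 300
    family_size: int = 5  # full-sib family size; 1 = unrelated individuals
    n_chromosomes: int = 14
    snps_per_chromosome: int = 500
    mean_spacing_bp: int = 25_000
    maf_range: tuple = (0.1, 0.9)
    tract_allele_freq_range: tuple = (0.75, 0.90)
    missing_rate: float = 0.002
    tracts: list = field(default_factory=list)
    traits: list = field(default_factory=list)
    seed: int = 17

    def __post_init__(self) -> None:
        for t in self.tracts:
            if not 0 < t.carrier_fraction <= 1:
                raise ValueError(f"tract {t.name}: carrier_fraction outside (0, 1]")
        for t in self.traits:
            if not 0 <= t.h2 < 1:
                raise ValueError(f"trait {t.name}: h2 must be in [0, 1)")

    @property
    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


def paper_scale_spec(seed: int = 17) -> SimSpec:
    """Full-study-scale layout: 2,288 individuals x 49,268 SNPs on 14 autosomes."""
    return SimSpec(n_individuals=2288, n_chromosomes=14,
                   snps_per_chromosome=3519,  # 14 x 3519 = 49,266 + 2 on chr 1
                   mean_spacing_bp=49_000, seed=seed)


def default_island_spec(seed: int = 17) -> SimSpec:
    """Desk-scale preset with three high-frequency islands, two mid-frequency
    consensus tracts, and three traits each affected by one island."""
    tracts = [
        PlantedTract("island_A", "2", 2_000_000, 2_500_000, 0.85),
        PlantedTract("island_B", "5", 5_000_000, 3_000_000, 0.90),
        PlantedTract("island_C", "9", 1_500_000, 2_200_000, 0.95),
        PlantedTract("bg_D", "3", 4_000_000, 2_000_000, 0.30),
        PlantedTract("bg_E", "7", 6_000_000, 2_400_000, 0.50),
    ]
    traits = [
        TraitSpec("FBW", {"island_A": 1.0}),
        TraitSpec("ADG", {"island_B": 1.0}),
        TraitSpec("RFI", {"island_C": -1.0}),
    ]
    return SimSpec(tracts=tracts, traits=traits, seed=seed)


def chrom_starts(table: pd.DataFrame) -> list[int]:
    """Index of the first SNP of each chromosome (map order)."""
    chroms = table["chrom"].to_numpy()
    return [0] + list(np.flatnonzero(chroms[1:] != chroms[:-1]) + 1)


def _family_genotypes(rng, freqs, starts, n_individuals, family_size):
    """Full-sib families: two HWE parents per family, sibs inherit one whole
    parental haplotype per chromosome from each parent."""
    m = freqs.size
    bounds = starts + [m]
    rows = []
    while len(rows) < n_individuals:
        parents = rng.random((2, 2, m)) < freqs  # (parent, haplotype, snp)
        n_sibs = min(family_size, n_individuals - len(rows))
        for _ in range(n_sibs):
            child = np.zeros(m, dtype=np.int8)
            for lo, hi in zip(bounds, bounds[1:]):
                pick = rng.integers(0, 2, size=2)
                child[lo:hi] = (parents[0, pick[0], lo:hi].astype(np.int8)
                                + parents[1, pick[1], lo:hi])
            rows.append(child)
    return np.vstack(rows)


@dataclass
class TruthTable:
    """Ground truth recorded while simulating."""

    tract_intervals: dict      # tract name -> (chrom, start_bp, end_bp)
    tract_carriers: dict       # tract name -> sorted list of individual ids
    trait_effects: dict        # trait name -> {tract name: effect in SD units}
    trait_h2: dict             # trait name -> h2
    fixed_effects: dict        # trait name -> {column: coefficient}
    phenotypic_sd: dict        # trait name -> target SD of u + e


def simulate_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate the genotype panel and plant the homozygous tracts.

    Individuals come in full-sib families of ``family_size``: each family
    draws two unrelated parents from Hardy-Weinberg proportions at per-SNP
    frequencies p_k ~ Uniform over ``maf_range``, and every sib inherits one
    whole parental haplotype per chromosome from each parent (no
    recombination). This gives the genomic relationship matrix the
    within-family block structure of a farmed population, which is what makes
    the polygenic/residual variance split identifiable downstream; with
    ``family_size=1`` genotypes are plain HWE draws. A planted tract
    overwrites its carriers
    with one shared homozygous haplotype (two copies of the counted allele at
    every tract SNP); carriers are sampled without replacement. Inside a
    tract the background allele frequency of the planted allele is drawn high
    (``tract_allele_freq_range``), mimicking a selective sweep: carriers are
    then homozygous for alleles that are common in the whole population, so
    tract SNPs remain compatible with Hardy-Weinberg screening, while
    non-carriers still segregate and are not called as ROH. Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    individuals = [f"ind{i + 1:04d}" for i in range(spec.n_individuals)]
    rows = []
    for chrom in spec.chromosome_names:
        spacing = rng.integers(max(1, spec.mean_spacing_bp // 2),
                               spec.mean_spacing_bp * 3 // 2,
                               size=spec.snps_per_chromosome)
        pos = 1 + np.cumsum(spacing)
        for j, p in enumerate(pos):
            rows.append((f"chr{chrom}_snp{j + 1}", chrom, int(p)))
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    table["a1"] = "A"
    table["a2"] = "B"
    snp_map = SNPMap(table)
    m = len(table)
    freqs = rng.uniform(*spec.maf_range, size=m)

    chrom_col = table["chrom"].to_numpy()
    pos_col = table["pos"].to_numpy()
    tract_masks: list[np.ndarray] = []
    for tract in spec.tracts:
        in_tract = ((chrom_col == tract.chrom)
                    & (pos_col >= tract.start_bp) & (pos_col <= tract.end_bp))
        tract_masks.append(in_tract)
        # swept region: the planted allele is common in the whole population
        freqs[in_tract] = rng.uniform(*spec.tract_allele_freq_range,
                                      size=int(in_tract.sum()))
    if spec.family_size <= 1:
        codes = rng.binomial(2, freqs, size=(spec.n_individuals, m)).astype(np.int8)
    else:
        codes = _family_genotypes(rng, freqs, chrom_starts(table),
                                  spec.n_individuals, spec.family_size)

    tract_carriers: dict[str, list[str]] = {}
    tract_intervals: dict[str, tuple] = {}
    for tract, in_tract in zip(spec.tracts, tract_masks):
        n_in = int(in_tract.sum())
        if n_in < 5:
            import warnings

            warnings.warn(f"tract {tract.name} covers only {n_in} SNPs; it will "
                          "fail the consensus minimum-SNP filter", stacklevel=2)
        n_carriers = max(1, round(tract.carrier_fraction * spec.n_individuals))
        carrier_idx = rng.choice(spec.n_individuals, size=n_carriers, replace=False)
        codes[np.ix_(np.sort(carrier_idx), np.flatnonzero(in_tract))] = 2
        tract_carriers[tract.name] = sorted(individuals[i] for i in carrier_idx)
        tract_intervals[tract.name] = (tract.chrom, tract.start_bp, tract.end_bp)

    if spec.missing_rate > 0:
        miss = rng.random(codes.shape) < spec.missing_rate
        codes[miss] = MISSING

    truth = TruthTable(tract_intervals=tract_intervals, tract_carriers=tract_carriers,
                       trait_effects={}, trait_h2={}, fixed_effects={},
                       phenotypic_sd={})
    return GenotypeMatrix(individuals, snp_map, codes), truth


def simulate_phenotypes(g: GenotypeMatrix, truth: TruthTable, spec: SimSpec,
                        schema: PhenotypeSchema | None = None) -> PhenotypeTable:
    """Draw traits from the animal model with the planted tract effects.

    u ~ N(0, sigma2_u G) with G the VanRaden GRM of the simulated panel
    (identity-blended if singular), e iid normal, fixed-effect levels assigned
    uniformly from the declared level sets, age uniform on the declared range.
    Unit phenotypic variance: sigma2_u = h2, sigma2_e = 1 - h2, so tract
    effects are in phenotypic-SD units. Truth is recorded in place.
    """
    schema = schema or PhenotypeSchema()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7_919]))
    n = g.n_individuals
    df = pd.DataFrame({"id": g.individuals})
    for factor, levels in schema.factor_levels.items():
        df[factor] = rng.choice([str(x) for x in levels], size=n)
        df[factor] = pd.Categorical(df[factor], categories=[str(x) for x in levels])
    lo, hi = schema.age_range
    df["age_days"] = rng.integers(lo, hi + 1, size=n)

    gm, _ = stabilize(vanraden_grm(g))
    chol = np.linalg.cholesky(
        gm.values + 1e-10 * np.eye(n))

    carrier_sets = {name: set(ids) for name, ids in truth.tract_carriers.items()}
    for tspec in spec.traits:
        if tspec.h2 >= 1:
            raise ValueError("h2 = 1 leaves no residual variance")
        sigma_u = np.sqrt(tspec.h2)
        sigma_e = np.sqrt(1.0 - tspec.h2)
        u = sigma_u * (chol @ rng.standard_normal(n))
        e = sigma_e * rng.standard_normal(n)
        y = u + e
        fixed: dict[str, float] = {}
        for factor, levels in schema.factor_levels.items():
            levels = [str(x) for x in levels]
            coefs = dict(zip(levels, np.concatenate(
                [[0.0], rng.normal(0.0, tspec.fixed_effect_sd, size=len(levels) - 1)])))
            y = y + df[factor].astype(str).map(coefs).to_numpy(float)
            fixed.update({f"{factor}[{lv}]": c for lv, c in coefs.items() if lv != levels[0]})
        y = y + tspec.age_slope * (df["age_days"].to_numpy(float) - (lo + hi) / 2.0)
        fixed["age_days"] = tspec.age_slope
        for tract_name, effect in tspec.tract_effects.items():
            carrier = df["id"].isin(carrier_sets[tract_name]).to_numpy(float)
            y = y + effect * carrier
        df[tspec.name] = y
        truth.trait_effects[tspec.name] = dict(tspec.tract_effects)
        truth.trait_h2[tspec.name] = tspec.h2
        truth.fixed_effects[tspec.name] = fixed
        truth.phenotypic_sd[tspec.name] = 1.0

    # schema with only the simulated traits declared
    sim_schema = PhenotypeSchema(factor_levels=schema.factor_levels,
                                 covariates=schema.covariates,
                                 age_range=schema.age_range,
                                 traits=tuple(t.name for t in spec.traits))
    return PhenotypeTable(df, sim_schema)


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    """Planted-tract truth as a flat table (one row per tract)."""
    rows = []
    for name, (chrom, start, end) in truth.tract_intervals.items():
        rows.append((name, chrom, start, end, len(truth.tract_carriers[name])))
    return pd.DataFrame(rows, columns=["tract", "chrom", "start_bp", "end_bp",
                                       "n_carriers"])


def write_toy_gff3(g: GenotypeMatrix, truth: TruthTable, path,
                   genes_per_tract: int = 1, seed: int = 0) -> None:
    """Emit a small synthetic GFF3 with genes placed on and off the planted
    tracts, for exercising the annotation stage."""
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    k = 0
    for name, (chrom, start, end) in truth.tract_intervals.items():
        for _ in range(genes_per_tract):
            k += 1
            g_start = int(rng.integers(start, max(start + 1, end - 10_000)))
            g_end = min(end, g_start + int(rng.integers(5_000, 50_000)))
            lines.append(f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t+\t."
                         f"\tID=gene{k};Name=GENE_{name.upper()}")
    # off-tract decoys
    pos = g.snps.table.groupby("chrom")["pos"].max()
    for chrom, chrom_max in pos.items():
        k += 1
        g_start = int(chrom_max) + 100_000
        lines.append(f"{chrom}\tsim\tgene\t{g_start}\t{g_start + 20_000}\t.\t-\t."
                     f"\tID=gene{k};Name=DECOY_{chrom}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
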