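"""Reading, writing and quality control of SNP-array genotype panels.

Genotypes are held as allele counts of a designated *counted allele* per SNP:
0, 1 or 2 copies, with ``MISSING`` (-1) as a distinct fourth state. The module
speaks PLINK text (PED/MAP) and binary (BED/BIM/FAM, SNP-major v1.00), applies
the standard array-QC filters (sex-chromosome removal, per-individual and
per-SNP call rate, Hardy-Weinberg exact test), and reads phenotype tables with
declared factor level sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel code for a missing genotype call. Never a valid allele count.
MISSING: int = -1

#: Chromosome labels treated as sex chromosomes / non-autosomal by default.
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "23", "24", "25", "26"})


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates its format contract."""


@dataclass
class SNPMap:
    """Marker map: one row per SNP with chromosome, id, bp position and alleles.

    ``a1`` is the counted allele (genotype codes count its copies), ``a2`` the
    other allele. Positions must be strictly increasing within a chromosome.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos, a1, a2

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "a1", "a2"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"SNP map missing columns {required - set(self.table.columns)}")
        if self.table["snp_id"].duplicated().any():
            dup = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count codes with missing state.

    ``codes`` is an int8 array of shape (n_individuals, n_snps) over
    {0, 1, 2, MISSING}; row order follows ``individuals``, column order the
    SNP map.
    """

    individuals: list[str]
    snps: SNPMap
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.individuals)}, {len(self.snps)})"
            )
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.codes[~valid].flat[0]
            raise ValueError(f"invalid genotype code {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to masked individuals and/or SNPs."""
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        individuals = [s for s, keep in zip(self.individuals, ind_mask) if keep]
        snps = SNPMap(self.snps.table.loc[snp_mask].reset_index(drop=True))
        return GenotypeMatrix(individuals, snps, self.codes[np.ix_(ind_mask, snp_mask)])


@dataclass
class QCParams:
    """Quality-control thresholds.

    Defaults follow common array practice: retain SNPs with call rate >= 0.95,
    individuals with call rate > 0.90, and SNPs whose HWE exact p >= 1e-6;
    sex-chromosome SNPs are dropped first.
    """

    min_snp_call_rate: float = 0.95
    min_individual_call_rate: float = 0.90
    hwe_p_threshold: float = 1e-6
    drop_sex_chromosomes: bool = True
    sex_chromosome_labels: frozenset = SEX_CHROMOSOMES

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_individual_call_rate", "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts removed at each QC step, in application order."""

    n_snps_in: int = 0
    n_individuals_in: int = 0
    sex_chrom_snps_removed: int = 0
    individuals_removed: int = 0
    low_call_snps_removed: int = 0
    hwe_snps_removed: int = 0
    n_snps_out: int = 0
    n_individuals_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": ["input", "sex_chromosomes", "individual_call_rate",
                      "snp_call_rate", "hwe", "output"],
             "snps_removed": [0, self.sex_chrom_snps_removed, 0,
                              self.low_call_snps_removed, self.hwe_snps_removed, 0],
             "individuals_removed": [0, 0, self.individuals_removed, 0, 0, 0]}
        )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    The counted allele of each SNP is the first non-missing allele observed in
    file order; "0 0" allele pairs become :data:`MISSING`.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    individuals: list[str] = []
    a1 = np.array([""] * n_snps, dtype=object)
    a2 = np.array([""] * n_snps, dtype=object)
    code_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            individuals.append(parts[1])
            alleles = parts[6:]
            row = np.empty(n_snps, dtype=np.int8)
            for k in range(n_snps):
                x, y = alleles[2 * k], alleles[2 * k + 1]
                if x == "0" or y == "0":
                    row[k] = MISSING
                    continue
                for al in (x, y):
                    if a1[k] == "":
                        a1[k] = al
                    elif a2[k] == "" and al != a1[k]:
                        a2[k] = al
                row[k] = (x == a1[k]) + (y == a1[k])
            code_rows.append(row)
    if not code_rows:
        raise PlinkFormatError(f"{ped_path}: no individuals")
    a2[a2 == ""] = "0"  # monomorphic: unknown other allele
    snp_ids = [r[1] for r in map_rows]
    table = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": [r[0] for r in map_rows],
         "pos": [r[2] for r in map_rows], "a1": a1, "a2": a2}
    )
    return GenotypeMatrix(individuals, SNPMap(table), np.vstack(code_rows))


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; inverse of :func:`read_plink_text` up to allele naming."""
    t = g.snps.table
    with open(map_path, "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    a1 = t["a1"].to_numpy()
    a2 = t["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(g.individuals):
            fields = [f"FAM{i + 1}", iid, "0", "0", "0", "-9"]
            for k, c in enumerate(g.codes[i]):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [a1[k], a1[k]]
                elif c == 1:
                    fields += [a1[k], a2[k]]
                else:
                    fields += [a2[k], a2[k]]
            fh.write(" ".join(fields) + "\n")


def align_counted_alleles(g: GenotypeMatrix, reference: GenotypeMatrix) -> GenotypeMatrix:
    """Re-orient ``g`` so each SNP counts the same allele as ``reference``.

    Readers may designate different counted alleles (the text reader uses the
    first allele observed); flipping a SNP maps code c -> 2 - c and swaps the
    allele pair, leaving MISSING untouched.
    """
    if list(g.snps.table["snp_id"]) != list(reference.snps.table["snp_id"]):
        raise ValueError("SNP sets differ; cannot align")
    codes = g.codes.copy()
    table = g.snps.table.copy()
    flip = (table["a1"].to_numpy() != reference.snps.table["a1"].to_numpy())
    for k in np.flatnonzero(flip):
        col = codes[:, k]
        observed = col != MISSING
        col[observed] = 2 - col[observed]
        table.loc[k, ["a1", "a2"]] = [reference.snps.table["a1"].iloc[k],
                                      reference.snps.table["a2"].iloc[k]]
    return GenotypeMatrix(list(g.individuals), SNPMap(table), codes)


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM), SNP-major v1.00
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes in a SNP-major .bed byte, LSB first:
#   00 hom a1 (2 copies of allele1), 01 missing, 10 het, 11 hom a2.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read BED/BIM/FAM. Only SNP-major (mode byte 0x01) files are supported.

    BIM allele 1 is taken as the counted allele, matching PLINK's convention
    that the .bed 2-bit code counts A1 copies.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, usecols=[0, 1],
                      names=["fid", "iid"], dtype=str)
    n_ind, n_snps = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != b"\x01":
        raise PlinkFormatError(f"{bed_path}: individual-major bed files are unsupported")
    bytes_per_snp = (n_ind + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"{bed_path}: payload is {payload.size} bytes, "
            f"expected {bytes_per_snp * n_snps} for {n_ind} x {n_snps}"
        )
    blocks = payload.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, LSB first within each byte
    pairs = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = _BED_DECODE[pairs.reshape(n_snps, -1)[:, :n_ind]].T
    table = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(list(fam["iid"]), SNPMap(table), np.ascontiguousarray(codes))


def write_plink_binary(g: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    """Write SNP-major BED/BIM/FAM."""
    t = g.snps.table
    with open(bim_path, "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(fam_path, "w") as fh:
        for i, iid in enumerate(g.individuals):
            fh.write(f"FAM{i + 1} {iid} 0 0 0 -9\n")
    n_ind = g.n_individuals
    bytes_per_snp = (n_ind + 3) // 4
    enc = np.zeros((g.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        lut[code % 4] = bits  # MISSING=-1 -> index 3
    enc[:, :n_ind] = lut[g.codes.T % 4]
    packed = (enc.reshape(g.n_snps, bytes_per_snp, 4)
              * np.array([1, 4, 16, 64], dtype=np.uint8)).sum(axis=2, dtype=np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (the Wigginton et al. formulation, PLINK's default,
    without the mid-p adjustment).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no individuals")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log unnormalised probability of each het count (hypergeometric-type kernel)
    from scipy.special import gammaln

    hom_r = (n_rare - het_values) // 2
    hom_c = n - het_values - hom_r
    logp = (het_values * np.log(2)
            - gammaln(hom_r + 1) - gammaln(het_values + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[het_values == n_het][0]
    # small tolerance so ties at equal probability are counted (floating point)
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def apply_qc(g: GenotypeMatrix, params: QCParams | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filters in a fixed, logged order.

    1. drop sex-chromosome SNPs; 2. drop individuals with call rate <= the
    individual threshold; 3. drop SNPs with call rate < the SNP threshold;
    4. drop SNPs with HWE exact p below the threshold.
    """
    params = params or QCParams()
    report = QCReport(n_snps_in=g.n_snps, n_individuals_in=g.n_individuals)

    if params.drop_sex_chromosomes:
        autosomal = ~g.snps.table["chrom"].isin(params.sex_chromosome_labels).to_numpy()
        report.sex_chrom_snps_removed = int((~autosomal).sum())
        g = g.subset(snp_mask=autosomal)

    observed = g.codes != MISSING
    if g.n_snps:
        ind_rate = observed.mean(axis=1)
        keep_ind = ind_rate > params.min_individual_call_rate
        report.individuals_removed = int((~keep_ind).sum())
        g = g.subset(ind_mask=keep_ind)
        observed = observed[keep_ind]

    if g.n_individuals and g.n_snps:
        snp_rate = observed.mean(axis=0)
        keep_snp = snp_rate >= params.min_snp_call_rate
        report.low_call_snps_removed = int((~keep_snp).sum())
        g = g.subset(snp_mask=keep_snp)

    if g.n_individuals and g.n_snps:
        keep = np.ones(g.n_snps, bool)
        for k in range(g.n_snps):
            col = g.codes[:, k]
            n2 = int((col == 2).sum())
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            if n2 + n1 + n0 == 0:
                continue
            if hwe_exact_test(n2, n1, n0) < params.hwe_p_threshold:
                keep[k] = False
        report.hwe_snps_removed = int((~keep).sum())
        g = g.subset(snp_mask=keep)

    if g.n_snps == 0 or g.n_individuals == 0:
        raise ValueError("QC removed all SNPs or all individuals")
    report.n_snps_out = g.n_snps
    report.n_individuals_out = g.n_individuals
    return g, report


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: Feed-efficiency and growth trait columns used in association analysis.
TRAITS = ("FBW", "FBL", "HW", "HL", "DFI", "ADG", "FCR", "KR", "RFI", "RG", "RIG")


@dataclass
class PhenotypeSchema:
    """Declared factor level sets and covariate range for a phenotype table."""

    factor_levels: dict = field(default_factory=lambda: {
        "farm": ["farm1", "farm2"],
        "sex": ["female", "male"],
        "color_type": ["dark", "demi", "mahogany", "pastel", "stardust"],
        "row_year": [f"{row}_{year}" for year in (2018, 2019)
                     for row in (1, 4, 5, 7, 8, 11)],
    })
    covariates: tuple = ("age_days",)
    age_range: tuple = (184, 229)
    traits: tuple = TRAITS


@dataclass
class PhenotypeTable:
    """Typed phenotype/covariate table keyed by individual id."""

    data: pd.DataFrame
    schema: PhenotypeSchema

    @property
    def individuals(self) -> list[str]:
        return list(self.data["id"])


def read_phenotypes(tsv_path, schema: PhenotypeSchema | None = None) -> PhenotypeTable:
    """Read and validate a tab-separated phenotype table.

    Unknown factor levels are rejected; rows missing a trait value are kept
    (complete-case handling happens per model downstream).
    """
    schema = schema or PhenotypeSchema()
    df = pd.read_csv(tsv_path, sep="\t", dtype={"id": str})
    mandatory = ["id"] + list(schema.factor_levels) + list(schema.covariates)
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing mandatory columns {missing_cols}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    for factor, levels in schema.factor_levels.items():
        observed = df[factor].astype(str)
        bad = set(observed) - set(map(str, levels))
        if bad:
            raise ValueError(f"unknown level(s) {sorted(bad)} for factor {factor!r}; "
                             f"declared levels: {levels}")
        df[factor] = pd.Categorical(observed, categories=[str(x) for x in levels])
    lo, hi = schema.age_range
    age = df["age_days"]
    if ((age < lo) | (age > hi)).any():
        raise ValueError(f"age_days outside declared range [{lo}, {hi}]")
    return PhenotypeTable(df, schema)


def write_phenotypes(table: PhenotypeTable, tsv_path) -> None:
    table.data.to_csv(tsv_path, sep="\t", index=False)
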