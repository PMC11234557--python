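"""VanRaden genomic relationship matrix (GRM).

G = W W' / (2 * sum_k p_k (1 - p_k)), where W holds genotype codes centered
by twice the sample allele frequency (VanRaden's first method). Missing cells
are imputed to the SNP mean, i.e. set to 0 after centering, and monomorphic
SNPs contribute to neither the numerator nor the denominator. G is the
covariance structure of the polygenic random effect in the animal model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class GRMMatrix:
    """Symmetric relationship matrix over an ordered individual list."""

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM not symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite GRM entries")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def reorder(self, individuals: list[str]) -> "GRMMatrix":
        """Restrict/permute to the given individual order."""
        index = {ind: i for i, ind in enumerate(self.individuals)}
        idx = np.array([index[i] for i in individuals])
        return GRMMatrix(list(individuals), self.values[np.ix_(idx, idx)])


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the counted allele, missing cells excluded."""
    observed = g.codes != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        k = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"SNP {g.snps.table['snp_id'].iloc[k]!r} has no non-missing calls")
    totals = np.where(observed, g.codes, 0).sum(axis=0)
    return totals / (2.0 * n_obs)


def vanraden_grm(g: GenotypeMatrix) -> GRMMatrix:
    """Build the VanRaden GRM from a genotype matrix (>= 2 individuals)."""
    if g.n_individuals < 2:
        raise ValueError("GRM needs at least 2 individuals")
    p = allele_frequencies(g)
    poly = (p > 0) & (p < 1)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom == 0:
        raise ValueError("all SNPs monomorphic; GRM denominator is zero")
    codes = g.codes[:, poly].astype(float)
    w = codes - 2.0 * p[poly]
    w[g.codes[:, poly] == MISSING] = 0.0
    values = (w @ w.T) / denom
    values = (values + values.T) / 2.0  # exact symmetry
    return GRMMatrix(list(g.individuals), values)


def stabilize(gm: GRMMatrix, blend_weight: float = 0.02,
              min_eigenvalue: float = 1e-8) -> tuple[GRMMatrix, dict]:
    """Blend a singular/near-singular GRM with the identity: G* = (1-w)G + wI.

    Returns the (possibly unchanged) matrix and a small diagnostics dict with
    the smallest eigenvalue before/after and the weight actually applied.
    """
    eigvals = np.linalg.eigvalsh(gm.values)
    info = {"min_eigenvalue_before": float(eigvals[0]), "blend_weight_applied": 0.0}
    if eigvals[0] > min_eigenvalue:
        log.info("GRM well-conditioned (min eigenvalue %.3g); no blending", eigvals[0])
        info["min_eigenvalue_after"] = float(eigvals[0])
        return gm, info
    blended = (1.0 - blend_weight) * gm.values + blend_weight * np.eye(gm.n)
    info["blend_weight_applied"] = blend_weight
    info["min_eigenvalue_after"] = float(np.linalg.eigvalsh(blended)[0])
    log.info("GRM blended with identity (w=%.3g): min eigenvalue %.3g -> %.3g",
             blend_weight, info["min_eigenvalue_before"], info["min_eigenvalue_after"])
    return GRMMatrix(list(gm.individuals), blended), info


def write_grm(gm: GRMMatrix, prefix) -> None:
    """Write lower-triangle TSV (i, j, value) plus an id index file."""
    with open(f"{prefix}.grm.id", "w") as fh:
        for ind in gm.individuals:
            fh.write(f"{ind}\n")
    with open(f"{prefix}.grm.tsv", "w") as fh:
        for i in range(gm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{gm.values[i, j]:.10g}\n")


def read_grm(prefix) -> GRMMatrix:
    individuals = [line.strip() for line in open(f"{prefix}.grm.id") if line.strip()]
    n = len(individuals)
    values = np.zeros((n, n))
    tri = pd.read_csv(f"{prefix}.grm.tsv", sep="\t", header=None,
                      names=["i", "j", "value"])
    values[tri["i"] - 1, tri["j"] - 1] = tri["value"]
    values = values + np.tril(values, -1).T
    return GRMMatrix(individuals, values)
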