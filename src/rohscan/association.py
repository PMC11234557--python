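"""Animal-model association of consensus ROH with quantitative traits.

The model is y = mu + X b + Z u + e with a polygenic random effect
u ~ N(0, G sigma2_u) (G the VanRaden GRM) and residuals e ~ N(0, I sigma2_e).
Consensus-ROH carrier indicators enter X simultaneously as 0/1 fixed effects
alongside the management factors (farm, sex, color type, row-year) and the
age covariate. Variance components are estimated by REML, profiled over the
variance ratio after rotating the model into the GRM eigenbasis, and each ROH
coefficient is tested with a Wald statistic.

The Wald reference distribution is Student-t with the residual degrees of
freedom (n - p); its square is F(1, n - p), which tracks the denominator-df
Wald tests of standard REML software and converges to the chi-square(1) test
as n grows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .consensus import ConsensusROH
from .genotype_io import PhenotypeTable
from .grm import GRMMatrix

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10
_DELTA_BRACKET = (1e-4, 1e4)  # delta = sigma2_e / sigma2_u
_DELTA_GRID_POINTS = 61


@dataclass
class FixedEffectsSpec:
    """Book-keeping for a built design matrix."""

    columns: list[str]
    factor_columns: list[str]
    covariate_columns: list[str]
    roh_columns: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (column, reason)


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    log_likelihood: float

    @property
    def h2(self) -> float:
        total = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / total if total > 0 else 0.0


@dataclass
class MixedModelFit:
    """A fitted animal model for one trait."""

    trait: str
    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    varcomp: VarianceComponents
    df_residual: int
    identifiable: bool
    dropped: list[tuple[str, str]]

    def wald_p(self, name: str) -> float:
        t = self.coefficients[name] / self.standard_errors[name]
        return float(2.0 * stats.t.sf(abs(t), self.df_residual))


@dataclass(frozen=True)
class AssociationResult:
    label: str
    trait: str
    estimate: float
    se: float
    p_value: float
    significant: bool
    frequency: float
    aliased: bool = False


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def _rank_filter(X: pd.DataFrame,
                 tol: float = 1e-8) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop columns linearly dependent on *earlier* ones.

    Incremental orthogonalisation in column order, so the intercept and
    factor columns take precedence over later ROH indicators when a set of
    columns is collinear.
    """
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    Q = np.empty((n, 0))
    keep_cols: list[str] = []
    dropped: list[tuple[str, str]] = []
    for i, name in enumerate(X.columns):
        col = A[:, i]
        scale = np.linalg.norm(col)
        if scale == 0:
            dropped.append((name, "aliased (rank-deficient)"))
            continue
        resid = col - Q @ (Q.T @ col)
        resid -= Q @ (Q.T @ resid)  # second pass for numerical safety
        if np.linalg.norm(resid) <= tol * scale:
            dropped.append((name, "aliased (rank-deficient)"))
            continue
        Q = np.column_stack([Q, resid / np.linalg.norm(resid)])
        keep_cols.append(name)
    return X[keep_cols], dropped


def build_design(phenos: PhenotypeTable,
                 consensus: list[ConsensusROH] | None = None,
                 carriers: pd.DataFrame | None = None,
                 factors: list[str] | None = None,
                 covariates: list[str] | None = None) -> tuple[FixedEffectsSpec, pd.DataFrame]:
    """Intercept + treatment-coded factors + covariates + ROH 0/1 indicators.

    The first level (alphabetically) of each factor is the reference level.
    Factors with a single observed level are dropped with a warning; exactly
    collinear columns (including ROH indicators aliased with each other or
    with the intercept) are detected by pivoted QR and dropped with a logged
    reason.
    """
    df = phenos.data
    factors = list(phenos.schema.factor_levels) if factors is None else factors
    covariates = list(phenos.schema.covariates) if covariates is None else covariates
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    dropped: list[tuple[str, str]] = []
    factor_cols: list[str] = []
    for factor in factors:
        observed = df[factor].astype(str)
        levels = sorted(observed.unique())
        if len(levels) < 2:
            dropped.append((factor, "single observed level"))
            warnings.warn(f"factor {factor!r} has a single observed level; dropped",
                          stacklevel=2)
            continue
        for level in levels[1:]:  # first level = reference
            col = f"{factor}[{level}]"
            X[col] = (observed == level).astype(float)
            factor_cols.append(col)
    cov_cols = []
    for cov in covariates:
        X[cov] = df[cov].astype(float)
        cov_cols.append(cov)
    roh_cols: list[str] = []
    if consensus:
        if carriers is None:
            raise ValueError("consensus regions given without a carrier matrix")
        ids = df["id"].astype(str)
        for c in consensus:
            X[c.label] = carriers.loc[ids, c.label].to_numpy(dtype=float)
            roh_cols.append(c.label)
    X, rank_dropped = _rank_filter(X)
    dropped.extend(rank_dropped)
    for col, reason in rank_dropped:
        log.info("design column %s dropped: %s", col, reason)
    spec = FixedEffectsSpec(
        columns=list(X.columns),
        factor_columns=[c for c in factor_cols if c in X.columns],
        covariate_columns=[c for c in cov_cols if c in X.columns],
        roh_columns=[c for c in roh_cols if c in X.columns],
        dropped=dropped,
    )
    return spec, X


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _profiled_reml(lam: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """Restricted log-likelihood profiled over sigma2_e at variance ratio
    lam = sigma2_u / sigma2_e; returns (ll, beta, cov_unscaled, s2e)."""
    n, p = Xr.shape
    w = lam * d + 1.0
    xtwx = (Xr.T / w) @ Xr
    xtwy = (Xr.T / w) @ yr
    try:
        cf = np.linalg.cholesky(xtwx)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    beta = np.linalg.solve(xtwx, xtwy)
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        return -np.inf, None, None, None
    s2e = rss / (n - p)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * s2e) + 1.0)
                 + float(np.log(w).sum())
                 + 2.0 * float(np.log(np.diag(cf)).sum()))
    return ll, beta, np.linalg.inv(xtwx), s2e


def reml_fit(y: np.ndarray, X: pd.DataFrame | np.ndarray, gm: GRMMatrix,
             trait: str = "y", sigma_u_zero: bool = False,
             eig: tuple[np.ndarray, np.ndarray] | None = None,
             dropped: list | None = None) -> MixedModelFit:
    """REML fit of the single-random-effect animal model.

    Rotates y and X by the eigenvectors of G so the covariance is diagonal,
    profiles the restricted likelihood over the variance ratio on a log grid
    spanning delta = sigma2_e/sigma2_u in [1e-4, 1e4], then refines by bounded
    1-D optimisation. ``eig`` lets callers reuse a precomputed
    eigendecomposition of the same G. With ``sigma_u_zero`` the polygenic
    variance is constrained to zero (generalised least squares collapses to
    ordinary least squares).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"b{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if ya.shape[0] != n or gm.n != n:
        raise ValueError("y, X and G dimensions disagree")
    if n <= p:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    if eig is None:
        d, U = np.linalg.eigh(gm.values)
    else:
        d, U = eig
    if d[0] < -1e-6 * max(1.0, d[-1]):
        raise ValueError(
            f"G has negative eigenvalue {d[0]:.3g}; stabilize() it first")
    d = np.clip(d, 0.0, None)
    yr = U.T @ ya
    Xr = U.T @ Xa

    identifiable = (d.max() - d.min()) > 1e-8 * max(1.0, d.max())
    if sigma_u_zero or not identifiable:
        if not identifiable and not sigma_u_zero:
            warnings.warn(
                "G is (a multiple of) the identity: the polygenic/residual "
                "variance split is not identifiable; reporting sigma2_u = 0 "
                "with the total variance in sigma2_e", stacklevel=2)
        ll, beta, cov_u, s2e = _profiled_reml(0.0, d, yr, Xr)
        lam_hat = 0.0
    else:
        lam_lo, lam_hi = 1.0 / _DELTA_BRACKET[1], 1.0 / _DELTA_BRACKET[0]
        grid = np.logspace(np.log10(lam_lo), np.log10(lam_hi), _DELTA_GRID_POINTS)
        grid = np.concatenate([[0.0], grid])
        lls = np.array([_profiled_reml(lam, d, yr, Xr)[0] for lam in grid])
        k = int(np.nanargmax(lls))
        lo = grid[max(k - 1, 0)] if k > 0 else 0.0
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda lam: -_profiled_reml(lam, d, yr, Xr)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6 * max(1.0, hi)})
            lam_hat = float(res.x)
            if -res.fun < lls[k]:
                lam_hat = float(grid[k])
        else:
            lam_hat = float(grid[k])
        ll, beta, cov_u, s2e = _profiled_reml(lam_hat, d, yr, Xr)
    if not np.isfinite(ll):
        raise ValueError(
            f"non-finite REML likelihood on the ratio bracket "
            f"[{1/_DELTA_BRACKET[1]:.1e}, {1/_DELTA_BRACKET[0]:.1e}]")
    sigma2_e = max(s2e, _VAR_FLOOR)
    sigma2_u = max(lam_hat * s2e, 0.0)
    if 0 < sigma2_u < _VAR_FLOOR:
        sigma2_u = _VAR_FLOOR
    cov = cov_u * sigma2_e
    se = np.sqrt(np.diag(cov))
    return MixedModelFit(
        trait=trait,
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        varcomp=VarianceComponents(sigma2_u, sigma2_e, float(ll)),
        df_residual=n - p,
        identifiable=identifiable,
        dropped=list(dropped or []),
    )


# ---------------------------------------------------------------------------
# Wald tests and orchestration
# ---------------------------------------------------------------------------

def wald_tests(fit: MixedModelFit, roh_columns: list[str],
               frequencies: dict[str, float] | None = None,
               alpha: float = 0.01) -> list[AssociationResult]:
    """Per-ROH Wald test of its fitted indicator coefficient.

    Aliased (dropped) ROH columns are reported as untestable rows with NaN
    statistics, never as p = 1.
    """
    frequencies = frequencies or {}
    dropped_names = {name for name, _ in fit.dropped}
    results: list[AssociationResult] = []
    for label in roh_columns:
        if label in dropped_names or label not in fit.coefficients.index:
            results.append(AssociationResult(
                label=label, trait=fit.trait, estimate=np.nan, se=np.nan,
                p_value=np.nan, significant=False,
                frequency=frequencies.get(label, np.nan), aliased=True))
            continue
        p = fit.wald_p(label)
        results.append(AssociationResult(
            label=label, trait=fit.trait,
            estimate=float(fit.coefficients[label]),
            se=float(fit.standard_errors[label]),
            p_value=p, significant=p < alpha,
            frequency=frequencies.get(label, np.nan)))
    return results


def screen_fixed_effects(phenos: PhenotypeTable, trait: str, gm: GRMMatrix,
                         factors: list[str] | None = None,
                         covariates: list[str] | None = None,
                         alpha: float = 0.01) -> pd.DataFrame:
    """Univariate significance screen of each factor/covariate for one trait.

    Each term is fitted alone (intercept + term) in the same REML machinery
    and tested jointly with a Wald F statistic on its coefficients. Constant
    terms are flagged untestable.
    """
    factors = list(phenos.schema.factor_levels) if factors is None else factors
    covariates = list(phenos.schema.covariates) if covariates is None else covariates
    df = phenos.data
    keep = df[trait].notna().to_numpy()
    sub = PhenotypeTable(df.loc[keep].reset_index(drop=True), phenos.schema)
    y = sub.data[trait].to_numpy(float)
    g_sub = gm.reorder([str(i) for i in sub.data["id"]])
    eig = np.linalg.eigh(g_sub.values)
    rows = []
    for term, is_factor in [(f, True) for f in factors] + [(c, False) for c in covariates]:
        spec, X = build_design(sub, factors=[term] if is_factor else [],
                               covariates=[] if is_factor else [term])
        term_cols = spec.factor_columns if is_factor else spec.covariate_columns
        if not term_cols:
            rows.append((term, np.nan, np.nan, False, "untestable (constant)"))
            continue
        fit = reml_fit(y, X, g_sub, trait=trait, eig=eig)
        b = fit.coefficients[term_cols].to_numpy()
        C = fit.covariance.loc[term_cols, term_cols].to_numpy()
        k = len(term_cols)
        fstat = float(b @ np.linalg.solve(C, b)) / k
        p = float(stats.f.sf(fstat, k, fit.df_residual))
        rows.append((term, fstat, p, p < alpha, ""))
    return pd.DataFrame(rows, columns=["term", "f_statistic", "p_value",
                                       "significant", "note"])


def run_association(phenos: PhenotypeTable, consensus: list[ConsensusROH],
                    carriers: pd.DataFrame, gm: GRMMatrix,
                    traits: list[str] | None = None,
                    alpha: float = 0.01) -> pd.DataFrame:
    """Fit the full animal model per trait and test every consensus ROH.

    All consensus indicators are fitted simultaneously; individuals missing a
    trait are dropped for that trait's model (complete case, logged). Returns
    a long-format table with one row per (ROH, trait), including a
    Benjamini-Hochberg FDR column for reference (the ``significant`` flag
    uses the nominal threshold only).
    """
    traits = list(phenos.schema.traits) if traits is None else traits
    frequencies = {c.label: c.frequency for c in consensus}
    all_results: list[AssociationResult] = []
    for trait in traits:
        if trait not in phenos.data.columns:
            warnings.warn(f"trait {trait!r} absent from phenotype table; skipped",
                          stacklevel=2)
            continue
        keep = phenos.data[trait].notna().to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("trait %s: %d individuals without records dropped", trait, n_dropped)
        sub = PhenotypeTable(phenos.data.loc[keep].reset_index(drop=True), phenos.schema)
        if len(sub.data) < 3:
            warnings.warn(f"trait {trait!r}: too few records; skipped", stacklevel=2)
            continue
        y = sub.data[trait].to_numpy(float)
        g_sub = gm.reorder([str(i) for i in sub.data["id"]])
        spec, X = build_design(sub, consensus, carriers)
        fit = reml_fit(y, X, g_sub, trait=trait, dropped=spec.dropped)
        all_results.extend(wald_tests(fit, [c.label for c in consensus],
                                      frequencies, alpha=alpha))
    out = pd.DataFrame([r.__dict__ for r in all_results])
    if len(out):
        out["fdr_bh"] = np.nan
        tested = out["p_value"].notna()
        if tested.any():
            out.loc[tested, "fdr_bh"] = _bh_fdr(out.loc[tested, "p_value"].to_numpy())
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def significant_report(results: pd.DataFrame, consensus: list[ConsensusROH],
                       gene_overlaps: dict[str, list] | None = None) -> pd.DataFrame:
    """Significant-region report: one row per ROH with its associated traits,
    p-values, frequency, SNP count and (optionally) overlapping genes."""
    by_label = {c.label: c for c in consensus}
    sig = results[results["significant"].fillna(False)]
    rows = []
    for label, grp in sig.groupby("label", sort=False):
        c = by_label[label]
        genes = "-"
        if gene_overlaps is not None:
            genes = "; ".join(g.gene_id for g in gene_overlaps.get(label, [])) or "-"
        rows.append((c.chrom, c.start_bp, c.end_bp, c.length_bp,
                     "; ".join(grp["trait"]),
                     "; ".join(f"{p:.4g}" for p in grp["p_value"]),
                     round(100.0 * c.frequency, 2), c.n_snps, genes))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "length_bp",
                                       "associated_traits", "p_values",
                                       "frequency_pct", "n_snps", "candidate_genes"])
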