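"""Per-SNP mixed-model regression scan with Wald chi-squared tests.

Each SNP enters the animal model as a fixed allele-substitution effect:
y = 1*mu + b*x + Za + e, with the variance components estimated once
from the no-SNP model and held fixed for every marker (the P3D/EMMAX
device).  ``fit_single_snp`` solves Henderson's mixed model equations
directly; ``scan`` gets the identical answer for the whole genome from
one spectral rotation, at the cost of a weighted 2-covariate regression
per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .reml import SpectralCache, VarianceComponents, build_spectral_cache, incidence_Z

__all__ = ["AssociationRecord", "ScanResult", "fit_single_snp", "scan",
           "wald_pvalue", "bonferroni_threshold", "ScanEngine"]


def wald_pvalue(wald: float | np.ndarray) -> float | np.ndarray:
    """Upper-tail chi-square(df=1) probability of the Wald statistic."""
    w = np.asarray(wald, dtype=float)
    if np.any(w < 0):
        raise ValueError("Wald statistic must be non-negative")
    p = chi2.sf(w, df=1)
    return float(p) if np.isscalar(wald) or w.ndim == 0 else p


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test p-value threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's mixed-model regression result."""

    snp: str
    chromosome: int
    pos_cm: float
    maf: float
    b_hat: float
    var_b: float
    wald: float
    p_raw: float
    tested: bool = True


@dataclass
class ScanResult:
    """Whole-genome scan: one record per retained SNP, in map order."""

    records: pd.DataFrame  # snp, chromosome, pos_cm, maf, b_hat, var_b, wald, p_raw, tested
    vc: VarianceComponents
    n_individuals: int

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def top_hit(self) -> pd.Series:
        tested = self.records[self.records["tested"]]
        return tested.loc[tested["wald"].idxmax()]


def _mme_solve(y: np.ndarray, X: np.ndarray, A: np.ndarray,
               phen_idx: np.ndarray, vc: VarianceComponents
               ) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's MME for fixed beta and random a; returns (beta_hat, Var(beta_hat)).

    Coefficient matrix [[X'X, X'Z], [Z'X, Z'Z + A^-1 * k]] with
    k = sigma_e2/sigma_a2; Var(beta_hat) = sigma_e2 * C^{beta,beta}.
    A^-1 comes from a Cholesky factorisation with a small jitter.
    """
    if vc.sigma_a2 <= 0:
        raise ValueError("MME requires sigma_a2 > 0; use OLS in the null limit")
    n_ped = A.shape[0]
    Z = np.zeros((len(phen_idx), n_ped))
    Z[np.arange(len(phen_idx)), phen_idx] = 1.0
    k = vc.sigma_e2 / vc.sigma_a2
    try:
        Ainv = cho_solve(cho_factor(A), np.eye(n_ped))
    except np.linalg.LinAlgError:
        Ainv = cho_solve(cho_factor(A + 1e-10 * np.eye(n_ped)), np.eye(n_ped))
    p = X.shape[1]
    C = np.block([[X.T @ X, X.T @ Z],
                  [Z.T @ X, Z.T @ Z + Ainv * k]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    return sol[:p], vc.sigma_e2 * Cinv[:p, :p]


def fit_single_snp(y: np.ndarray, x: np.ndarray, A: np.ndarray,
                   phen_idx: np.ndarray, vc: VarianceComponents,
                   snp: str = "", chromosome: int = 0, pos_cm: float = np.nan
                   ) -> AssociationRecord:
    """Fit one SNP through the mixed model equations.

    Equivalent to generalised least squares of y on [1, x] with
    V = Z A Z' sigma_a2 + I sigma_e2.  ``x`` must vary among the
    phenotyped individuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("SNP has no genotype variation among phenotyped "
                         "individuals (monomorphic)")
    X = np.column_stack([np.ones_like(y), x])
    beta, var_beta = _mme_solve(y, X, A, phen_idx, vc)
    b_hat = float(beta[1])
    var_b = float(var_beta[1, 1])
    wald = b_hat**2 / var_b
    maf = min(x.mean() / 2.0, 1.0 - x.mean() / 2.0)
    return AssociationRecord(snp=snp, chromosome=chromosome, pos_cm=pos_cm,
                             maf=float(maf), b_hat=b_hat, var_b=var_b,
                             wald=wald, p_raw=wald_pvalue(wald))


class ScanEngine:
    """Reusable spectral machinery for scanning (and permuting) one dataset.

    Rotates y and every genotype column by the eigenvectors of
    K = Z A Z' once; each SNP then costs a closed-form weighted 2x2
    regression.  Reused by the permutation module, where only the rotated
    phenotype changes.
    """

    def __init__(self, genotypes: GenotypeMatrix, trait: pd.DataFrame,
                 pedigree: Pedigree, A: np.ndarray, vc: VarianceComponents,
                 cache: SpectralCache | None = None):
        ids = list(trait["id"])
        self.phen_idx = incidence_Z(pedigree, trait)
        rows = genotypes.row_index(ids)
        self.G = genotypes.codes[rows].astype(float)
        self.snp_map = genotypes.snp_map
        self.vc = vc
        if cache is None:
            cache = build_spectral_cache(A, self.phen_idx)
        self.cache = cache
        lam = vc.lambda_ratio
        self.v = 1.0 / (lam * cache.eigvals + 1.0)
        self.ot = cache.Xt[:, 0]                      # rotated intercept
        self.Gt = cache.U.T @ self.G                  # rotated genotypes
        vo = self.v * self.ot
        self.a11 = float(vo @ self.ot)
        self.a1x = vo @ self.Gt
        self.axx = self.v @ self.Gt**2
        self.det = self.a11 * self.axx - self.a1x**2
        self.untested = np.ptp(self.G, axis=0) == 0   # monomorphic columns
        self.maf = np.minimum(self.G.mean(axis=0) / 2.0,
                              1.0 - self.G.mean(axis=0) / 2.0)

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.cache.rotate(np.asarray(y, dtype=float))

    def wald_vector(self, yt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(b_hat, var_b, wald) for every SNP given an already-rotated y."""
        b1 = float((self.v * self.ot) @ yt)
        bx = (self.v * yt) @ self.Gt
        with np.errstate(divide="ignore", invalid="ignore"):
            b_hat = (self.a11 * bx - self.a1x * b1) / self.det
            var_b = self.vc.sigma_e2 * self.a11 / self.det
            wald = b_hat**2 / var_b
        b_hat[self.untested] = np.nan
        var_b = np.where(self.untested, np.nan, var_b)
        wald[self.untested] = np.nan
        return b_hat, var_b, wald

    def max_wald(self, yt: np.ndarray) -> float:
        _, _, wald = self.wald_vector(yt)
        return float(np.nanmax(wald))


def scan(genotypes: GenotypeMatrix, trait: pd.DataFrame, pedigree: Pedigree,
         A: np.ndarray, vc: VarianceComponents,
         engine: ScanEngine | None = None) -> ScanResult:
    """Genome scan: one Wald test per SNP with fixed variance components.

    Monomorphic columns (possible only when QC was skipped) yield a
    flagged no-test record instead of aborting.
    """
    if engine is None:
        engine = ScanEngine(genotypes, trait, pedigree, A, vc)
    y = trait["value"].to_numpy(dtype=float)
    b_hat, var_b, wald = engine.wald_vector(engine.rotate(y))
    with np.errstate(invalid="ignore"):
        p_raw = chi2.sf(wald, df=1)
    records = engine.snp_map.copy()
    records["maf"] = engine.maf
    records["b_hat"] = b_hat
    records["var_b"] = var_b
    records["wald"] = wald
    records["p_raw"] = p_raw
    records["tested"] = ~engine.untested
    return ScanResult(records=records, vc=vc, n_individuals=len(y))
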