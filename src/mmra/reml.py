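"""REML variance components for the animal model y = 1*mu + Za + e.

With a single random effect the restricted likelihood can be profiled
down to one dimension: after one eigendecomposition of K = Z A Z' the
marginal covariance is V = sigma_e2 * (lambda * K + I) with
lambda = sigma_a2 / sigma_e2, the rotated model is heteroscedastic
ordinary regression, and sigma_e2 has a closed form at every lambda.
A bounded 1-D optimisation of the profile then gives the exact REML
estimates — no EM/AI iterations and nothing to tune.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .pedigree import Pedigree

__all__ = ["VarianceComponents", "SpectralCache", "incidence_Z",
           "build_spectral_cache", "restricted_loglik",
           "estimate_variance_components", "NonIdentifiableError"]

_LOG2PI = np.log(2.0 * np.pi)
LAMBDA_BOUNDS = (1e-6, 1e3)


class NonIdentifiableError(RuntimeError):
    """Z A Z' is numerically a multiple of I: lambda cannot be estimated."""


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variance with derived heritability.

    ``h2 = sigma_a2 / (sigma_a2 + sigma_e2)``; ``loglik`` is the restricted
    log-likelihood at the optimum (including its -((n-p)/2) log 2*pi
    constant); ``boundary`` flags an estimate clipped at sigma_a2 = 0.
    """

    sigma_a2: float
    sigma_e2: float
    loglik: float
    converged: bool
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def lambda_ratio(self) -> float:
        """sigma_a2 / sigma_e2."""
        return self.sigma_a2 / self.sigma_e2


def incidence_Z(pedigree: Pedigree, trait: pd.DataFrame) -> np.ndarray:
    """Map phenotype records to pedigree positions (the incidence of a).

    Returns the pedigree index of each phenotyped record, so that
    Z = I[idx, :]; repeated records for one individual are not supported.
    """
    ids = list(trait["id"])
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate phenotype record for id {dup!r}")
    return pedigree.index_of(ids)


@dataclass
class SpectralCache:
    """One-time eigendecomposition of K = Z A Z' plus rotated fixed effects."""

    eigvals: np.ndarray   # d, ascending
    U: np.ndarray         # eigenvectors, K = U diag(d) U'
    Xt: np.ndarray        # U' X for the fixed-effect design X (n, p)
    n: int
    p: int

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ y


def build_spectral_cache(A: np.ndarray, phen_idx: np.ndarray,
                         X: np.ndarray | None = None) -> SpectralCache:
    """Eigendecompose K = A[idx][:, idx] once; default design is the intercept."""
    K = A[np.ix_(phen_idx, phen_idx)]
    d, U = eigh(K)
    n = len(phen_idx)
    if X is None:
        X = np.ones((n, 1))
    return SpectralCache(eigvals=d, U=U, Xt=U.T @ X, n=n, p=X.shape[1])


def restricted_loglik(lambda_ratio: float, cache: SpectralCache,
                      y: np.ndarray) -> float:
    """Restricted log-likelihood at lambda = sigma_a2/sigma_e2, sigma_e2 profiled out.

    -2 lR = (n-p) log 2*pi + (n-p) log s2 + sum log w + log|X'W^-1 X| + (n-p)
    with w_i = lambda d_i + 1 and s2 = RSS_gls / (n - p).
    """
    if lambda_ratio < 0:
        raise ValueError("lambda_ratio must be non-negative")
    w = lambda_ratio * cache.eigvals + 1.0
    if np.any(w <= 0):
        raise ValueError("lambda * K + I not positive definite")
    v = 1.0 / w
    yt = cache.rotate(np.asarray(y, dtype=float))
    Xt = cache.Xt
    XtWX = Xt.T @ (v[:, None] * Xt)
    XtWy = Xt.T @ (v * yt)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(v @ resid**2)
    nu = cache.n - cache.p
    s2 = rss / nu
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return -0.5 * (nu * _LOG2PI + nu * np.log(s2) + np.log(w).sum()
                   + logdet_xwx + nu)


def _backsolve(lambda_ratio: float, cache: SpectralCache, y: np.ndarray
               ) -> tuple[float, float]:
    """(sigma_e2, sigma_a2) at a given lambda."""
    w = lambda_ratio * cache.eigvals + 1.0
    v = 1.0 / w
    yt = cache.rotate(np.asarray(y, dtype=float))
    Xt = cache.Xt
    beta = np.linalg.solve(Xt.T @ (v[:, None] * Xt), Xt.T @ (v * yt))
    resid = yt - Xt @ beta
    s2 = float(v @ resid**2) / (cache.n - cache.p)
    return s2, lambda_ratio * s2


def estimate_variance_components(trait: pd.DataFrame, A: np.ndarray,
                                 pedigree: Pedigree,
                                 cache: SpectralCache | None = None,
                                 xtol: float = 1e-6) -> VarianceComponents:
    """REML fit of the intercept-only animal model.

    Maximises the profiled restricted likelihood over
    lambda in [1e-6, 1e3] (Brent on log10 lambda); sigma_a2 may hit the
    zero boundary, in which case it is clipped and flagged rather than
    raised — boundary nulls are a legitimate outcome in permutation runs.

    Raises
    ------
    NonIdentifiableError
        when Z A Z' is numerically indistinguishable from a multiple of I
        (no relatedness among phenotyped individuals).
    """
    y = trait["value"].to_numpy(dtype=float)
    if cache is None:
        phen_idx = incidence_Z(pedigree, trait)
        cache = build_spectral_cache(A, phen_idx)
    if np.ptp(cache.eigvals) < 1e-10:
        raise NonIdentifiableError(
            "Z A Z' has a flat spectrum: additive and residual variance "
            "are confounded for these data")

    lo, hi = np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        lambda t: -restricted_loglik(10.0**t, cache, y),
        bounds=(lo, hi), method="bounded",
        options={"xatol": xtol})
    lam = float(10.0**res.x)

    boundary = False
    # the profile decreasing towards the lower bound means sigma_a2 -> 0
    if res.x <= lo + 10 * xtol and \
            restricted_loglik(0.0, cache, y) >= -res.fun - 1e-9:
        lam = 0.0
        boundary = True
    s2, sa2 = _backsolve(lam, cache, y)
    return VarianceComponents(
        sigma_a2=sa2, sigma_e2=s2,
        loglik=restricted_loglik(lam, cache, y),
        converged=bool(res.success), boundary=boundary)
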