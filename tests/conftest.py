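"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own computational
paths: kinship by the textbook coancestry recursion, REML and GLS by
brute-force dense matrix algebra, haplotype counting by direct gamete
enumeration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mmra


# ---------------------------------------------------------------------------
# independent oracles


def kinship_oracle(ids, sire, dam):
    """Coancestry recursion: f(i,j) memoised over a (possibly small) pedigree.

    A = 2 * f off-diagonal convention folded in: returns the additive
    relationship matrix a_ij = 2 * f(i, j).
    """
    parents = {i: (s if s != "0" else None, d if d != "0" else None)
               for i, s, d in zip(ids, sire, dam)}
    order = {i: k for k, i in enumerate(ids)}
    memo = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] <= order[b] else (b, a)
        if key in memo:
            return memo[key]
        x, y = key
        if x == y:
            sx, dx = parents[x]
            val = 0.5 * (1.0 + f(sx, dx))
        else:
            # y is not an ancestor of x because order[x] <= order[y]
            sy, dy = parents[y]
            val = 0.5 * (f(x, sy) + f(x, dy))
        memo[key] = val
        return val

    n = len(ids)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2.0 * f(ids[i], ids[j])
    return A


def random_pedigree(rng, n):
    """Random valid pedigree of n individuals; parents drawn from earlier records."""
    ids = [f"I{k}" for k in range(n)]
    sire, dam = [], []
    for k in range(n):
        if k < 2 or rng.random() < 0.35:
            sire.append("0")
            dam.append("0")
        else:
            s, d = rng.choice(k, size=2, replace=False)
            sire.append(ids[s])
            dam.append(ids[d])
    return mmra.Pedigree(ids, sire, dam)


def reml_loglik_oracle(lam, K, X, y):
    """Dense REML criterion -0.5[(n-p)log 2pi + log|V*| + log|X'V*^-1 X| + y'Py]
    with V* = lam*K + I and sigma_e2 profiled out, all by explicit inversion."""
    n, p = X.shape
    Vs = lam * K + np.eye(n)
    Vinv = np.linalg.inv(Vs)
    XVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XVX, X.T @ Vinv @ y)
    r = y - X @ beta
    rss = r @ Vinv @ r
    nu = n - p
    s2 = rss / nu
    _, ld_v = np.linalg.slogdet(Vs)
    _, ld_x = np.linalg.slogdet(XVX)
    return -0.5 * (nu * np.log(2 * np.pi) + nu * np.log(s2) + ld_v + ld_x + nu)


def gls_oracle(y, X, V):
    """(beta_hat, Var(beta_hat)) = ((X'V^-1X)^-1 X'V^-1 y, (X'V^-1X)^-1)."""
    Vinv = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vinv @ X)
    return C @ X.T @ Vinv @ y, C


def gamete_count_oracle(gi, gj):
    """Two-locus haplotype frequencies by direct counting; only valid when
    no individual is heterozygous at both loci."""
    counts = np.zeros((2, 2))
    for a, b in zip(gi, gj):
        assert not (a == 1 and b == 1), "phase-ambiguous individual"
        ai = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[a]
        bj = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[b]
        if a == 1:
            counts[0, bj[0]] += 1
            counts[1, bj[1]] += 1
        elif b == 1:
            counts[ai[0], 0] += 1
            counts[ai[1], 1] += 1
        else:
            counts[ai[0], bj[0]] += 1
            counts[ai[1], bj[1]] += 1
    f = counts / (2 * len(gi))
    return np.array([f[0, 0], f[0, 1], f[1, 0], f[1, 1]])


# ---------------------------------------------------------------------------
# fixtures


SMALL_QTN = [mmra.QtnSpec(1, 20, "additive", 3.0)]


def small_config(seed=0, qtn=None, **kw):
    """A desk-scale analogue of the default design: 5x4x10 families."""
    defaults = dict(n_sires=5, n_dams_per_sire=4, n_progeny_per_dam=10,
                    n_phenotyped_per_dam=8, n_chromosomes=2,
                    snps_per_chromosome=60,
                    qtn_spec=SMALL_QTN if qtn is None else qtn, seed=seed)
    defaults.update(kw)
    return mmra.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_pop():
    return mmra.simulate_population(small_config(seed=11))


@pytest.fixture(scope="session")
def small_A(small_pop):
    return mmra.build_A(small_pop.pedigree)


@pytest.fixture(scope="session")
def small_fit(small_pop, small_A):
    vc = mmra.estimate_variance_components(
        small_pop.trait, small_A, small_pop.pedigree)
    return small_pop, small_A, vc


@pytest.fixture
def trio():
    return mmra.Pedigree(["A", "B", "C"], ["0", "0", "A"], ["0", "0", "B"])
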