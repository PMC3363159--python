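"""Pairwise linkage disequilibrium (D', LOD, confidence intervals) from
unphased genotypes, and Gabriel-criteria LD-block calling.

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity; D' confidence bounds come from the
likelihood of the nine two-locus genotype classes evaluated on a D' grid
with allele frequencies fixed at their estimates.  Blocks follow the
Gabriel et al. confidence-interval criteria (the method behind
Haploview's default block definition): a pair is in "strong LD" when its
D' CI is [>= 0.70, >= 0.98], shows "strong recombination" when the upper
bound is < 0.90, and a marker interval is a block when its outermost
pair is in strong LD and at least 95% of its informative pairs are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["LDPair", "LDBlock", "GabrielParams", "DegeneratePairError",
           "em_haplotype_freq", "d_prime", "lod_score",
           "ld_confidence_interval", "compute_ld_pair", "pairwise_ld",
           "gabriel_blocks"]


class DegeneratePairError(ValueError):
    """D' is undefined: at least one locus is monomorphic in the sample."""


# ---------------------------------------------------------------------------
# haplotype-frequency estimation


def _class_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype-class counts, rows = gi, cols = gj."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype columns differ in length")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1)
    return counts


def em_haplotype_freq(geno_i: np.ndarray, geno_j: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """ML two-locus haplotype frequencies (p11, p12, p21, p22) by EM.

    Haplotype "ab" carries allele a at locus i and allele b at locus j
    (alleles labelled 1/2; genotype codes count allele 2).  Only the
    double heterozygote is phase-ambiguous; EM starts from linkage
    equilibrium and iterates its expected phase split.
    """
    counts = _class_counts(geno_i, geno_j)
    n = counts.sum()
    if np.ptp(np.asarray(geno_i)) == 0 or np.ptp(np.asarray(geno_j)) == 0:
        raise DegeneratePairError("monomorphic locus: D' undefined")

    # unambiguous haplotype counts; genotype class (a, b) contributes
    # known gametes except (1, 1)
    base = np.zeros((2, 2))  # [allele_i - 1, allele_j - 1]
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            # per individual, two gametes; for non-double-het classes the
            # split of alleles across gametes is unique
            alleles_i = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[a]
            alleles_j = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[b]
            if a == 1:
                # locus i heterozygous, locus j homozygous: gametes are
                # (1, j-allele) and (2, j-allele)
                base[0, alleles_j[0]] += c
                base[1, alleles_j[1]] += c
            elif b == 1:
                base[alleles_i[0], 0] += c
                base[alleles_i[1], 1] += c
            else:
                base[alleles_i[0], alleles_j[0]] += c
                base[alleles_i[1], alleles_j[1]] += c
    n_dh = counts[1, 1]

    # start at linkage equilibrium
    p_i2 = np.asarray(geno_i).mean() / 2.0
    p_j2 = np.asarray(geno_j).mean() / 2.0
    f = np.array([[(1 - p_i2) * (1 - p_j2), (1 - p_i2) * p_j2],
                  [p_i2 * (1 - p_j2), p_i2 * p_j2]])

    for _ in range(max_iter):
        # E: split double heterozygotes between coupling (11/22) and
        # repulsion (12/21) phase
        coup = f[0, 0] * f[1, 1]
        rep = f[0, 1] * f[1, 0]
        tot = coup + rep
        w = 0.5 if tot == 0 else coup / tot
        counts_h = base.copy()
        counts_h[0, 0] += n_dh * w
        counts_h[1, 1] += n_dh * w
        counts_h[0, 1] += n_dh * (1 - w)
        counts_h[1, 0] += n_dh * (1 - w)
        # M
        f_new = counts_h / (2.0 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return np.array([f[0, 0], f[0, 1], f[1, 0], f[1, 1]])


def _freq_margins(hap_freqs: np.ndarray) -> tuple[float, float, float, float]:
    p11, p12, p21, p22 = hap_freqs
    p1 = p11 + p12   # allele 1 at locus i
    q1 = p11 + p21   # allele 1 at locus j
    return p1, 1.0 - p1, q1, 1.0 - q1


def d_prime(hap_freqs: np.ndarray) -> float:
    """Lewontin's D' = |D| / Dmax with D = p11 - p1*q1."""
    p11, p12, p21, p22 = np.asarray(hap_freqs, dtype=float)
    total = p11 + p12 + p21 + p22
    if abs(total - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    p1, p2, q1, q2 = _freq_margins(hap_freqs)
    D = p11 - p1 * q1
    if D > 0:
        dmax = min(p1 * q2, p2 * q1)
    else:
        dmax = min(p1 * q1, p2 * q2)
    if dmax <= 0:
        raise DegeneratePairError("monomorphic margin: D' undefined")
    return float(min(abs(D) / dmax, 1.0))


def _genotype_class_probs(hap_freqs: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities under random union of gametes."""
    f = np.asarray(hap_freqs, dtype=float).reshape(2, 2)
    T = np.zeros((3, 3))
    for (a1, b1), (a2, b2) in itertools.product(
            itertools.product(range(2), range(2)), repeat=2):
        T[a1 + a2, b1 + b2] += f[a1, b1] * f[a2, b2]
    return T


def _class_loglik(counts: np.ndarray, hap_freqs: np.ndarray) -> float:
    T = _genotype_class_probs(hap_freqs)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logT = np.log(np.clip(T, 1e-300, None))
    return float((counts[mask] * logT[mask]).sum())


def lod_score(geno_i: np.ndarray, geno_j: np.ndarray,
              hap_freqs: np.ndarray | None = None) -> float:
    """log10 likelihood ratio of the estimated D against D = 0.

    Both likelihoods use the multinomial over the nine genotype classes;
    the null fixes allele frequencies at their estimates and sets D = 0.
    Non-negative up to EM convergence tolerance (clamped at 0).
    """
    counts = _class_counts(geno_i, geno_j)
    if hap_freqs is None:
        hap_freqs = em_haplotype_freq(geno_i, geno_j)
    p1, p2, q1, q2 = _freq_margins(hap_freqs)
    null = np.array([p1 * q1, p1 * q2, p2 * q1, p2 * q2])
    lod = (_class_loglik(counts, hap_freqs) - _class_loglik(counts, null)) \
        / np.log(10.0)
    return float(max(lod, 0.0))


def _freqs_at_dprime(dp: float, sign: float, p1: float, p2: float,
                     q1: float, q2: float) -> np.ndarray:
    """Haplotype frequencies at a given |D'| with fixed margins and D sign."""
    if sign >= 0:
        D = dp * min(p1 * q2, p2 * q1)
    else:
        D = -dp * min(p1 * q1, p2 * q2)
    f = np.array([p1 * q1 + D, p1 * q2 - D, p2 * q1 - D, p2 * q2 + D])
    return np.clip(f, 0.0, 1.0)


def ld_confidence_interval(geno_i: np.ndarray, geno_j: np.ndarray,
                           hap_freqs: np.ndarray | None = None,
                           grid_step: float = 0.01,
                           coverage: float = 0.90) -> tuple[float, float]:
    """Likelihood-based D' confidence bounds on a [0, 1] grid.

    The nine-class genotype likelihood is evaluated at each grid value of
    D' (allele frequencies fixed at their estimates, sign of D fixed at
    the point estimate's), normalised to a weight distribution, and the
    two-sided `coverage` interval is read off the cumulative weights —
    the computation behind Gabriel-style "strong LD" calls.
    """
    counts = _class_counts(geno_i, geno_j)
    if hap_freqs is None:
        hap_freqs = em_haplotype_freq(geno_i, geno_j)
    p1, p2, q1, q2 = _freq_margins(hap_freqs)
    if min(p1, p2, q1, q2) <= 0:
        raise DegeneratePairError("monomorphic margin: D' undefined")
    sign = 1.0 if (hap_freqs[0] - p1 * q1) >= 0 else -1.0

    grid = np.arange(0.0, 1.0 + grid_step / 2.0, grid_step)
    logl = np.array([_class_loglik(counts, _freqs_at_dprime(dp, sign,
                                                            p1, p2, q1, q2))
                     for dp in grid])
    w = np.exp(logl - logl.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo_mass = (1.0 - coverage) / 2.0
    hi_mass = 1.0 - lo_mass
    ci_low = float(grid[np.searchsorted(cum, lo_mass)])
    ci_high = float(grid[np.searchsorted(cum, hi_mass)])
    return ci_low, ci_high


@dataclass(frozen=True)
class LDPair:
    """Pairwise LD summary between two SNPs."""

    snp_i: str
    snp_j: str
    hap_freqs: tuple[float, float, float, float]
    D: float
    d_prime: float
    lod: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def compute_ld_pair(geno_i: np.ndarray, geno_j: np.ndarray,
                    snp_i: str = "", snp_j: str = "",
                    grid_step: float = 0.01) -> LDPair:
    """All pairwise LD quantities for one SNP pair; degenerate pairs are flagged."""
    try:
        f = em_haplotype_freq(geno_i, geno_j)
        dp = d_prime(f)
        lod = lod_score(geno_i, geno_j, f)
        lo, hi = ld_confidence_interval(geno_i, geno_j, f, grid_step)
    except DegeneratePairError:
        return LDPair(snp_i, snp_j, (np.nan,) * 4, np.nan, np.nan, np.nan,
                      np.nan, np.nan, degenerate=True)
    p1, _, q1, _ = _freq_margins(f)
    return LDPair(snp_i, snp_j, tuple(f), float(f[0] - p1 * q1), dp, lod,
                  lo, hi)


def pairwise_ld(genotypes: GenotypeMatrix, snp_ids: list[str] | None = None,
                grid_step: float = 0.01) -> pd.DataFrame:
    """All pairwise LD records among `snp_ids` (default: every SNP), as a
    long-format DataFrame ordered by map position."""
    snp_col = genotypes.snp_map["snp"]
    if snp_ids is None:
        idx = np.arange(genotypes.n_snps)
    else:
        lookup = {s: i for i, s in enumerate(snp_col)}
        idx = np.asarray([lookup[s] for s in snp_ids], dtype=np.intp)
    rows = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            pair = compute_ld_pair(genotypes.codes[:, i], genotypes.codes[:, j],
                                   snp_col.iloc[i], snp_col.iloc[j], grid_step)
            rows.append({
                "snp_i": pair.snp_i, "snp_j": pair.snp_j,
                "chromosome_i": genotypes.snp_map["chromosome"].iloc[i],
                "chromosome_j": genotypes.snp_map["chromosome"].iloc[j],
                "D": pair.D, "d_prime": pair.d_prime, "lod": pair.lod,
                "ci_low": pair.ci_low, "ci_high": pair.ci_high,
                "degenerate": pair.degenerate,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gabriel blocks


@dataclass(frozen=True)
class GabrielParams:
    """Haploview-default thresholds for the Gabriel et al. criteria."""

    ci_low_strong: float = 0.70
    ci_high_strong: float = 0.98
    ci_high_recomb: float = 0.90
    informative_fraction: float = 0.95


@dataclass(frozen=True)
class LDBlock:
    """A contiguous run of markers qualifying as one LD block."""

    chromosome: int
    first_snp: str
    last_snp: str
    members: tuple[str, ...]
    n_strong_ld_pairs: int
    n_informative_pairs: int


def _classify(pair_row, params: GabrielParams) -> str:
    if pair_row["degenerate"] or np.isnan(pair_row["ci_low"]):
        return "uninformative"
    if pair_row["ci_low"] >= params.ci_low_strong and \
            pair_row["ci_high"] >= params.ci_high_strong:
        return "strong_ld"
    if pair_row["ci_high"] < params.ci_high_recomb:
        return "strong_recomb"
    return "uninformative"


def gabriel_blocks(pairs: pd.DataFrame, snp_map: pd.DataFrame,
                   params: GabrielParams | None = None) -> list[LDBlock]:
    """Call LD blocks from pairwise D' confidence intervals.

    A candidate interval qualifies when its outermost pair is in strong
    LD and strong-LD pairs make up at least `informative_fraction` of
    its informative (strong LD + strong recombination) pairs.  Qualifying
    intervals are selected greedily, longest first, leftmost on ties,
    without overlap.  Works per chromosome; `pairs` must contain every
    pair among the candidate SNPs of each chromosome.
    """
    params = params or GabrielParams()
    blocks: list[LDBlock] = []
    cls = {(r["snp_i"], r["snp_j"]): _classify(r, params)
           for _, r in pairs.iterrows()}

    for chrom, grp in snp_map.groupby("chromosome", sort=True):
        snps = list(grp.sort_values("pos_cm")["snp"])
        m = len(snps)
        if m < 2:
            continue

        def pair_class(a: int, b: int) -> str:
            key = (snps[a], snps[b])
            if key in cls:
                return cls[key]
            return cls.get((snps[b], snps[a]), "uninformative")

        candidates = []  # (length, start, end)
        for a in range(m - 1):
            for b in range(a + 1, m):
                if pair_class(a, b) != "strong_ld":
                    continue
                n_strong = n_recomb = 0
                for i in range(a, b + 1):
                    for j in range(i + 1, b + 1):
                        c = pair_class(i, j)
                        if c == "strong_ld":
                            n_strong += 1
                        elif c == "strong_recomb":
                            n_recomb += 1
                informative = n_strong + n_recomb
                if informative == 0:
                    continue
                if n_strong / informative >= params.informative_fraction:
                    candidates.append((b - a, a, b, n_strong, informative))

        # greedy: longest span first, leftmost on ties
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(m, bool)
        for _, a, b, n_strong, informative in candidates:
            if taken[a:b + 1].any():
                continue
            taken[a:b + 1] = True
            blocks.append(LDBlock(
                chromosome=int(chrom), first_snp=snps[a], last_snp=snps[b],
                members=tuple(snps[a:b + 1]),
                n_strong_ld_pairs=n_strong, n_informative_pairs=informative))

    blocks.sort(key=lambda blk: (blk.chromosome,
                                 list(snp_map["snp"]).index(blk.first_snp)))
    return blocks
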