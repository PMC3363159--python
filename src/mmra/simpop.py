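"""Synthetic two-generation half-sib population with LD-bearing genotypes.

Emulates the statistical structure of a classic QTL-mapping benchmark
population: 20 sires each mated to 10 unrelated dams, 15 progeny per dam
(10 phenotyped), every individual genotyped for 9,990 SNPs on 5
chromosomes of 1 Morgan, with a causal architecture of one large additive
QTN, two linked additive pairs (coupling and repulsion phase), one
paternally expressed imprinted QTN and one epistatic pair, at trait
heritability ~0.30.

Founder haplotypes are mosaics of a small pool of ancestral haplotypes
(Markov switching along the map), which produces both long-range linkage
disequilibrium and a sizeable fraction of monomorphic markers without a
forward-in-time burn-in.  Gametes are dropped down the pedigree with
recombination under the Haldane map function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QtnSpec, SimulationConfig
from .genotypes import GenotypeMatrix, PhasedGenotypes, make_snp_map
from .pedigree import Pedigree

__all__ = [
    "simulate_pedigree", "simulate_founder_haplotypes", "drop_genes",
    "assign_genetic_values", "simulate_phenotypes", "simulate_population",
    "solve_phenotype_variances",
    "SimulatedPopulation", "haldane_recomb_fraction", "qtn_truth_table",
]


def haldane_recomb_fraction(d_morgan: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for map distance d (Morgan): 0.5*(1 - exp(-2d))."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgan, dtype=float)))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Build the mating design: each sire x its block of dams, fixed progeny count.

    Founders (sires then dams) come first with unknown parents; every dam
    is mated to exactly one sire; record order is parents before offspring.
    """
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    for s in range(1, config.n_sires + 1):
        ids.append(f"S{s}")
        sires.append("0")
        dams.append("0")
    for d in range(1, config.n_dams + 1):
        ids.append(f"D{d}")
        sires.append("0")
        dams.append("0")
    prog = 0
    for d in range(1, config.n_dams + 1):
        mate = (d - 1) // config.n_dams_per_sire + 1  # sire of this dam's family
        for _ in range(config.n_progeny_per_dam):
            prog += 1
            ids.append(f"P{prog}")
            sires.append(f"S{mate}")
            dams.append(f"D{d}")
    return Pedigree(ids, sires, dams)


def _ancestral_pool(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Ancestral haplotypes (K, m) with alleles 1/2.

    Per-SNP allele-2 frequencies are drawn from Beta(0.5, 0.5): the
    U-shape makes ~1/3 of markers monomorphic within a 10-haplotype pool,
    matching the large monomorphic fraction such SNP panels show.
    Causal loci are redrawn from Beta(2, 2) until polymorphic so the
    default architecture always segregates.
    """
    K, m = config.n_ancestral_haplotypes, config.n_snps
    freq = rng.beta(0.5, 0.5, size=m)
    pool = (rng.random((K, m)) < freq[None, :]).astype(np.int8) + 1

    for col in _qtn_columns(config):
        guard = 0
        while len(np.unique(pool[:, col])) < 2:
            pool[:, col] = (rng.random(K) < rng.beta(2.0, 2.0)).astype(np.int8) + 1
            guard += 1
            if guard > 100:  # impossible unless K == 1
                break
    _enforce_linkage_phase(pool, config)
    return pool


def _qtn_columns(config: SimulationConfig) -> list[int]:
    cols = []
    for q in config.qtn_spec:
        base = (q.chromosome - 1) * config.snps_per_chromosome
        cols.append(base + q.snp_index - 1)
        if q.partner_snp is not None:
            cols.append(base + q.partner_snp - 1)
    return cols


def _enforce_linkage_phase(pool: np.ndarray, config: SimulationConfig) -> None:
    """Relabel alleles so linked QTN pairs sit in the annotated phase.

    For a chromosome carrying two additive QTN tagged "coupling", the
    gametic disequilibrium D between their allele-2 indicators in the
    ancestral pool is forced non-negative (trait-raising alleles on the
    same haplotypes); "repulsion" forces it non-positive.  Only the
    second locus's labels are flipped, so single-locus frequencies are
    unchanged.
    """
    by_phase: dict[tuple[int, str], list[int]] = {}
    for q in config.qtn_spec:
        if q.action == "additive" and q.phase_note in ("coupling", "repulsion"):
            col = (q.chromosome - 1) * config.snps_per_chromosome + q.snp_index - 1
            by_phase.setdefault((q.chromosome, q.phase_note), []).append(col)
    for (_, phase), cols in by_phase.items():
        if len(cols) != 2:
            continue
        a, b = cols
        xa = (pool[:, a] == 2).astype(float)
        xb = (pool[:, b] == 2).astype(float)
        D = np.mean(xa * xb) - xa.mean() * xb.mean()
        if (phase == "coupling" and D < 0) or (phase == "repulsion" and D > 0):
            pool[:, b] = 3 - pool[:, b]


def simulate_founder_haplotypes(config: SimulationConfig,
                                rng: np.random.Generator) -> PhasedGenotypes:
    """Founder (sire + dam) haplotypes as ancestral-haplotype mosaics.

    Each of the 2*(n_sires + n_dams) founder haplotypes follows a Markov
    chain over the ancestral pool: between adjacent SNPs the chain
    switches to a uniformly drawn ancestor with probability
    1 - exp(-rate * d_cM).
    """
    pool = _ancestral_pool(config, rng)
    snp_map = make_snp_map(config.n_chromosomes, config.snps_per_chromosome,
                           config.chromosome_length)
    n_f = config.n_sires + config.n_dams
    n_hap = 2 * n_f
    K = config.n_ancestral_haplotypes

    haps = np.empty((n_hap, config.n_snps), dtype=np.int8)
    for c in range(1, config.n_chromosomes + 1):
        sel = snp_map["chromosome"].to_numpy() == c
        cols = np.flatnonzero(sel)
        pos = snp_map.loc[sel, "pos_cm"].to_numpy()
        m = len(cols)
        p_switch = 1.0 - np.exp(-config.ancestral_switch_rate * np.diff(pos))

        start = rng.integers(K, size=n_hap)
        switch = rng.random((n_hap, m - 1)) < p_switch[None, :]
        new_anc = rng.integers(K, size=(n_hap, m - 1))

        candidates = np.concatenate([start[:, None], new_anc], axis=1)
        keep = np.concatenate(
            [np.ones((n_hap, 1), bool), switch], axis=1)
        src = np.where(keep, np.arange(m)[None, :], 0)
        src = np.maximum.accumulate(src, axis=1)
        anc = np.take_along_axis(candidates, src, axis=1)
        haps[:, cols] = pool[anc, cols[None, :]]

    ids = [f"S{s}" for s in range(1, config.n_sires + 1)] + \
          [f"D{d}" for d in range(1, config.n_dams + 1)]
    return PhasedGenotypes(haps.reshape(n_f, 2, config.n_snps), ids, snp_map)


def _meiosis(parent_haps: np.ndarray, r_adj: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Gametes (n, m) from parents' phased chromosomes (n, 2, m).

    A crossover occurs independently in each marker interval with the
    Haldane probability `r_adj`; the starting strand is uniform.
    """
    n, _, m = parent_haps.shape
    start = rng.integers(2, size=n)
    switch = rng.random((n, m - 1)) < r_adj[None, :]
    strand = (start[:, None] + np.concatenate(
        [np.zeros((n, 1), np.int64), np.cumsum(switch, axis=1)], axis=1)) % 2
    return np.take_along_axis(
        parent_haps, strand[:, None, :], axis=1)[:, 0, :]


def drop_genes(pedigree: Pedigree, founder_haps: PhasedGenotypes,
               snp_map: pd.DataFrame, rng: np.random.Generator) -> PhasedGenotypes:
    """Gene dropping: phased genotypes for every pedigree member.

    Founders take their haplotypes from `founder_haps`; each non-founder
    receives one recombinant gamete from its sire (paternal slot) and one
    from its dam (maternal slot), with crossovers under the Haldane map
    function.  Raises if a non-founder has any unknown parent.
    """
    n = len(pedigree)
    m = len(snp_map)
    sire_idx, dam_idx = pedigree.parent_indices()
    founder_row = {ind: i for i, ind in enumerate(founder_haps.ids)}

    haps = np.zeros((n, 2, m), dtype=np.int8)
    chrom = snp_map["chromosome"].to_numpy()
    pos_cm = snp_map["pos_cm"].to_numpy()

    max_gen = int(pedigree.generation.max())
    for g in range(max_gen + 1):
        members = np.flatnonzero(pedigree.generation == g)
        founders = members[(sire_idx[members] < 0) & (dam_idx[members] < 0)]
        nonfound = members[(sire_idx[members] >= 0) | (dam_idx[members] >= 0)]
        for i in founders:
            try:
                haps[i] = founder_haps.haplotypes[founder_row[pedigree.ids[i]]]
            except KeyError:
                raise ValueError(
                    f"founder {pedigree.ids[i]!r} has no simulated haplotypes")
        if len(nonfound) == 0:
            continue
        if np.any(sire_idx[nonfound] < 0) or np.any(dam_idx[nonfound] < 0):
            bad = nonfound[(sire_idx[nonfound] < 0) | (dam_idx[nonfound] < 0)][0]
            raise ValueError(
                f"non-founder {pedigree.ids[bad]!r} lacks a genotyped parent")
        for c in np.unique(chrom):
            cols = np.flatnonzero(chrom == c)
            d_morgan = np.diff(pos_cm[cols]) / 100.0
            r_adj = np.asarray(haldane_recomb_fraction(d_morgan))
            pat = _meiosis(haps[sire_idx[nonfound]][:, :, cols], r_adj, rng)
            mat = _meiosis(haps[dam_idx[nonfound]][:, :, cols], r_adj, rng)
            haps[np.ix_(nonfound, [0], cols)] = pat[:, None, :]
            haps[np.ix_(nonfound, [1], cols)] = mat[:, None, :]

    return PhasedGenotypes(haps, list(pedigree.ids), snp_map)


def assign_genetic_values(phased: PhasedGenotypes, qtn_spec: list[QtnSpec],
                          snps_per_chromosome: int) -> np.ndarray:
    """Per-individual genetic value from the causal architecture.

    additive            effect * (number of copies of allele 2)
    imprinted_paternal  effect if allele 2 sits on the paternal haplotype
    epistatic_pair      effect if >= 1 copy of allele 2 at BOTH partner loci
    Contributions sum across QTN.
    """
    h = phased.haplotypes
    g = np.zeros(h.shape[0])
    for q in qtn_spec:
        col = (q.chromosome - 1) * snps_per_chromosome + q.snp_index - 1
        if col >= h.shape[2]:
            raise ValueError(f"QTN column {col} outside genotype matrix")
        if q.action == "additive":
            g += q.effect * (h[:, :, col] == 2).sum(axis=1)
        elif q.action == "imprinted_paternal":
            g += q.effect * (h[:, 0, col] == 2)
        elif q.action == "epistatic_pair":
            pcol = (q.chromosome - 1) * snps_per_chromosome + q.partner_snp - 1
            if pcol >= h.shape[2]:
                raise ValueError(f"partner QTN column {pcol} outside matrix")
            carrier_a = (h[:, :, col] == 2).any(axis=1)
            carrier_b = (h[:, :, pcol] == 2).any(axis=1)
            g += q.effect * (carrier_a & carrier_b)
    return g


def solve_phenotype_variances(genetic_values: np.ndarray,
                              is_progeny: np.ndarray,
                              config: SimulationConfig
                              ) -> tuple[float, float]:
    """(sigma_poly2, sigma_e2) calibrated to the target heritability.

    Polygenic variance is set so that `polygenic_fraction` of the total
    genetic variance is polygenic given the realised QTN variance among
    progeny; residual variance then makes genetic/total = target_h2.
    """
    v_qtn = float(np.var(genetic_values[is_progeny])) if is_progeny.any() else 0.0
    f = config.polygenic_fraction
    if v_qtn > 0:
        sigma_poly2 = v_qtn * f / (1.0 - f)
    else:
        sigma_poly2 = 1.0 if f > 0 else 0.0
    v_g = v_qtn + sigma_poly2
    h2 = config.target_h2
    sigma_e2 = v_g * (1.0 - h2) / h2 if v_g > 0 else 1.0
    return sigma_poly2, sigma_e2


def simulate_phenotypes(pedigree: Pedigree, genetic_values: np.ndarray,
                        config: SimulationConfig, rng: np.random.Generator,
                        sigma_poly2: float | None = None,
                        sigma_e2: float | None = None) -> pd.DataFrame:
    """Phenotypes for the chosen progeny subset; parents stay unphenotyped.

    phenotype = mean + QTN value + polygenic effect + N(0, sigma_e2).
    The polygenic effect follows the pedigree: founders ~ N(0, sigma_p2),
    descendants = midparent + Mendelian sampling N(0, sigma_p2 / 2).
    Unless given explicitly, sigma_p2 and sigma_e2 are solved from the
    realised QTN variance so that total genetic variance / total variance
    equals `target_h2` with `polygenic_fraction` of the genetic variance
    polygenic.  Exactly `n_phenotyped_per_dam` progeny per dam are drawn
    uniformly at random.

    Returns a DataFrame with columns ``id`` and ``value``.
    """
    if not 0.0 < config.target_h2 < 1.0:
        raise ValueError("target_h2 must lie strictly inside (0, 1)")
    n = len(pedigree)
    sire_idx, dam_idx = pedigree.parent_indices()
    is_progeny = (sire_idx >= 0) & (dam_idx >= 0)

    solved_poly, solved_e = solve_phenotype_variances(
        genetic_values, is_progeny, config)
    if sigma_poly2 is None:
        sigma_poly2 = solved_poly
    if sigma_e2 is None:
        sigma_e2 = solved_e

    poly = np.zeros(n)
    for g in range(int(pedigree.generation.max()) + 1):
        members = np.flatnonzero(pedigree.generation == g)
        founders = members[~is_progeny[members]]
        offspring = members[is_progeny[members]]
        poly[founders] = rng.normal(0.0, np.sqrt(sigma_poly2), size=len(founders))
        if len(offspring):
            mid = 0.5 * (poly[sire_idx[offspring]] + poly[dam_idx[offspring]])
            poly[offspring] = mid + rng.normal(
                0.0, np.sqrt(sigma_poly2 / 2.0), size=len(offspring))

    # draw the phenotyped subset per dam
    chosen: list[int] = []
    prog_by_dam: dict[int, list[int]] = {}
    for i in np.flatnonzero(is_progeny):
        prog_by_dam.setdefault(dam_idx[i], []).append(i)
    for d in sorted(prog_by_dam):
        sibs = np.asarray(prog_by_dam[d])
        k = min(config.n_phenotyped_per_dam, len(sibs))
        chosen.extend(sorted(rng.choice(sibs, size=k, replace=False)))
    chosen = np.asarray(chosen, dtype=np.intp)

    y = (config.overall_mean + genetic_values[chosen] + poly[chosen]
         + rng.normal(0.0, np.sqrt(sigma_e2), size=len(chosen)))
    return pd.DataFrame({"id": [pedigree.ids[i] for i in chosen], "value": y})


def qtn_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """The simulated causal loci as a tidy table (for power evaluation)."""
    step_cm = config.chromosome_length * 100.0 / config.snps_per_chromosome
    rows = []
    for q in config.qtn_spec:
        rows.append({
            "chromosome": q.chromosome, "snp_index": q.snp_index,
            "pos_cm": q.snp_index * step_cm, "action": q.action,
            "effect": q.effect, "partner_snp": q.partner_snp or "",
            "phase": q.phase_note,
        })
    return pd.DataFrame(rows)


@dataclass
class SimulatedPopulation:
    """Everything one simulation run produces."""

    config: SimulationConfig
    pedigree: Pedigree
    phased: PhasedGenotypes
    genotypes: GenotypeMatrix
    snp_map: pd.DataFrame
    trait: pd.DataFrame          # columns id, value (phenotyped progeny only)
    genetic_values: np.ndarray   # QTN genetic value per pedigree member
    qtn: pd.DataFrame            # truth table


def simulate_population(config: SimulationConfig,
                        seed: int | None = None) -> SimulatedPopulation:
    """Run the full generator: pedigree, haplotypes, genotypes, phenotypes.

    A single Generator seeded from `seed` (default: ``config.seed``)
    drives every stochastic step in a fixed order, so runs are exactly
    reproducible.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ped = simulate_pedigree(config)
    founders = simulate_founder_haplotypes(config, rng)
    phased = drop_genes(ped, founders, founders.snp_map, rng)
    g = assign_genetic_values(phased, config.qtn_spec, config.snps_per_chromosome)
    trait = simulate_phenotypes(ped, g, config, rng)
    return SimulatedPopulation(
        config=config, pedigree=ped, phased=phased,
        genotypes=phased.to_genotype_matrix(), snp_map=founders.snp_map,
        trait=trait, genetic_values=g, qtn=qtn_truth_table(config))
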