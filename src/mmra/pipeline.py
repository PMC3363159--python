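"""End-to-end pipeline: simulate/load -> QC -> REML -> scan -> permutation
threshold -> LD blocks, in the published analysis order."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import SimulationConfig
from .genotypes import GenotypeMatrix
from .ld import GabrielParams, LDBlock, gabriel_blocks, pairwise_ld
from .pedigree import Pedigree, build_A, read_pedigree, write_pedigree
from .permutation import (PermutationNull, declare_significant,
                          empirical_threshold, max_statistic_null)
from .qc import QcReport, filter_snps, restrict_individuals
from .reml import VarianceComponents, build_spectral_cache, incidence_Z, \
    estimate_variance_components
from .scan import ScanEngine, ScanResult, bonferroni_threshold, scan
from .simpop import simulate_population

log = logging.getLogger("mmra")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs for one pipeline run.

    Exactly one of `simulation` or the (pedigree_path, genotype paths,
    phenotype_path) file set must be provided.
    """

    simulation: SimulationConfig | None = None
    pedigree_path: str | None = None
    ped_path: str | None = None          # PLINK .ped (with map_path)
    map_path: str | None = None
    genotype_tsv: str | None = None      # native TSV (with map_path)
    phenotype_path: str | None = None
    maf_threshold: float = 0.03
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    workers: int = 1
    gabriel: GabrielParams = field(default_factory=GabrielParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.pedigree_path is not None and \
            self.phenotype_path is not None and \
            (self.ped_path is not None or self.genotype_tsv is not None)
        if (self.simulation is None) == (not has_files):
            raise ValueError("provide exactly one of: a simulation config, "
                             "or pedigree+genotype+phenotype paths")


@dataclass
class PipelineResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix        # post-QC, analysis individuals
    qc: QcReport
    vc: VarianceComponents
    scan: ScanResult
    null: PermutationNull
    perm_threshold: float
    bonferroni_p: float
    significant: pd.DataFrame
    tally: pd.Series
    blocks: list[LDBlock]
    manifest: dict


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        pop = simulate_population(cfg.simulation, seed=cfg.seed)
        return pop.pedigree, pop.genotypes, pop.trait
    ped = read_pedigree(cfg.pedigree_path)
    trait = mio.read_phenotypes(cfg.phenotype_path)
    if cfg.ped_path is not None:
        geno = mio.read_plink_text(cfg.ped_path, cfg.map_path)
    else:
        snp_map = mio.read_snp_map(cfg.map_path)
        geno = mio.read_genotype_tsv(cfg.genotype_tsv, snp_map)
    return ped, geno, trait


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write all artifacts to disk.

    Stage order is fixed: individual restriction and marker QC precede
    the REML fit, whose variance components are then fixed for the scan
    and for every permuted rescan; LD blocks are called among the
    significant SNPs.  Any stage failure is re-raised with the stage name.
    """
    timings: dict[str, float] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-12s %8.2fs", name, timings[name])
        return out

    pedigree, genotypes, trait = stage("load", lambda: _load_inputs(cfg))

    # analysis set: phenotyped individuals plus all parents
    def _qc():
        parent_ids = [i for i, s, d in zip(pedigree.ids, pedigree.sire,
                                           pedigree.dam)
                      if s == "0" and d == "0"]
        keep = parent_ids + [i for i in trait["id"] if i not in set(parent_ids)]
        restricted = restrict_individuals(genotypes, keep)
        return filter_snps(restricted, cfg.maf_threshold)

    geno_qc, qc_report = stage("qc", _qc)

    A = stage("relmat", lambda: build_A(pedigree))
    phen_idx = incidence_Z(pedigree, trait)
    cache = stage("spectral", lambda: build_spectral_cache(A, phen_idx))
    vc = stage("reml", lambda: estimate_variance_components(
        trait, A, pedigree, cache=cache))

    engine = ScanEngine(geno_qc, trait, pedigree, A, vc, cache=cache)
    scan_result = stage("scan", lambda: scan(
        geno_qc, trait, pedigree, A, vc, engine=engine))

    y = trait["value"].to_numpy(dtype=float)
    null = stage("permute", lambda: max_statistic_null(
        engine, y, cfg.n_perm, cfg.seed, cfg.workers))
    threshold = empirical_threshold(null, cfg.alpha)
    bonf_p = bonferroni_threshold(cfg.alpha, scan_result.n_snps)
    significant, tally = declare_significant(scan_result, threshold)

    def _blocks():
        out: list[LDBlock] = []
        for chrom in sorted(significant["chromosome"].unique()):
            snps = list(significant.loc[significant["chromosome"] == chrom]
                        .sort_values("pos_cm")["snp"])
            if len(snps) < 2:
                continue
            pairs = pairwise_ld(geno_qc, snps)
            sub_map = geno_qc.snp_map[geno_qc.snp_map["snp"].isin(snps)]
            out.extend(gabriel_blocks(pairs, sub_map, cfg.gabriel))
        return out

    blocks = stage("blocks", _blocks)

    manifest = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "maf_threshold": cfg.maf_threshold,
        "workers": cfg.workers,
        "threshold_convention": "ceil((1-alpha)*n_perm)-th smallest max "
                                "Wald; significance requires strict excess",
        "perm_wald_threshold": threshold,
        "bonferroni_p_threshold": bonf_p,
        "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2, "h2": vc.h2,
        "n_individuals": scan_result.n_individuals,
        "n_snps_tested": scan_result.n_snps,
        "timings_s": timings,
        "simulation": (cfg.simulation.to_dict() if cfg.simulation else None),
    }

    result = PipelineResult(
        pedigree=pedigree, genotypes=geno_qc, qc=qc_report, vc=vc,
        scan=scan_result, null=null, perm_threshold=threshold,
        bonferroni_p=bonf_p, significant=significant, tally=tally,
        blocks=blocks, manifest=manifest)

    if cfg.out_dir is not None:
        _write_artifacts(result, cfg, Path(cfg.out_dir))
    return result


def _write_artifacts(res: PipelineResult, cfg: PipelineConfig,
                     out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(res.pedigree, out / "pedigree.tsv")
    (out / "qc_report.txt").write_text(res.qc.summary())
    res.scan.records.to_csv(out / "scan.tsv", sep="\t", index=False)
    np.savetxt(out / "perm_max_wald.tsv", res.null.max_wald, fmt="%.6f")
    res.significant.to_csv(out / "significant_snps.tsv", sep="\t", index=False)
    res.tally.to_csv(out / "per_chromosome_counts.tsv", sep="\t")
    with open(out / "ld_blocks.tsv", "w") as fh:
        fh.write("chromosome\tfirst_snp\tlast_snp\tn_snps\t"
                 "n_strong_ld_pairs\tn_informative_pairs\n")
        for blk in res.blocks:
            fh.write(f"{blk.chromosome}\t{blk.first_snp}\t{blk.last_snp}\t"
                     f"{len(blk.members)}\t{blk.n_strong_ld_pairs}\t"
                     f"{blk.n_informative_pairs}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
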