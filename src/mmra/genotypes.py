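"""In-memory containers for SNP genotypes, marker maps and phased haplotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhasedGenotypes", "make_snp_map", "validate_snp_map"]


def make_snp_map(n_chromosomes: int, snps_per_chromosome: int,
                 chromosome_length: float = 1.0) -> pd.DataFrame:
    """Evenly spaced marker map: SNP k (1-based) sits at k*(L/m) Morgan.

    Under the defaults (1 Morgan, 1,998 SNPs) the first SNP of each
    chromosome is at 0.05 cM and the last at 100 cM.  Returns a DataFrame
    with columns ``snp`` (id "C<c>S<k>"), ``chromosome`` (1-based) and
    ``pos_cm``.
    """
    step_cm = chromosome_length * 100.0 / snps_per_chromosome
    k = np.arange(1, snps_per_chromosome + 1)
    frames = []
    for c in range(1, n_chromosomes + 1):
        frames.append(pd.DataFrame({
            "snp": [f"C{c}S{i}" for i in k],
            "chromosome": c,
            "pos_cm": k * step_cm,
        }))
    return pd.concat(frames, ignore_index=True)


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    """Check required columns and strictly increasing positions per chromosome."""
    for col in ("snp", "chromosome", "pos_cm"):
        if col not in snp_map.columns:
            raise ValueError(f"snp map lacks column {col!r}")
    for c, grp in snp_map.groupby("chromosome", sort=False):
        pos = grp["pos_cm"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            bad = int(np.argmax(np.diff(pos) <= 0)) + 1
            raise ValueError(
                f"positions not strictly increasing on chromosome {c} "
                f"(map row {grp.index[bad]})")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes: count of allele "2" (0, 1 or 2).

    Rows are keyed to pedigree ids, columns to the marker map.  No missing
    values are representable; the simulator genotypes every individual.
    """

    codes: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D individuals x SNPs array")
        if self.codes.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of ids")
        if self.codes.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match the SNP map")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 2):
            raise ValueError("genotype codes must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def row_index(self, ids) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.ids)}
        try:
            return np.asarray([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not genotyped") from None


@dataclass
class PhasedGenotypes:
    """Two haplotypes per individual with parental-origin labels.

    ``haplotypes`` has shape (n_individuals, 2, n_snps) with alleles coded
    1/2; axis 1 index 0 is the paternally inherited haplotype and index 1
    the maternally inherited one (for founders the labels are arbitrary
    but fixed).
    """

    haplotypes: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.ndim != 3 or h.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if h.shape[0] != len(self.ids):
            raise ValueError("haplotype rows do not match ids")
        if h.size and not np.isin(h, (1, 2)).all():
            raise ValueError("alleles must be coded 1/2")
        self.haplotypes = h

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def collapse(self) -> np.ndarray:
        """Unphased codes: count of allele 2 per individual and SNP."""
        return (self.haplotypes == 2).sum(axis=1).astype(np.int8)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.collapse(), list(self.ids), self.snp_map)
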