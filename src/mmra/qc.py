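"""Marker quality control: minor-allele frequencies and the two-stage filter.

The analysis set is restricted first (unphenotyped progeny dropped, parents
kept), MAF is then computed on the retained individuals, and markers are
removed in two classes: monomorphic (MAF = 0) and low-MAF (0 < MAF <
threshold, strict).  Genotype codes are re-oriented after restriction so
that the code always counts the minor allele in the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["QcReport", "restrict_individuals", "minor_allele_frequency",
           "filter_snps"]


@dataclass(frozen=True)
class QcReport:
    """Bookkeeping of the marker filter; counts partition the input."""

    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_retained: int
    retained_index: np.ndarray

    def __post_init__(self) -> None:
        if self.n_input != self.n_monomorphic + self.n_low_maf + self.n_retained:
            raise ValueError("QC counts do not partition the input markers")

    def summary(self) -> str:
        return (f"markers in: {self.n_input}\n"
                f"removed monomorphic (MAF = 0): {self.n_monomorphic}\n"
                f"removed low MAF: {self.n_low_maf}\n"
                f"retained: {self.n_retained}\n")


def restrict_individuals(genotypes: GenotypeMatrix, keep_ids) -> GenotypeMatrix:
    """Restrict rows to `keep_ids` (order preserved as given)."""
    keep_ids = list(keep_ids)
    if len(keep_ids) == 0:
        raise ValueError("empty analysis set: no individuals to keep")
    rows = genotypes.row_index(keep_ids)
    return GenotypeMatrix(genotypes.codes[rows], keep_ids, genotypes.snp_map)


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF of one genotype column of codes 0/1/2: min(p2, 1 - p2)."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty genotype column")
    p2 = column.sum() / (2.0 * column.size)
    return float(min(p2, 1.0 - p2))


def filter_snps(genotypes: GenotypeMatrix, maf_threshold: float = 0.03
                ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop monomorphic and low-MAF markers; recode to minor-allele counts.

    A marker is monomorphic when every retained individual carries the
    same genotype; low-MAF when 0 < MAF < `maf_threshold` (a MAF exactly
    equal to the threshold is retained).  Columns whose allele "2" is the
    major allele in the analysis set are flipped (code -> 2 - code) so
    retained codes always count the minor allele.  The SNP map stays
    aligned with the retained columns.
    """
    if not 0.0 <= maf_threshold < 0.5:
        raise ValueError("maf_threshold must lie in [0, 0.5)")
    codes = genotypes.codes
    n = codes.shape[0]
    p2 = codes.sum(axis=0) / (2.0 * n)
    maf = np.minimum(p2, 1.0 - p2)

    mono = maf == 0.0
    low = (~mono) & (maf < maf_threshold)
    keep = ~(mono | low)
    retained_idx = np.flatnonzero(keep)

    kept = codes[:, keep].astype(np.int8)
    flip = p2[keep] > 0.5
    kept[:, flip] = 2 - kept[:, flip]

    report = QcReport(
        n_input=codes.shape[1],
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low.sum()),
        n_retained=int(keep.sum()),
        retained_index=retained_idx,
    )
    kept_map = genotypes.snp_map.iloc[retained_idx].reset_index(drop=True)
    return GenotypeMatrix(kept, list(genotypes.ids), kept_map), report
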