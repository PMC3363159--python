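"""Readers and writers: pedigree TSV, native genotype TSV, PLINK-style
.ped/.map text, phenotype TSV, and the simulator's truth file.

The native interchange format is a plain TSV of genotype codes
(individuals x SNPs, values 0/1/2) with a separate 3-column map; PLINK
text (.ped/.map, alleles coded 1/2, no missing codes) is supported as a
convenience for tools that expect it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhasedGenotypes, validate_snp_map

__all__ = ["read_plink_text", "write_plink_text", "read_genotype_tsv",
           "write_genotype_tsv", "read_phenotypes", "write_phenotypes",
           "read_snp_map", "write_snp_map"]


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    """PLINK .map: chromosome, SNP id, cM position, bp column = marker index."""
    with open(path, "w") as fh:
        for k, row in enumerate(snp_map.itertuples(index=False), 1):
            fh.write(f"{row.chromosome}\t{row.snp}\t{row.pos_cm}\t{k}\n")


def read_snp_map(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 map columns")
            rows.append({"snp": parts[1], "chromosome": int(parts[0]),
                         "pos_cm": float(parts[2])})
    snp_map = pd.DataFrame(rows)
    try:
        validate_snp_map(snp_map)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    return snp_map


def write_plink_text(genotypes: GenotypeMatrix | PhasedGenotypes,
                     ped_path: str | Path, map_path: str | Path,
                     pedigree=None) -> None:
    """PLINK-style .ped/.map with alleles coded 1/2.

    Unphased codes are written as sorted allele pairs (0 -> "1 1",
    1 -> "1 2", 2 -> "2 2"); phased input preserves haplotype order.
    Family id is fixed at 1; parental ids come from `pedigree` when given.
    """
    if isinstance(genotypes, PhasedGenotypes):
        ids = genotypes.ids
        a1 = genotypes.haplotypes[:, 0, :]
        a2 = genotypes.haplotypes[:, 1, :]
        snp_map = genotypes.snp_map
    else:
        ids = genotypes.ids
        codes = genotypes.codes
        a1 = np.where(codes >= 1, 2, 1)
        a2 = np.where(codes == 2, 2, 1)
        snp_map = genotypes.snp_map
    parents = {}
    if pedigree is not None:
        parents = {i: (s, d) for i, s, d in
                   zip(pedigree.ids, pedigree.sire, pedigree.dam)}
    write_snp_map(snp_map, map_path)
    with open(ped_path, "w") as fh:
        for r, ind in enumerate(ids):
            sire, dam = parents.get(ind, ("0", "0"))
            geno = " ".join(f"{x} {y}" for x, y in zip(a1[r], a2[r]))
            fh.write(f"1 {ind} {sire} {dam} 0 -9 {geno}\n")


def read_plink_text(ped_path: str | Path, map_path: str | Path
                    ) -> GenotypeMatrix:
    """Read PLINK text genotypes into codes = count of allele "2".

    Raises on any allele symbol outside {1, 2} — including PLINK's "0"
    missing code, which the pipeline's complete-data contract excludes.
    """
    snp_map = read_snp_map(map_path)
    m = len(snp_map)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"for {m} SNPs, got {len(parts)}")
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype="U2")
            if not np.isin(alleles, ("1", "2")).all():
                bad = alleles[~np.isin(alleles, ("1", "2"))][0]
                raise ValueError(
                    f"{ped_path}:{lineno}: allele symbol {bad!r} outside "
                    f"{{1,2}} (missing genotypes are not supported)")
            codes = (alleles.reshape(m, 2) == "2").sum(axis=1)
            rows.append(codes.astype(np.int8))
    return GenotypeMatrix(np.vstack(rows), ids, snp_map)


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Native TSV: header of SNP ids, one row per individual (id + codes)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(genotypes.snp_map["snp"]) + "\n")
        for ind, row in zip(genotypes.ids, genotypes.codes):
            fh.write(ind + "\t" + "\t".join(map(str, row)) + "\n")


def read_genotype_tsv(path: str | Path, snp_map: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(snp_map["snp"]):
        raise ValueError(f"{path}: SNP columns do not match the map")
    return GenotypeMatrix(df.to_numpy(dtype=np.int8), list(df.index.astype(str)),
                          snp_map)


def write_phenotypes(trait: pd.DataFrame, path: str | Path) -> None:
    trait[["id", "value"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'id' and 'value'")
    if df["value"].isna().any():
        raise ValueError(f"{path}: missing phenotype values are not supported")
    return df[["id", "value"]]
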