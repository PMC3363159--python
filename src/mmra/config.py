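"""Configuration objects for the population simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["QtnSpec", "SimulationConfig", "default_qtn_spec"]

_ACTIONS = ("additive", "imprinted_paternal", "epistatic_pair")


@dataclass(frozen=True)
class QtnSpec:
    """One causal locus (QTN) placed on the simulated map.

    Parameters
    ----------
    chromosome : int
        1-based chromosome number.
    snp_index : int
        1-based marker index within the chromosome.
    action : str
        ``additive`` — effect per copy of allele 2 (allele substitution);
        ``imprinted_paternal`` — effect only when allele 2 is carried on the
        paternally inherited haplotype;
        ``epistatic_pair`` — effect only when the individual carries at
        least one copy of allele 2 at both this locus and ``partner_snp``.
    effect : float
        Trait-unit size of the contribution described above.
    partner_snp : int, optional
        Partner locus (same chromosome) for ``epistatic_pair`` only.
    phase_note : str
        Free-text annotation (e.g. "coupling"/"repulsion" for linked pairs).
    """

    chromosome: int
    snp_index: int
    action: str
    effect: float
    partner_snp: int | None = None
    phase_note: str = ""

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"unknown QTN action {self.action!r}")
        if self.action == "epistatic_pair" and self.partner_snp is None:
            raise ValueError("epistatic_pair requires partner_snp")
        if self.action != "epistatic_pair" and self.partner_snp is not None:
            raise ValueError(f"{self.action} must not carry a partner_snp")
        if self.snp_index < 1:
            raise ValueError("snp_index is 1-based and must be >= 1")


def default_qtn_spec() -> list[QtnSpec]:
    """The default causal architecture, mirroring the benchmark design.

    One large additive QTN on chromosome 1; two additive QTN in coupling
    phase on chromosome 2 and two in repulsion phase on chromosome 3; one
    paternally expressed (imprinted) QTN on chromosome 4; one epistatic
    pair on chromosome 5.  Effect sizes are package defaults (the true
    benchmark values were never published) calibrated so the chromosome-1
    QTN explains roughly 10% of phenotypic variance and the other additive
    QTN 2-4% each at heritability 0.30.
    """
    return [
        QtnSpec(1, 57, "additive", 4.0),
        QtnSpec(2, 1638, "additive", 2.0, phase_note="coupling"),
        QtnSpec(2, 1875, "additive", 2.0, phase_note="coupling"),
        QtnSpec(3, 100, "additive", 2.0, phase_note="repulsion"),
        QtnSpec(3, 300, "additive", 2.0, phase_note="repulsion"),
        QtnSpec(4, 1000, "imprinted_paternal", 2.5),
        QtnSpec(5, 600, "epistatic_pair", 2.5, partner_snp=1400),
    ]


@dataclass
class SimulationConfig:
    """Design of the simulated two-generation half-sib population.

    Defaults reproduce the benchmark population structure: 20 sires each
    mated to 10 dams, 15 progeny per dam (10 of them phenotyped), giving
    3,220 individuals of which 2,000 carry phenotypes; 5 chromosomes of
    1 Morgan carrying 1,998 evenly spaced SNPs each (9,990 markers).
    """

    n_sires: int = 20
    n_dams_per_sire: int = 10
    n_progeny_per_dam: int = 15
    n_phenotyped_per_dam: int = 10
    n_chromosomes: int = 5
    snps_per_chromosome: int = 1998
    chromosome_length: float = 1.0  # Morgan
    qtn_spec: list[QtnSpec] = field(default_factory=default_qtn_spec)
    target_h2: float = 0.30
    polygenic_fraction: float = 0.30  # share of genetic variance not from QTN
    n_ancestral_haplotypes: int = 10
    ancestral_switch_rate: float = 0.1  # per cM
    overall_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_sires=self.n_sires,
                      n_dams_per_sire=self.n_dams_per_sire,
                      n_progeny_per_dam=self.n_progeny_per_dam,
                      n_phenotyped_per_dam=self.n_phenotyped_per_dam,
                      n_chromosomes=self.n_chromosomes,
                      snps_per_chromosome=self.snps_per_chromosome,
                      n_ancestral_haplotypes=self.n_ancestral_haplotypes)
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be a positive count, got {value}")
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must lie strictly inside (0, 1)")
        if not 0.0 <= self.polygenic_fraction < 1.0:
            raise ValueError("polygenic_fraction must lie in [0, 1)")
        if self.n_phenotyped_per_dam > self.n_progeny_per_dam:
            raise ValueError("cannot phenotype more progeny than exist per dam")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive (Morgan)")
        if self.ancestral_switch_rate < 0:
            raise ValueError("ancestral_switch_rate must be non-negative")
        for q in self.qtn_spec:
            for idx in (q.snp_index, q.partner_snp):
                if idx is not None and not 1 <= idx <= self.snps_per_chromosome:
                    raise ValueError(
                        f"QTN index {idx} outside [1, {self.snps_per_chromosome}]")
            if not 1 <= q.chromosome <= self.n_chromosomes:
                raise ValueError(f"QTN chromosome {q.chromosome} out of range")

    # Derived structural counts -------------------------------------------------
    @property
    def n_dams(self) -> int:
        return self.n_sires * self.n_dams_per_sire

    @property
    def n_progeny(self) -> int:
        return self.n_dams * self.n_progeny_per_dam

    @property
    def n_individuals(self) -> int:
        return self.n_sires + self.n_dams + self.n_progeny

    @property
    def n_phenotyped(self) -> int:
        return self.n_dams * self.n_phenotyped_per_dam

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def to_dict(self) -> dict:
        return asdict(self)
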