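"""Simulate a two-generation half-sib population and inspect its structure.

The default configuration reproduces the benchmark half-sib design: 20 sires
x 10 dams x 15 progeny (3,220 individuals), 9,990 SNPs on 5 chromosomes,
2,000 phenotyped progeny at heritability 0.30.  Here we run a smaller
design so the script finishes in seconds.
"""

import mmra

cfg = mmra.SimulationConfig(
    n_sires=5, n_dams_per_sire=4, n_progeny_per_dam=10,
    n_phenotyped_per_dam=8, n_chromosomes=2, snps_per_chromosome=200,
    qtn_spec=[mmra.QtnSpec(1, 50, "additive", 4.0)], seed=7)
pop = mmra.simulate_population(cfg)

print(f"individuals: {len(pop.pedigree)} "
      f"({cfg.n_sires} sires + {cfg.n_dams} dams + {cfg.n_progeny} progeny)")
print(f"SNP markers: {pop.genotypes.n_snps}  phenotypes: {len(pop.trait)}")
print(f"phenotype mean ~ {pop.trait['value'].mean():.1f} "
      f"(configured overall mean {cfg.overall_mean})")
print("causal loci:")
print(pop.qtn.to_string(index=False))
# The truth table is what a power study scores detections against: the
# scan should localise the additive locus near its pos_cm.
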