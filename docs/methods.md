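# Methods

This note documents the statistical models, algorithms and defaults in
`mmra`, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## The animal model and REML

The baseline model is the intercept-only animal model

    y = 1μ + Za + e,    a ~ N(0, A σ²_a),    e ~ N(0, I σ²_e)

where `A` is the pedigree additive relationship matrix and `Z` picks the
phenotyped individuals out of the pedigree. `A` is built densely by the
tabular method (`a_ii = 1 + ½ a_{s(i),d(i)}`, `a_ij = ½(a_{j,s(i)} +
a_{j,d(i)})`, unknown parents contributing zero). At the default scale
(3,220 individuals) dense `A` is ~83 MB and a sparse-inverse shortcut
buys nothing worth its complexity.

With a single random effect, REML reduces exactly to one dimension:
writing `K = ZAZ' = U diag(d) U'` (computed once) and
`λ = σ²_a/σ²_e`, the marginal covariance is `σ²_e (λK + I)`, the
rotated model is a heteroscedastic regression with weights
`1/(λ d_i + 1)`, and `σ²_e` has a closed form at every `λ`. The profile
restricted likelihood

    −2 lR(λ) = (n−p) log 2π + (n−p) log σ̂²_e(λ) + Σ log(λ d_i + 1)
               + log |X'W⁻¹X| + (n−p)

is maximised by bounded Brent search over `log₁₀ λ ∈ [−6, 3]`
(tolerance 1e−6). This is exact, deterministic and easy to check
against a brute-force dense evaluation, which the tests do to 1e−8.
`σ²_a` may hit the zero boundary; the estimate is then clipped and
flagged rather than raised, because boundary nulls are a routine
outcome when the procedure runs inside permutation loops. A spectrum of
`K` numerically indistinguishable from flat (no relatedness) raises a
non-identifiability error instead of returning an arbitrary split.

## The single-SNP scan

Each marker enters as a fixed allele-substitution effect:
`y = 1μ + b x + Za + e`, with `x ∈ {0,1,2}` counting copies of the
minor allele. The variance components are estimated once from the
no-SNP model and fixed for every marker (the P3D/EMMAX device); with
them fixed, Henderson's mixed model equations and generalised least
squares with `V = ZAZ'σ²_a + Iσ²_e` give identical `b̂` and `Var(b̂)`,
and the test is `W = b̂²/Var(b̂) ~ χ²(1)` under the null.

`fit_single_snp` solves the MME literally (dense `A⁻¹` via Cholesky,
jittered by 1e−10 only if the factorisation fails); `scan` obtains the
same numbers genome-wide from the one-time spectral rotation: rotating
`y`, the intercept and every genotype column by `U` turns each SNP into
a closed-form weighted 2×2 regression. The equivalence of the two
routes, and of both against a brute-force GLS oracle, is asserted in
the tests to 1e−8. Monomorphic columns (possible only if QC is skipped)
produce flagged no-test records instead of aborting the scan.

## Marker quality control

Individuals first: unphenotyped progeny are dropped, parents kept (the
analysis set is 2,220 under the default design). MAF is computed on
that set; markers with MAF = 0 are removed as monomorphic and markers
with 0 < MAF < 0.03 as low-MAF — the inequality is strict, so a MAF of
exactly 0.03 is retained. Retained columns are re-oriented so the code
always counts the minor allele of the analysis set. The QC report's
three counts always partition the input panel.

## Permutation thresholds

Phenotypes are permuted against the fixed genotype and pedigree data;
each permuted dataset is rescanned and only the largest Wald statistic
kept. The threshold for level α is the ⌈(1−α)N⌉-th smallest of the N
maxima, and a SNP is significant when its observed statistic strictly
exceeds it — one defensible reading of "the 95th percentile", stated
explicitly so results are reproducible. The variance components are
*not* re-estimated inside permutations: under a permuted (null)
phenotype the REML estimate collapses to the boundary anyway, and fixed
components keep each permutation at the cost of one rotation plus a
vectorised scan. Per-permutation RNG streams are derived from
`(seed, permutation index)`, so the null vector is bit-identical for
any worker count.

One calibration subtlety is worth recording: with components *fixed at
the observed-data estimates*, the raw p of a single permuted-phenotype
test is anticonservative (the assumed covariance no longer matches the
permuted data), which is irrelevant to the max-statistic procedure —
observed and permuted scans share the same misfit — but matters when
quoting raw type-I error. The calibration tests therefore re-fit the
components on each null replicate, which is also what a full analysis
of such data would do.

## Pairwise LD and Gabriel blocks

Two-locus haplotype frequencies are estimated from unphased genotypes
by EM over the double-heterozygote ambiguity (deterministic start at
linkage equilibrium, convergence at 1e−8 or 1,000 iterations). From
the frequencies: `D = p11 − p1 q1`, `D′ = |D|/D_max` with the usual
frequency-dependent `D_max`; the LOD is the log₁₀ ratio of the
nine-genotype-class multinomial likelihood at the estimate versus
`D = 0` with allele frequencies held at their estimates. D′ confidence
bounds come from the same likelihood evaluated on a D′ grid
(step 0.01, sign of D fixed at the estimate), normalised and read at
the 5th/95th cumulative points — the Gabriel-style computation.

Blocks follow the Gabriel confidence-interval criteria with the
standard defaults, all exposed as configuration: a pair is in strong LD
iff its CI is `[≥0.70, ≥0.98]`, shows strong recombination iff the
upper bound is `<0.90`; an interval qualifies iff its outermost pair is
in strong LD and strong-LD pairs are ≥95% of its informative pairs;
qualifying intervals are taken greedily, longest first, leftmost on
ties. The marker-count-specific CI sub-rules that Haploview adds for
2–4-marker blocks are deliberately not replicated: the uniform
criteria are simpler, and the tests verify the implementation against
an exhaustive enumeration of all candidate intervals. Block calling is
applied to the significant SNPs per chromosome; the SNP list is an
explicit argument, so users may add background markers or known causal
positions.

## The population simulator

The generator emulates the statistical structure of a two-generation
half-sib mapping design; by default, 20 sires × 10 dams × 15 progeny
(3,220 individuals), 10 of 15 progeny per dam phenotyped (2,000
records, chosen uniformly at random per dam), 5 chromosomes of
1 Morgan carrying 1,998 evenly spaced SNPs. Marker k of a chromosome
sits at `k·(L/m)` Morgan — the map convention is the simulator's own
and is recorded in its `.map` output.

**Founder LD.** Founder haplotypes are mosaics over a pool of 10
ancestral haplotypes with Markov switching along the map (switch
probability `1 − exp(−0.1·d_cM)` between adjacent markers). Ancestral
allele frequencies are drawn from Beta(0.5, 0.5); the U-shape makes
roughly a third of markers monomorphic in the pool, matching the large
monomorphic fraction such SNP panels show, and the mosaic structure
yields LD that decays with map distance without a forward-in-time
burn-in. Causal loci are redrawn from Beta(2, 2) until polymorphic so
the architecture always segregates. Low-MAF (0 < MAF < 0.03)
markers are rare under this founder model — a 10-haplotype pool rarely
produces population frequencies that small — so the low-MAF QC class
is exercised by construction in the tests rather than by the default
simulation.

**Transmission.** Gametes recombine under the Haldane map function
(crossover probability `½(1 − e^{−2d})` per marker interval);
parental origin is recorded per haplotype, which is what makes
imprinting representable.

**Causal architecture.** The default mirrors the benchmark design: one
large additive locus on chromosome 1 (effect 4.0, at 2.85 cM); two
additive pairs on chromosomes 2 and 3 (effects 2.0, at 81.90/93.75 and
5.0/15.0 cM) in coupling and repulsion phase respectively — phase is
enforced by relabelling alleles at the second locus of a pair so the
founder-pool gametic D between trait-raising alleles has the annotated
sign; one paternally expressed locus on chromosome 4 (contrast 2.5,
expressed only when allele 2 is paternally inherited); one epistatic
pair on chromosome 5 (contrast 2.5, expressed only in carriers at both
loci). True effect sizes for such benchmarks are typically
unpublished; these defaults make the chromosome-1 locus explain ~10%
of phenotypic variance and each smaller additive locus ~2–4% at
heritability 0.30.

**Phenotypes.** `phenotype = mean + QTN value + polygenic + residual`,
with the polygenic effect following the pedigree (founders
`N(0, σ²_p)`, offspring midparent plus Mendelian sampling
`N(0, σ²_p/2)` — exact for non-inbred parents, which the
two-generation design guarantees). `σ²_p` is set so that a configurable
fraction (default 0.30) of total genetic variance is polygenic given
the realised QTN variance, and the residual variance then makes total
genetic/total variance equal the target heritability 0.30. Tests may
override both variances directly (e.g. the noise-free limit).

Note that an imprinted or epistatic locus still leaks a marginal
additive signal (a paternally expressed locus is exactly linear in
genotype with slope half its contrast), so "non-detection" by the
additive scan is a statement about power at given effect sizes and
thresholds, not an impossibility; the end-to-end tests use contrasts
whose marginal signal sits below the genome-wide threshold at the
tested scale.

**What the generator does not emulate:** sequence-level realism,
mutation, selection or multi-generation breeding; missing genotypes
(panels are complete by construction); any attempt to match the
coordinate conventions or the exact genotypes of any particular
benchmark release. Passing tests therefore demonstrate correctness of the
algorithms and calibration under a realistic family/LD structure, not
agreement with any particular real dataset.

## Reproducibility and problem sizes

All randomness flows from one seed: the simulator uses a single
`numpy` Generator in a fixed call order, and permutation streams are
derived from `(seed, index)`. Pipeline runs write a manifest with the
seed, parameters and the threshold convention, and identical seeds give
byte-identical outputs.

Problem sizes in the test-suite: oracle comparisons run at n ≤ 50
where brute-force dense algebra is exact and fast; calibration studies
(type-I error, FWER, CI coverage) use 200-phenotype populations with
500–2,000 markers and 200–1,000 replicates; parameter-recovery checks
for heritability run 20 replicates at the full default design. The
permutation default in the pipeline is 10,000 (configurable);
desk-scale studies in the tests use 100–200 permutations, which is
sufficient for a 0.05-tail threshold.

## Known limitations

- Single-trait, intercept-only fixed effects, one random effect; no
  dominance, maternal or repeated-records models.
- The scan is purely additive: imprinting and epistasis are simulated
  (to measure what the method misses) but never modelled.
- Permutation ignores family structure under the null (plain
  exchangeability), as in the original procedure; gene-dropping
  permutations are out of scope.
- Dense linear algebra throughout: comfortable to ~5,000 phenotypes on
  one CPU, not intended for biobank scale.
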