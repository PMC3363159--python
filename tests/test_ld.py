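"""Two-locus EM, D', LOD, D' confidence intervals and Gabriel block calling."""

import numpy as np
import pandas as pd
import pytest

import mmra
from mmra.genotypes import GenotypeMatrix, make_snp_map
from mmra.ld import DegeneratePairError, GabrielParams, _classify

from conftest import gamete_count_oracle


def _simulate_pair(hap_freqs, n, rng):
    """Unphased genotype columns from random union of gametes."""
    haps = rng.choice(4, size=(n, 2), p=np.asarray(hap_freqs))
    # haplotype index: 0=11, 1=12, 2=21, 3=22 (allele at locus i, j)
    gi = (haps >= 2).sum(axis=1)
    gj = (haps % 2).sum(axis=1)
    return gi, gj


class TestEmHaplotypeFreq:
    def test_equals_gamete_counting_without_double_heterozygotes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gi = rng.integers(0, 3, size=60)
            gj = np.where(gi == 1, rng.choice([0, 2], size=60),
                          rng.integers(0, 3, size=60))
            if np.ptp(gi) == 0 or np.ptp(gj) == 0:
                continue
            est = mmra.em_haplotype_freq(gi, gj)
            np.testing.assert_allclose(est, gamete_count_oracle(gi, gj),
                                       atol=1e-7)

    def test_independent_loci_near_zero_D(self):
        rng = np.random.default_rng(1)
        gi, gj = _simulate_pair([0.25, 0.25, 0.25, 0.25], 10_000, rng)
        f = mmra.em_haplotype_freq(gi, gj)
        D = f[0] - (f[0] + f[1]) * (f[0] + f[2])
        se = np.sqrt(0.25 * 0.25 / (2 * 10_000))  # binomial-scale SE
        assert abs(D) < 3 * se

    def test_identical_columns_complete_ld(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=300)
        f = mmra.em_haplotype_freq(g, g)
        assert f[1] == pytest.approx(0.0, abs=1e-9)
        assert f[2] == pytest.approx(0.0, abs=1e-9)
        assert mmra.d_prime(f) == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(DegeneratePairError):
            mmra.em_haplotype_freq(np.zeros(10, int),
                                   np.array([0, 1, 2] * 3 + [1]))

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        gi, gj = _simulate_pair([0.5, 0.1, 0.15, 0.25], 400, rng)
        f = mmra.em_haplotype_freq(gi, gj)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)


class TestDPrime:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.5, 0.0, 0.0, 0.5), 1.0),
        ((0.25, 0.25, 0.25, 0.25), 0.0),
        ((0.4, 0.1, 0.1, 0.4), 0.6),  # D=0.15, Dmax=0.25
    ])
    def test_hand_computed_values(self, freqs, expected):
        assert mmra.d_prime(np.asarray(freqs)) == pytest.approx(expected)

    def test_label_and_locus_swap_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            f = rng.dirichlet([2, 1, 1, 2])
            try:
                base = mmra.d_prime(f)
            except DegeneratePairError:
                continue
            p11, p12, p21, p22 = f
            swap_i = np.array([p21, p22, p11, p12])   # relabel locus i
            swap_j = np.array([p12, p11, p22, p21])   # relabel locus j
            swap_loci = np.array([p11, p21, p12, p22])
            for other in (swap_i, swap_j, swap_loci):
                assert mmra.d_prime(other) == pytest.approx(base, abs=1e-12)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegeneratePairError):
            mmra.d_prime(np.array([0.5, 0.5, 0.0, 0.0]))


class TestLodScore:
    def test_zero_disequilibrium_gives_zero(self):
        # full factorial genotype table with independent margins: D-hat = 0
        gi = np.repeat([0, 1, 2], 9)
        gj = np.tile(np.repeat([0, 1, 2], 3), 3)
        assert mmra.lod_score(gi, gj) == pytest.approx(0.0, abs=1e-6)

    def test_identical_columns_strong_support(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=500)
        assert mmra.lod_score(g, g) > 2.0

    def test_independent_loci_median_near_zero(self):
        rng = np.random.default_rng(6)
        lods = []
        for _ in range(200):
            gi, gj = _simulate_pair([0.25, 0.25, 0.25, 0.25], 500, rng)
            lods.append(mmra.lod_score(gi, gj))
        assert np.median(lods) < 0.5
        assert min(lods) >= 0.0


class TestConfidenceInterval:
    def test_complete_ld_upper_bound_saturates(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.5, size=500)
        lo, hi = mmra.ld_confidence_interval(g, g)
        assert hi == 1.0

    def test_true_complete_ld_has_high_lower_bound(self):
        rng = np.random.default_rng(8)
        good = 0
        for _ in range(100):
            gi, gj = _simulate_pair([0.6, 0.0, 0.0, 0.4], 500, rng)
            if np.ptp(gi) == 0 or np.ptp(gj) == 0:
                continue
            lo, _ = mmra.ld_confidence_interval(gi, gj)
            if lo >= 0.98:
                good += 1
        assert good >= 95

    def test_tiny_samples_are_uncertain(self):
        rng = np.random.default_rng(9)
        widths = []
        for _ in range(20):
            gi, gj = _simulate_pair([0.25, 0.25, 0.25, 0.25], 10, rng)
            if np.ptp(gi) == 0 or np.ptp(gj) == 0:
                continue
            lo, hi = mmra.ld_confidence_interval(gi, gj)
            widths.append(hi - lo)
        assert np.median(widths) > 0.5

    def test_bounds_ordered_within_unit_interval(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            gi, gj = _simulate_pair([0.45, 0.05, 0.1, 0.4], 150, rng)
            lo, hi = mmra.ld_confidence_interval(gi, gj)
            assert 0.0 <= lo <= hi <= 1.0


def _pairs_from_classes(snps, classes):
    """Build a pairwise DataFrame inducing the requested Gabriel classes."""
    rows = []
    for (i, j), cls in classes.items():
        if cls == "strong_ld":
            lo, hi = 0.8, 1.0
        elif cls == "strong_recomb":
            lo, hi = 0.1, 0.5
        else:
            lo, hi = 0.2, 0.95
        rows.append({"snp_i": snps[i], "snp_j": snps[j], "ci_low": lo,
                     "ci_high": hi, "degenerate": False,
                     "D": 0.1, "d_prime": 0.5, "lod": 1.0})
    return pd.DataFrame(rows)


def _blocks_oracle(m, classes, frac=0.95):
    """Exhaustive candidate-interval enumeration with greedy selection."""
    cands = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            if classes.get((a, b), "uninformative") != "strong_ld":
                continue
            ns = nr = 0
            for i in range(a, b + 1):
                for j in range(i + 1, b + 1):
                    c = classes.get((i, j), "uninformative")
                    ns += c == "strong_ld"
                    nr += c == "strong_recomb"
            if ns + nr and ns / (ns + nr) >= frac:
                cands.append((b - a, a, b))
    cands.sort(key=lambda t: (-t[0], t[1]))
    taken = [False] * m
    out = []
    for _, a, b in cands:
        if any(taken[a:b + 1]):
            continue
        for k in range(a, b + 1):
            taken[k] = True
        out.append((a, b))
    return sorted(out)


class TestGabrielBlocks:
    def _map(self, m):
        return make_snp_map(1, m)

    def test_all_strong_pairs_form_one_block(self):
        snps = ["C1S1", "C1S2", "C1S3"]
        classes = {(0, 1): "strong_ld", (0, 2): "strong_ld",
                   (1, 2): "strong_ld"}
        blocks = mmra.gabriel_blocks(_pairs_from_classes(snps, classes),
                                     self._map(3))
        assert len(blocks) == 1
        assert blocks[0].members == tuple(snps)

    def test_strong_recombination_prevents_block(self):
        snps = ["C1S1", "C1S2"]
        classes = {(0, 1): "strong_recomb"}
        assert mmra.gabriel_blocks(_pairs_from_classes(snps, classes),
                                   self._map(2)) == []

    def test_matches_exhaustive_enumeration_on_random_classifications(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = int(rng.integers(3, 13))
            snps = [f"C1S{k}" for k in range(1, m + 1)]
            classes = {}
            for a in range(m - 1):
                for b in range(a + 1, m):
                    classes[(a, b)] = rng.choice(
                        ["strong_ld", "strong_recomb", "uninformative"],
                        p=[0.5, 0.2, 0.3])
            blocks = mmra.gabriel_blocks(_pairs_from_classes(snps, classes),
                                         self._map(m))
            got = sorted((snps.index(b.first_snp), snps.index(b.last_snp))
                         for b in blocks)
            assert got == _blocks_oracle(m, classes)

    def test_blocks_disjoint_and_contiguous(self):
        rng = np.random.default_rng(12)
        m = 12
        snps = [f"C1S{k}" for k in range(1, m + 1)]
        classes = {(a, b): rng.choice(["strong_ld", "uninformative"])
                   for a in range(m - 1) for b in range(a + 1, m)}
        blocks = mmra.gabriel_blocks(_pairs_from_classes(snps, classes),
                                     self._map(m))
        used = set()
        for blk in blocks:
            idx = [snps.index(s) for s in blk.members]
            assert idx == list(range(min(idx), max(idx) + 1))
            assert not used & set(idx)
            used |= set(idx)

    def test_haplotype_copies_form_single_block_from_genotypes(self):
        # SNPs 1-4 share one founder pattern (2% noise); 5-6 independent
        rng = np.random.default_rng(13)
        n = 300
        base = rng.binomial(2, 0.45, size=n)
        cols = []
        for _ in range(4):
            noisy = base.copy()
            flip = rng.random(n) < 0.02
            noisy[flip] = rng.integers(0, 3, size=flip.sum())
            cols.append(noisy)
        for _ in range(2):
            cols.append(rng.binomial(2, 0.45, size=n))
        geno = GenotypeMatrix(np.asarray(cols, dtype=np.int8).T,
                              [f"I{i}" for i in range(n)], self._map(6))
        pairs = mmra.pairwise_ld(geno)
        blocks = mmra.gabriel_blocks(pairs, geno.snp_map)
        assert len(blocks) == 1
        assert blocks[0].members == ("C1S1", "C1S2", "C1S3", "C1S4")

    def test_classification_thresholds(self):
        params = GabrielParams()
        strong = {"ci_low": 0.71, "ci_high": 0.99, "degenerate": False}
        recomb = {"ci_low": 0.0, "ci_high": 0.89, "degenerate": False}
        neither = {"ci_low": 0.3, "ci_high": 0.95, "degenerate": False}
        degen = {"ci_low": np.nan, "ci_high": np.nan, "degenerate": True}
        assert _classify(strong, params) == "strong_ld"
        assert _classify(recomb, params) == "strong_recomb"
        assert _classify(neither, params) == "uninformative"
        assert _classify(degen, params) == "uninformative"


class TestPairwiseDriver:
    def test_degenerate_pair_flagged_not_fatal(self):
        codes = np.column_stack([np.zeros(20, int),
                                 np.tile([0, 1, 2, 1], 5)]).astype(np.int8)
        geno = GenotypeMatrix(codes, [f"I{i}" for i in range(20)],
                              make_snp_map(1, 2))
        pairs = mmra.pairwise_ld(geno)
        assert len(pairs) == 1
        assert bool(pairs["degenerate"][0])

    def test_em_loglik_monotone_under_iteration(self):
        # EM likelihood (9-class multinomial) never decreases
        from mmra.ld import _class_counts, _class_loglik
        rng = np.random.default_rng(14)
        gi, gj = _simulate_pair([0.4, 0.1, 0.2, 0.3], 120, rng)
        counts = _class_counts(gi, gj)
        lls = []
        for iters in range(1, 12):
            f = mmra.em_haplotype_freq(gi, gj, tol=0.0, max_iter=iters)
            lls.append(_class_loglik(counts, f))
        assert np.all(np.diff(lls) >= -1e-9)
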