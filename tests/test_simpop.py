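"""The synthetic-population generator: pedigree design, founder LD,
gene dropping, causal effects and phenotype calibration."""

import numpy as np
import pandas as pd
import pytest

import mmra
from mmra.genotypes import make_snp_map
from mmra.simpop import haldane_recomb_fraction, _meiosis

from conftest import small_config


class TestSimulatePedigree:
    def test_default_design_counts(self):
        ped = mmra.simulate_pedigree(mmra.SimulationConfig())
        assert len(ped) == 3220
        assert int((ped.generation == 1).sum()) == 3000
        assert ped.n_founders == 220

    def test_single_trio(self):
        ped = mmra.simulate_pedigree(mmra.SimulationConfig(
            n_sires=1, n_dams_per_sire=1, n_progeny_per_dam=1,
            n_phenotyped_per_dam=1))
        assert len(ped) == 3
        assert ped.sire[2] == "S1" and ped.dam[2] == "D1"

    def test_every_progeny_matches_its_dams_mate(self):
        # exhaustive scan of all 3,000 second-generation records
        cfg = mmra.SimulationConfig()
        ped = mmra.simulate_pedigree(cfg)
        dam_mate = {}
        for ind, s, d in zip(ped.ids, ped.sire, ped.dam):
            if s == "0":
                continue
            if d in dam_mate:
                assert dam_mate[d] == s, f"dam {d} mated to two sires"
            dam_mate[d] = s
        # 10 dams per sire, each dam exactly one sire
        assert len(dam_mate) == cfg.n_dams
        per_sire = pd.Series(list(dam_mate.values())).value_counts()
        assert (per_sire == cfg.n_dams_per_sire).all()


class TestFounderHaplotypes:
    def test_single_ancestor_makes_everything_monomorphic(self):
        cfg = small_config(n_ancestral_haplotypes=1, qtn=[])
        rng = np.random.default_rng(0)
        founders = mmra.simulate_founder_haplotypes(cfg, rng)
        h = founders.haplotypes
        assert (h == h[:1, :1, :]).all()
        geno = founders.to_genotype_matrix()
        _, report = mmra.filter_snps(geno)
        assert report.n_retained == 0
        assert report.n_monomorphic == geno.n_snps

    def test_zero_switch_rate_copies_whole_ancestors(self):
        cfg = small_config(ancestral_switch_rate=0.0, qtn=[])
        rng = np.random.default_rng(3)
        pool_rng = np.random.default_rng(3)
        from mmra.simpop import _ancestral_pool
        pool = _ancestral_pool(cfg, pool_rng)
        founders = mmra.simulate_founder_haplotypes(cfg, rng)
        flat = founders.haplotypes.reshape(-1, founders.n_snps)
        chrom = founders.snp_map["chromosome"].to_numpy()
        for hap in flat[:10]:
            for c in np.unique(chrom):
                cols = chrom == c
                assert any((hap[cols] == anc[cols]).all() for anc in pool)

    def test_ld_decays_with_distance(self):
        # mean D' of adjacent polymorphic pairs must exceed pairs ~half a
        # chromosome apart (Monte-Carlo, fixed seed)
        cfg = small_config(snps_per_chromosome=100, n_chromosomes=1, qtn=[],
                          n_sires=10, n_dams_per_sire=5)
        founders = mmra.simulate_founder_haplotypes(
            cfg, np.random.default_rng(5))
        geno = founders.to_genotype_matrix()
        kept, _ = mmra.filter_snps(geno, 0.0)
        codes = kept.codes

        def mean_dprime(pairs):
            vals = []
            for i, j in pairs:
                try:
                    f = mmra.em_haplotype_freq(codes[:, i], codes[:, j])
                    vals.append(mmra.d_prime(f))
                except mmra.DegeneratePairError:
                    continue
            return np.mean(vals)

        m = kept.n_snps
        near = [(i, i + 1) for i in range(0, m - 1, 2)]
        far = [(i, i + m // 2) for i in range(m // 2)]
        assert mean_dprime(near) > mean_dprime(far)


class TestDropGenes:
    def test_haldane_limits(self):
        assert haldane_recomb_fraction(0.0) == 0.0
        assert haldane_recomb_fraction(1e9) == pytest.approx(0.5)
        assert haldane_recomb_fraction(0.1) == pytest.approx(
            0.5 * (1 - np.exp(-0.2)))

    def test_crossover_rate_matches_haldane_closed_form(self):
        # 100,000 meioses over a 2-SNP chromosome 0.1 Morgan apart
        rng = np.random.default_rng(12)
        n = 100_000
        parent = np.zeros((n, 2, 2), dtype=np.int8)
        parent[:, 0, :] = 1  # haplotype A alleles 1
        parent[:, 1, :] = 2  # haplotype B alleles 2
        r = np.asarray([haldane_recomb_fraction(0.1)])
        gametes = _meiosis(parent, r, rng)
        recomb = (gametes[:, 0] != gametes[:, 1]).mean()
        p = float(r[0])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(recomb - p) < 3 * se

    def test_zero_distance_never_recombines(self):
        rng = np.random.default_rng(1)
        parent = np.zeros((500, 2, 2), dtype=np.int8)
        parent[:, 0, :] = 1
        parent[:, 1, :] = 2
        gametes = _meiosis(parent, np.array([0.0]), rng)
        assert (gametes[:, 0] == gametes[:, 1]).all()

    def test_mendelian_consistency_and_collapse(self, small_pop):
        ped = small_pop.pedigree
        h = small_pop.phased.haplotypes
        codes = small_pop.genotypes.codes
        assert np.array_equal(small_pop.phased.collapse(), codes)
        sire, dam = ped.parent_indices()
        prog = np.flatnonzero((sire >= 0) & (dam >= 0))
        # each transmitted haplotype allele must exist in the labelled parent
        pat, mat = h[:, 0, :], h[:, 1, :]
        for child in prog[:50]:
            s, d = sire[child], dam[child]
            assert np.all((pat[child] == pat[s]) | (pat[child] == mat[s]))
            assert np.all((mat[child] == pat[d]) | (mat[child] == mat[d]))

    def test_missing_parent_haplotypes_error(self, small_pop):
        ped = mmra.Pedigree(["A", "B", "C"], ["0", "0", "A"], ["0", "0", "B"])
        snp_map = make_snp_map(1, 4)
        founders = mmra.PhasedGenotypes(
            np.ones((1, 2, 4), dtype=np.int8), ["A"], snp_map)
        with pytest.raises(ValueError, match="founder 'B'"):
            mmra.drop_genes(ped, founders, snp_map, np.random.default_rng(0))


class TestGeneticValues:
    def _phased(self, haps, m=4):
        arr = np.ones((len(haps), 2, m), dtype=np.int8)
        for i, (pat, mat) in enumerate(haps):
            arr[i, 0, 0] = pat
            arr[i, 1, 0] = mat
        return mmra.PhasedGenotypes(arr, [f"I{i}" for i in range(len(haps))],
                                    make_snp_map(1, m))

    def test_all_reference_homozygote_is_zero(self):
        ph = self._phased([(1, 1)])
        qtn = [mmra.QtnSpec(1, 1, "additive", 5.0),
               mmra.QtnSpec(1, 2, "imprinted_paternal", 3.0)]
        assert mmra.assign_genetic_values(ph, qtn, 4)[0] == 0.0

    def test_additive_substitution_effect(self):
        ph = self._phased([(1, 2), (2, 2)])
        qtn = [mmra.QtnSpec(1, 1, "additive", 2.0)]
        np.testing.assert_allclose(
            mmra.assign_genetic_values(ph, qtn, 4), [2.0, 4.0])

    def test_imprinting_all_four_phased_configurations(self):
        ph = self._phased([(1, 1), (1, 2), (2, 1), (2, 2)])
        qtn = [mmra.QtnSpec(1, 1, "imprinted_paternal", 1.5)]
        # effect expressed only when allele 2 is paternally inherited
        np.testing.assert_allclose(
            mmra.assign_genetic_values(ph, qtn, 4), [0.0, 0.0, 1.5, 1.5])

    def test_epistatic_pair_needs_both_carriers(self):
        m = 4
        arr = np.ones((4, 2, m), dtype=np.int8)
        # individual 0: carrier at both; 1: locus 1 only; 2: locus 3 only; 3: none
        arr[0, 0, 0] = 2
        arr[0, 1, 2] = 2
        arr[1, 0, 0] = 2
        arr[2, 1, 2] = 2
        ph = mmra.PhasedGenotypes(arr, list("abcd"), make_snp_map(1, m))
        qtn = [mmra.QtnSpec(1, 1, "epistatic_pair", 2.0, partner_snp=3)]
        np.testing.assert_allclose(
            mmra.assign_genetic_values(ph, qtn, m), [2.0, 0.0, 0.0, 0.0])

    def test_dangling_partner_rejected(self):
        with pytest.raises(ValueError):
            mmra.QtnSpec(1, 1, "epistatic_pair", 2.0)  # no partner
        with pytest.raises(ValueError, match="outside"):
            ph = self._phased([(1, 1)])
            mmra.assign_genetic_values(
                ph, [mmra.QtnSpec(1, 2, "epistatic_pair", 1.0,
                                  partner_snp=99)], 4)


class TestPhenotypes:
    def test_default_design_yields_2000_records(self):
        cfg = mmra.SimulationConfig()
        ped = mmra.simulate_pedigree(cfg)
        g = np.zeros(len(ped))
        trait = mmra.simulate_phenotypes(ped, g, cfg, np.random.default_rng(0))
        assert len(trait) == 2000
        parents = {i for i, s in zip(ped.ids, ped.sire) if s == "0"}
        assert not parents & set(trait["id"])

    def test_noise_free_limit_recovers_genetic_values(self, small_pop):
        cfg = small_pop.config
        ped = small_pop.pedigree
        g = small_pop.genetic_values
        trait = mmra.simulate_phenotypes(
            ped, g, cfg, np.random.default_rng(0),
            sigma_poly2=0.0, sigma_e2=0.0)
        idx = ped.index_of(list(trait["id"]))
        np.testing.assert_allclose(
            trait["value"].to_numpy() - cfg.overall_mean, g[idx], atol=1e-12)

    def test_full_sib_phenotypic_covariance_shows_transmission(self):
        # cov(full sibs) = sigma_poly2 / 2 under a purely polygenic trait
        cfg = small_config(n_sires=30, n_dams_per_sire=5,
                          n_progeny_per_dam=8, n_phenotyped_per_dam=8,
                          qtn=[], snps_per_chromosome=10)
        ped = mmra.simulate_pedigree(cfg)
        rng = np.random.default_rng(21)
        sp2, se2 = 4.0, 2.0
        trait = mmra.simulate_phenotypes(ped, np.zeros(len(ped)), cfg, rng,
                                         sigma_poly2=sp2, sigma_e2=se2)
        idx = ped.index_of(list(trait["id"]))
        dam_of = np.asarray(ped.dam)[idx]
        df = pd.DataFrame({"dam": dam_of, "y": trait["value"].to_numpy()})
        grand = df["y"].mean()
        cov = np.mean([
            np.mean([(a - grand) * (b - grand)
                     for k, a in enumerate(g) for b in g[k + 1:]])
            for _, g in df.groupby("dam")["y"] if len(g) > 1])
        assert cov == pytest.approx(sp2 / 2, abs=1.0)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            mmra.SimulationConfig(target_h2=1.0)
        with pytest.raises(ValueError):
            mmra.SimulationConfig(target_h2=0.0)


class TestStructuralInvariants:
    @pytest.mark.parametrize("sires,dams,prog", [(2, 3, 4), (1, 1, 1), (4, 2, 5)])
    def test_count_identity(self, sires, dams, prog):
        cfg = mmra.SimulationConfig(
            n_sires=sires, n_dams_per_sire=dams, n_progeny_per_dam=prog,
            n_phenotyped_per_dam=1)
        ped = mmra.simulate_pedigree(cfg)
        assert len(ped) == sires + sires * dams * (1 + prog)

    def test_default_config_reproduces_published_counts(self):
        cfg = mmra.SimulationConfig()
        assert cfg.n_dams == 200
        assert cfg.n_progeny == 3000
        assert cfg.n_individuals == 3220
        assert cfg.n_phenotyped == 2000
        assert cfg.n_snps == 9990

    def test_same_seed_reproduces_run(self):
        cfg = small_config(seed=9)
        a = mmra.simulate_population(cfg)
        b = mmra.simulate_population(cfg)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        pd.testing.assert_frame_equal(a.trait, b.trait)
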