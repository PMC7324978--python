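"""Synthetic-data generator: calibration, Mendelian mechanics, study driver."""

import itertools

import numpy as np
import pytest

from hspower.covariance import GeneticMap, SireDiplotypes, maternal_ld_from_haplotypes
from hspower.simulate import (
    FounderPopulation,
    StudyConfig,
    breed_halfsibs,
    founder_haplotypes,
    make_gamete,
    make_gametes,
    run_study,
    select_sires,
    simulate_phenotype,
)


class TestFounderHaplotypesMarkov:
    def test_zero_target_gives_independent_loci(self, rng):
        pop = founder_haplotypes(
            p=30, n_founders=1500, adjacent_r2_target=0.0, rng=rng, method="markov"
        )
        H = pop.haplotypes.astype(float)
        r = [np.corrcoef(H[:, k], H[:, k + 1])[0, 1] for k in range(29)]
        assert np.max(np.abs(r)) < 3.5 / np.sqrt(H.shape[0])

    def test_high_target_couples_adjacent_loci(self, rng):
        pop = founder_haplotypes(
            p=10, n_founders=800, adjacent_r2_target=0.95,
            freq_range=(0.45, 0.55), rng=rng, method="markov",
        )
        assert pop.mean_adjacent_r2() > 0.8

    def test_calibration_to_intermediate_target(self, rng):
        r2s = [
            founder_haplotypes(
                p=80, n_founders=1000, adjacent_r2_target=0.45,
                rng=np.random.default_rng(s), method="markov",
            ).mean_adjacent_r2()
            for s in range(6)
        ]
        assert np.mean(r2s) == pytest.approx(0.45, abs=0.05)

    def test_polymorphic_loci(self, rng):
        pop = founder_haplotypes(p=40, n_founders=200, rng=rng, method="markov")
        frq = pop.haplotypes.mean(0)
        assert np.all((frq > 0) & (frq < 1))


class TestFounderHaplotypesCoalescent:
    def test_shape_and_calibration(self):
        r2s, shapes = [], []
        for s in range(3):
            pop = founder_haplotypes(
                p=300, n_founders=2000, rng=np.random.default_rng(s),
                method="coalescent",
            )
            r2s.append(pop.mean_adjacent_r2())
            shapes.append((pop.n_founders, pop.p))
        assert all(sh == (2000, 300) for sh in shapes)
        # generator is calibrated to mean adjacent r2 ~ 0.45
        assert np.mean(r2s) == pytest.approx(0.45, abs=0.1)

    def test_map_positions_sorted_within_region(self):
        pop = founder_haplotypes(
            p=100, n_founders=300, rng=np.random.default_rng(1), method="coalescent"
        )
        assert np.all(np.diff(pop.gmap.position_cM) >= 0)
        assert pop.gmap.position_cM[-1] <= 1.0 + 1e-9


class TestSelectSires:
    def test_random_selection_of_all_males_is_identity_subset(self, rng):
        pop = founder_haplotypes(p=10, n_founders=20, rng=rng, method="markov")
        sires = select_sires(pop, 10, selection="random", rng=rng)
        assert sires.n_sires == 10
        h1, _ = pop.diplotypes(pop.males)
        assert all(any(np.array_equal(s, h) for h in h1) for s in sires.hap1)

    def test_truncation_selection_enriches_phenotype(self, rng):
        pop = founder_haplotypes(p=20, n_founders=400, rng=rng, method="markov")
        qtl = 7
        sires = select_sires(pop, 10, h2_trait=0.5, rng=rng, qtl_index=qtl)
        males1, males2 = pop.diplotypes(pop.males)
        pop_geno = (males1[:, qtl] + males2[:, qtl]).mean()
        sel_geno = (sires.hap1[:, qtl].astype(int) + sires.hap2[:, qtl]).mean()
        assert sel_geno >= pop_geno

    def test_single_family_design(self, rng):
        pop = founder_haplotypes(p=10, n_founders=40, rng=rng, method="markov")
        assert select_sires(pop, 1, rng=rng).n_sires == 1


class TestGametes:
    def test_fully_linked_gamete_is_parental(self, rng):
        gmap = GeneticMap(list("abcd"), [0.0, 0.0, 0.0, 0.0])
        h1 = np.array([1, 1, 0, 1], np.int8)
        h2 = np.array([0, 0, 1, 0], np.int8)
        for _ in range(10):
            g = make_gamete(h1, h2, gmap, rng)
            assert np.array_equal(g, h1) or np.array_equal(g, h2)

    def test_unlinked_loci_inherit_independently(self, rng):
        gmap = GeneticMap(["a", "b"], [0.0, 1e6])  # theta = 0.5
        h1 = np.array([[1, 1]] * 20000, np.int8)
        h2 = np.array([[0, 0]] * 20000, np.int8)
        g = make_gametes(h1, h2, gmap, rng).astype(float)
        c = np.cov(g[:, 0], g[:, 1])[0, 1]
        assert abs(c) < 3 * 0.25 / np.sqrt(20000)

    @pytest.mark.parametrize(
        "g1, g2", list(itertools.product([(0, 0), (0, 1), (1, 1)], repeat=2))
    )
    def test_transmitted_covariance_matches_sire_ld_term(self, g1, g2):
        """Gamete-level oracle for every two-locus diplotype class."""
        from hspower.covariance import sire_ld_term

        # explicit phase: haplotype 1 takes the first allele of each pair
        h1 = np.array([g1[0], g2[0]], np.int8)
        h2 = np.array([g1[1], g2[1]], np.int8)
        theta = 0.2
        d_cM = -50.0 * np.log(1.0 - 2.0 * theta)
        gmap = GeneticMap(["a", "b"], [0.0, d_cM])
        n = 100_000
        g = make_gametes(
            np.repeat(h1[None], n, 0), np.repeat(h2[None], n, 0),
            gmap, np.random.default_rng(42),
        ).astype(float)
        half = g - 0.5  # transmitted half-codes +-1/2
        emp = np.mean(half[:, 0] * half[:, 1]) - half[:, 0].mean() * half[:, 1].mean()
        expected = sire_ld_term((h1[0], h1[1]), (h2[0], h2[1]), theta)
        assert abs(emp - expected) < 3 * 0.25 / np.sqrt(n)


class TestBreedHalfsibs:
    def test_homozygous_parents_give_constant_code(self, rng):
        gmap = GeneticMap(["a", "b"], [0.0, 0.5])
        sires = SireDiplotypes(["s"], [[1, 1]], [[1, 1]])
        pool = FounderPopulation(np.ones((40, 2), np.int8), gmap, 0.0)
        prog = breed_halfsibs(sires, pool, [10], rng=rng)
        assert np.all(prog.X_raw == 1)

    def test_family_sizes_and_ids(self, rng):
        pop = founder_haplotypes(p=6, n_founders=200, rng=rng, method="markov")
        sires = select_sires(pop, 3, rng=rng)
        prog = breed_halfsibs(sires, pop, [5, 7, 9], rng=rng)
        assert prog.n == 21
        assert np.bincount(prog.family_ids).tolist() == [5, 7, 9]

    def test_dam_pool_exhaustion_raises(self, rng):
        pop = founder_haplotypes(p=4, n_founders=10, rng=rng, method="markov")
        sires = select_sires(pop, 1, rng=rng)
        with pytest.raises(ValueError, match="dam pool"):
            breed_halfsibs(sires, pop, [50], rng=rng)

    def test_progeny_correlation_converges_to_theoretical_R(self, rng):
        """Empirical progeny correlation matches R (10 SNPs, n = 2e4)."""
        from hspower.covariance import region_correlation

        pop = founder_haplotypes(
            p=10, n_founders=45000, rng=np.random.default_rng(103),
            method="coalescent",
        )
        sires = select_sires(pop, 2, selection="random", rng=rng)
        n = 20_000
        f1, f2 = pop.diplotypes(pop.females)
        gam = make_gametes(f1, f2, pop.gmap, rng)
        dams = maternal_ld_from_haplotypes(gam)
        rc = region_correlation(sires, pop.gmap, dams)
        prog = breed_halfsibs(sires, pop, [n // 2, n // 2], rng=rng)
        X = prog.X_raw.astype(float)
        poly = np.flatnonzero(X.std(axis=0) > 0)
        both = np.intersect1d(rc.kept_indices, poly)
        assert both.size >= 9  # region must actually segregate
        emp = np.corrcoef(X[:, both], rowvar=False)
        sel = np.searchsorted(rc.kept_indices, both)
        frob = np.linalg.norm(emp - rc.R[np.ix_(sel, sel)])
        assert frob <= 0.05

    def test_genotype_variance_matches_variance_formula(self, rng):
        """Progeny variance at each SNP equals p(1-p) + 1/4 - Ebar^2."""
        pop = founder_haplotypes(
            p=6, n_founders=45000, rng=np.random.default_rng(8), method="markov"
        )
        sires = select_sires(pop, 3, selection="random", rng=rng)
        f1, f2 = pop.diplotypes(pop.females)
        dams = maternal_ld_from_haplotypes(make_gametes(f1, f2, pop.gmap, rng))
        Ebar = sires.expectation_matrix().mean(axis=0)
        expected = dams.maternal_freq * (1 - dams.maternal_freq) + 0.25 - Ebar**2
        prog = breed_halfsibs(sires, pop, [20000] * 3, rng=rng)
        emp = prog.X_raw.astype(float).var(axis=0)
        assert emp == pytest.approx(expected, abs=0.02)


class TestModelMatrix:
    def test_centering_and_scaling(self, rng):
        pop = founder_haplotypes(p=8, n_founders=300, rng=rng, method="markov")
        sires = select_sires(pop, 2, rng=rng)
        prog = breed_halfsibs(sires, pop, [60, 60], rng=rng)
        X, kept = prog.model_matrix()
        for fam in (0, 1):
            assert X[prog.family_ids == fam].mean(0) == pytest.approx(
                np.zeros(len(kept)), abs=1e-12
            )
        assert (X**2).mean(0) == pytest.approx(np.ones(len(kept)))

    def test_coding_invariance_up_to_sign(self, rng):
        pop = founder_haplotypes(p=5, n_founders=200, rng=rng, method="markov")
        sires = select_sires(pop, 2, rng=rng)
        prog = breed_halfsibs(sires, pop, [40, 40], rng=rng)
        X1, kept1 = prog.model_matrix()
        flipped = prog.X_raw.copy()
        flipped[:, 2] *= -1  # relabel alleles at one SNP
        prog2_X, kept2 = (
            type(prog)(X_raw=flipped, family_ids=prog.family_ids).model_matrix()
        )
        assert np.array_equal(kept1, kept2)
        assert prog2_X[:, 2] == pytest.approx(-X1[:, 2])
        others = [i for i in range(len(kept1)) if kept1[i] != 2]
        assert prog2_X[:, others] == pytest.approx(X1[:, others])


class TestSimulatePhenotype:
    def test_variance_partition(self, rng):
        pop = founder_haplotypes(p=10, n_founders=2000, rng=rng, method="markov")
        sires = select_sires(pop, 2, rng=rng)
        ratios = []
        for s in range(8):
            prog = breed_halfsibs(
                sires, pop, [400, 400], rng=np.random.default_rng(s)
            )
            simulate_phenotype(prog, [4], h2=0.5, rng=np.random.default_rng(100 + s))
            g = prog.X_raw[:, 4].astype(float)
            ratios.append(g.var() / prog.y.var())
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)

    def test_tiny_h2_gives_noise(self, rng):
        pop = founder_haplotypes(p=6, n_founders=200, rng=rng, method="markov")
        sires = select_sires(pop, 1, rng=rng)
        prog = breed_halfsibs(sires, pop, [80], rng=rng)
        simulate_phenotype(prog, [2], h2=1e-4, rng=rng)
        g = prog.X_raw[:, 2].astype(float)
        assert abs(np.corrcoef(g, prog.y)[0, 1]) < 0.15

    def test_monomorphic_qtl_rejected(self, rng):
        gmap = GeneticMap(["a", "b"], [0.0, 0.5])
        sires = SireDiplotypes(["s"], [[1, 1]], [[1, 1]])
        pool = FounderPopulation(np.ones((40, 2), np.int8), gmap, 0.0)
        prog = breed_halfsibs(sires, pool, [10], rng=rng)
        with pytest.raises(ValueError, match="genetic variance"):
            simulate_phenotype(prog, [0], h2=0.3, rng=rng)


@pytest.fixture(scope="module")
def small_cfg():
    return StudyConfig(
        kappas=(1, 2),
        h2s=(0.1, 0.3),
        N=5,
        p=60,
        n_founders=300,
        n_dam_gametes=150,
        n_replicates=2,
        n_draws=10,
        founder_method="coalescent",
        seed=5,
    )


class TestRunStudy:
    def test_deterministic_given_seed(self, small_cfg):
        r1 = run_study(small_cfg)
        r2 = run_study(small_cfg)
        assert r1["summary"] == r2["summary"]
        assert r1["replicates"][0]["cells"] == r2["replicates"][0]["cells"]

    def test_summary_structure_and_kappa_trend(self, small_cfg):
        rep = run_study(small_cfg)
        s = rep["summary"]
        assert set(s) == {
            "kappa=1,h2=0.1", "kappa=1,h2=0.3", "kappa=2,h2=0.1", "kappa=2,h2=0.3"
        }
        # more signals to separate and less heritability both cost samples
        assert s["kappa=2,h2=0.1"]["median_n_opt_star"] >= s["kappa=1,h2=0.1"][
            "median_n_opt_star"
        ]
        assert s["kappa=1,h2=0.1"]["median_n_opt_star"] >= s["kappa=1,h2=0.3"][
            "median_n_opt_star"
        ]
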