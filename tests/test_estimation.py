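"""Phenotypes, RRBLUP models, and the closed-form progeny-value calculators."""

import numpy as np
import pytest
from scipy import stats

import heterosim as hs
from heterosim import estimation as est
from heterosim.reproduction import cross

from conftest import make_population
from test_traits import manual_arch


@pytest.fixture(scope="module")
def flat_map():
    """2 chromosomes x 30 unlinked-ish loci; all loci are QTL."""
    gmap = hs.make_genome_map(2, 30, rng_seed=201)
    return hs.sample_qtl_and_markers(gmap, 30, 10, rng_seed=202)


def _sim_training(rng, n, n_markers, ploidy=2, h2=1.0, mean_dd=0.0):
    """Training set from random dosages with known marker effects."""
    x = rng.integers(0, ploidy + 1, size=(n, n_markers))
    a = rng.standard_normal(n_markers)
    d = mean_dd * np.abs(a)
    arch = manual_arch(a, d, ploidy=ploidy)
    gv, _, _ = hs.genetic_value(arch, x)
    noise_sd = np.sqrt(gv.var() * (1 - h2) / h2) if h2 < 1 else 0.0
    y = gv + rng.normal(0, noise_sd, size=n)
    w = est.TrainingWindow(capacity=n)
    for i in range(n):
        w.add(x[i], y[i])
    return w, x, gv, arch


class TestPhenotype:
    def test_zero_error_returns_gv(self, small_map, founders, arch):
        import dataclasses

        exact = dataclasses.replace(arch, sigma_e2=0.0)
        p = est.phenotype(founders, exact, np.random.default_rng(0))
        gv, _, _ = hs.genetic_value(exact, founders.dosages(exact.qtl_index))
        assert np.allclose(p, gv)

    def test_initial_broad_sense_heritability_half(self, small_map, arch, founders):
        """Cycle-0 cohort: Var(GV)/Var(P) ~ 0.5 with the fixed error variance."""
        rng = np.random.default_rng(1)
        # random-mating cycle-0 cohort
        kids = []
        idx = rng.permutation(len(founders))
        for k in range(0, len(idx) - 1, 2):
            kids.append(
                cross(founders.haplotypes[idx[k]], founders.haplotypes[idx[k + 1]],
                      70, small_map, rng)
            )
        haps = np.concatenate(kids, axis=0)
        pop = hs.Population(
            haplotypes=haps,
            ids=np.arange(len(haps)),
            pedigree=np.full((len(haps), 2), -1),
        )
        p = est.phenotype(pop, arch, rng)
        gv, _, _ = hs.genetic_value(arch, pop.dosages(arch.qtl_index))
        h2 = gv.var() / p.var()
        boots = [
            gv[s].var() / p[s].var()
            for s in (rng.integers(0, len(p), len(p)) for _ in range(200))
        ]
        assert abs(h2 - 0.5) < max(3 * np.std(boots), 0.02)


class TestDesignMatrices:
    def test_diploid_codes(self):
        Z, W, f = est.build_design_matrices(np.array([[0, 1, 2]]), 2)
        assert np.allclose(Z, [[-1, 0, 1]])
        assert np.allclose(W, [[0, 1, 0]])
        Z, W, f = est.build_design_matrices(np.array([[0, 0, 0], [1, 1, 1]]), 2)
        assert f[0] == pytest.approx(1.0), "fully homozygous -> f = 1"
        assert f[1] == pytest.approx(0.0), "fully heterozygous diploid -> f = 0"

    def test_gca_maternal_code(self):
        assert np.allclose(est._gca_code(np.array([0, 1, 2]), 2), [-1, 1, 3])


class TestTrainingWindow:
    def test_eviction_keeps_most_recent(self):
        w = est.TrainingWindow(capacity=3)
        for k in range(5):
            w.add(np.array([k]), float(k))
        assert len(w) == 3
        assert np.allclose(w.phenotypes(), [2.0, 3.0, 4.0])

    def test_records_missing_parents_dropped(self, small_map, founders):
        w = est.TrainingWindow(capacity=10)
        pop = founders.subset(np.arange(3))
        pop.pedigree = np.array([[900, 901], [900, 902], [900, 903]])
        w.add_population(pop, np.zeros(3), small_map.marker_index,
                         parent_lookup={900: np.zeros(45), 901: np.zeros(45)})
        assert len(w) == 1 and w.n_dropped == 2


class TestRRBLUPD:
    def test_recovers_additive_signal(self):
        """Noiseless additive trait: near-perfect prediction accuracy."""
        rng = np.random.default_rng(11)
        w, x, gv, _ = _sim_training(rng, 500, 200)
        fit = est.fit_rrblup_d(w, 2)
        pred = est.predict_rrblup_d(fit, x)
        assert np.corrcoef(pred, gv)[0, 1] > 0.99

    def test_reduces_to_additive_rrblup_on_inbred_training(self):
        """All-homozygous training (W = 0): matches a pure additive REML fit."""
        rng = np.random.default_rng(12)
        n, m = 150, 60
        from heterosim.traits import additive_code

        x = 2 * rng.integers(0, 2, size=(n, m))
        a = rng.standard_normal(m)
        y = additive_code(x, 2) @ a + rng.normal(0, 0.5, n)
        w = est.TrainingWindow(capacity=n)
        for i in range(n):
            w.add(x[i], y[i])
        with pytest.warns(UserWarning, match="constant"):
            fit = est.fit_rrblup_d(w, 2)
        Z = additive_code(x, 2)
        beta, s2, s2e, Hi_r = est._reml_kernels(y, np.ones((n, 1)), [Z @ Z.T])
        a_add = (s2[0] / s2e) * (Z.T @ Hi_r)
        assert np.allclose(fit.a, a_add, atol=1e-6)
        assert np.allclose(fit.d_star, 0.0, atol=1e-6)

    def test_inbreeding_depression_sign(self):
        """b-hat matches the sign of simulated inbreeding depression in >= 9/10 reps."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n, m = 150, 40
            # mix of outbred and partially inbred genotypes for f variation
            p = rng.uniform(0.2, 0.8, m)
            x_out = rng.binomial(2, p, size=(n // 2, m))
            x_inb = 2 * rng.binomial(1, p, size=(n // 2, m))
            x = np.vstack([x_out, x_inb])
            a = rng.standard_normal(m)
            arch = manual_arch(a, np.abs(a))  # complete positive dominance
            gv, _, _ = hs.genetic_value(arch, x)
            y = gv + rng.normal(0, 0.2 * gv.std(), len(gv))
            w = est.TrainingWindow(capacity=len(y))
            for i in range(len(y)):
                w.add(x[i], y[i])
            fit = est.fit_rrblup_d(w, 2)
            # positive directional dominance: fully inbred mean < HWE mean
            p_hwe, p_i = hs.population_means_hwe_inbred(arch, p)
            hits += (fit.b < 0) == (p_i < p_hwe)
        assert hits >= 9

    def test_permuted_phenotypes_have_no_accuracy(self):
        rng = np.random.default_rng(13)
        accs = []
        for rep in range(8):
            w, x, gv, _ = _sim_training(rng, 120, 40)
            y = w.phenotypes()
            rng.shuffle(y)
            w2 = est.TrainingWindow(capacity=len(y))
            geno = w.genotypes()
            for i in range(len(y)):
                w2.add(geno[i], y[i])
            fit = est.fit_rrblup_d(w2, 2)
            accs.append(np.corrcoef(est.predict_rrblup_d(fit, x), gv)[0, 1])
        assert abs(np.mean(accs)) < 3 * np.std(accs, ddof=1) / np.sqrt(len(accs)) + 0.05

    def test_accuracy_grows_with_training_size(self):
        """Held-out accuracy increases with window size (frozen variance ratios)."""
        rng = np.random.default_rng(14)
        m = 100
        p = rng.uniform(0.1, 0.9, m)
        a = rng.standard_normal(m)
        arch = manual_arch(a, 0.3 * np.abs(a))

        def simulate(n):
            x = rng.binomial(2, p, size=(n, m))
            gv, _, _ = hs.genetic_value(arch, x)
            return x, gv + rng.normal(0, gv.std(), n)

        x_test, _ = simulate(300)
        gv_test, _, _ = hs.genetic_value(arch, x_test)
        accs, theta = [], None
        for n in (250, 500, 1000, 2000):
            x, y = simulate(n)
            w = est.TrainingWindow(capacity=n)
            for i in range(n):
                w.add(x[i], y[i])
            fit = est.fit_rrblup_d(w, 2, fixed_theta=theta)
            if theta is None:
                vc = fit.varcomp
                theta = np.array([vc["s2_a"] / vc["s2_e"], vc["s2_d"] / vc["s2_e"]])
            accs.append(np.corrcoef(est.predict_rrblup_d(fit, x_test), gv_test)[0, 1])
        assert all(a > 0 for a in accs)
        assert accs[-1] > accs[0]
        assert stats.spearmanr(accs, [250, 500, 1000, 2000]).statistic > 0

    def test_too_few_records_rejected(self):
        w = est.TrainingWindow(capacity=5)
        w.add(np.array([1.0]), 0.0)
        with pytest.raises(ValueError, match="training records"):
            est.fit_rrblup_d(w, 2)


class TestRRBLUPGCA:
    def _hybrid_training(self, rng, n, m, noise=0.0):
        a = rng.standard_normal(m)
        arch = manual_arch(a, np.zeros(m))
        xm = 2 * rng.integers(0, 2, size=(n, m))  # inbred diploid parents
        xp = 2 * rng.integers(0, 2, size=(n, m))
        x_hyb = (xm + xp) // 2  # gametes of inbreds are deterministic
        gv, _, _ = hs.genetic_value(arch, x_hyb)
        y = gv + rng.normal(0, noise, n)
        w = est.TrainingWindow(capacity=n)
        for i in range(n):
            w.add(x_hyb[i], y[i], mother_dosage=xm[i], father_dosage=xp[i])
        return w, xm, xp, gv

    def test_recovers_hybrid_signal(self):
        rng = np.random.default_rng(21)
        w, xm, xp, gv = self._hybrid_training(rng, 300, 80)
        fit = est.fit_rrblup_gca(w, 2)
        pred = (
            est.predict_gca_score(fit, xm, "M") + est.predict_gca_score(fit, xp, "P")
        )
        assert np.corrcoef(pred, gv)[0, 1] > 0.99

    def test_pool_swap_symmetry(self):
        rng = np.random.default_rng(22)
        w, xm, xp, gv = self._hybrid_training(rng, 200, 50, noise=0.1)
        fit = est.fit_rrblup_gca(w, 2)
        swapped = est.TrainingWindow(capacity=len(w))
        geno, y = w.genotypes(), w.phenotypes()
        gm, gp = w.parent_genotypes()
        for i in range(len(y)):
            swapped.add(geno[i], y[i], mother_dosage=gp[i], father_dosage=gm[i])
        fit_sw = est.fit_rrblup_gca(swapped, 2)
        assert np.allclose(fit_sw.a_m, fit.a_p, atol=1e-6)
        assert np.allclose(fit_sw.a_p, fit.a_m, atol=1e-6)


class TestBreedingValue:
    def test_additive_reduction_and_centering(self, flat_map, founders=None):
        rng = np.random.default_rng(31)
        x = rng.integers(0, 3, size=(40, 10))
        p = x.mean(axis=0) / 2
        a = rng.standard_normal(10)
        bv = est.breeding_value(a, np.zeros(10), x, p, 2)
        classic = (x - 2 * p) @ a
        assert np.allclose(bv, classic)
        assert abs(bv.mean()) < 1e-10

    def test_ranking_matches_progeny_means(self, flat_map):
        """BV ranking vs brute-force mean progeny GV over random pool mates."""
        rng = np.random.default_rng(32)
        pool = hs.simulate_founder_haplotypes(30, 2, flat_map, rng_seed=33)
        arch = hs.scale_architecture(
            hs.sample_architecture(flat_map, 1.0, 0.2, 2, rng_seed=34), pool
        )
        dos = pool.dosages(arch.qtl_index)
        p = dos.mean(axis=0) / 2
        bv = est.breeding_value(arch.a, arch.d, dos, p, 2)
        n_cand, n_mates = 12, 150
        mc = []
        for i in range(n_cand):
            mates = rng.integers(0, len(pool), n_mates)
            gvs = []
            for j in mates:
                kid = cross(pool.haplotypes[i], pool.haplotypes[j], 1, flat_map, rng)
                gv, _, _ = hs.genetic_value(arch, kid.sum(axis=1)[:, arch.qtl_index])
                gvs.append(gv[0])
            mc.append(np.mean(gvs))
        rho = stats.spearmanr(bv[:n_cand], mc).statistic
        assert rho > 0.9


class TestCrossPerformance:
    def test_mendelian_examples(self):
        arch_d = manual_arch([0.0], [1.0])
        # both parents heterozygous: progeny 1/4:1/2:1/4 -> E[xD] = 0.5
        assert est.cross_performance(arch_d, np.array([1]), np.array([1])) == pytest.approx(0.5)
        # opposite homozygotes: all progeny heterozygous
        assert est.cross_performance(arch_d, np.array([0]), np.array([2])) == pytest.approx(1.0)

    @pytest.mark.parametrize("ploidy", [2, 4])
    def test_monte_carlo_oracle(self, flat_map, ploidy):
        rng = np.random.default_rng(41)
        pool = hs.simulate_founder_haplotypes(10, ploidy, flat_map, rng_seed=42)
        arch = hs.scale_architecture(
            hs.sample_architecture(flat_map, 1.0, 0.5, ploidy, rng_seed=43), pool
        )
        d1, d2 = pool.dosages(arch.qtl_index)[:2]
        closed = est.cross_performance(arch, d1, d2)
        prog = cross(pool.haplotypes[0], pool.haplotypes[1], 4000, flat_map, rng)
        gv, _, _ = hs.genetic_value(arch, prog.sum(axis=1)[:, arch.qtl_index])
        assert abs(closed - gv.mean()) < 3 * gv.std() / np.sqrt(len(gv))

    def test_ploidy_mismatch_rejected(self):
        arch = manual_arch([1.0], [0.0])
        with pytest.raises(ValueError, match="locus set"):
            est.cross_performance(arch, np.array([1]), np.array([1, 2]))


class TestGCA:
    def test_additive_gca_ranks_like_bv(self, flat_map):
        pool_a = hs.simulate_founder_haplotypes(20, 2, flat_map, rng_seed=51)
        pool_b = hs.simulate_founder_haplotypes(20, 2, flat_map, rng_seed=52)
        pool_b.pool = "B"
        arch = hs.scale_architecture(
            hs.sample_architecture(flat_map, 0.0, 0.0, 2, rng_seed=53), pool_a
        )
        dos = pool_a.dosages(arch.qtl_index)
        p = dos.mean(axis=0) / 2
        bv = est.breeding_value(arch.a, arch.d, dos, p, 2)
        gca = np.array([est.gca_true(arch, dos[i], pool_b) for i in range(len(pool_a))])
        assert stats.spearmanr(bv, gca).statistic == pytest.approx(1.0)

    def test_monte_carlo_oracle(self, flat_map):
        rng = np.random.default_rng(54)
        pool_a = hs.simulate_founder_haplotypes(10, 2, flat_map, rng_seed=55)
        pool_b = hs.simulate_founder_haplotypes(10, 2, flat_map, rng_seed=56)
        arch = hs.scale_architecture(
            hs.sample_architecture(flat_map, 1.0, 0.5, 2, rng_seed=57), pool_a
        )
        cand = pool_a.dosages(arch.qtl_index)[0]
        closed = est.gca_true(arch, cand, pool_b)
        gvs = []
        for _ in range(4000):
            j = rng.integers(0, len(pool_b))
            kid = cross(pool_a.haplotypes[0], pool_b.haplotypes[j], 1, flat_map, rng)
            gv, _, _ = hs.genetic_value(arch, kid.sum(axis=1)[:, arch.qtl_index])
            gvs.append(gv[0])
        gvs = np.array(gvs)
        assert abs(closed - gvs.mean()) < 3 * gvs.std() / np.sqrt(len(gvs))
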