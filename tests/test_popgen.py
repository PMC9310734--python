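import itertools

import numpy as np
import pytest
from scipy.special import comb

from landpop.gl import GenotypeLikelihoodSet
from landpop.popgen import (
    SiteFrequencySpectrum,
    estimate_inbreeding,
    estimate_sfs,
    fold_sfs,
    fst_from_joint_sfs,
    fst_matrix,
    gl_covariance_pca,
    individual_heterozygosity,
    intersect_sites,
    joint_sfs,
    pairwise_genetic_distance,
    site_af_likelihood,
    theta_pi,
)
from landpop.synthetic import (
    LocalityTable,
    MetapopulationTruth,
    simulate_genotype_likelihoods,
)

from conftest import certain_gl


def brute_force_af_likelihood(gls: np.ndarray) -> np.ndarray:
    """Enumeration oracle: sum over all genotype configurations with
    hypergeometric weights C(2, g_i) / C(2N, d)."""
    n = gls.shape[0]
    out = np.zeros(2 * n + 1)
    for config in itertools.product(range(3), repeat=n):
        d = sum(config)
        w = np.prod([gls[i, g] * comb(2, g) for i, g in enumerate(config)])
        out[d] += w
    out /= comb(2 * n, np.arange(2 * n + 1))
    return out / out.max()


class TestSiteAFLikelihood:
    def test_certain_genotypes_give_indicator(self):
        gls = np.zeros((3, 3))
        gls[0, 0] = gls[1, 1] = gls[2, 2] = 1
        L = site_af_likelihood(gls)
        expected = np.zeros(7)
        expected[3] = 1
        np.testing.assert_allclose(L, expected, atol=1e-12)

    def test_single_certain_homozygote(self):
        gls = np.array([[1.0, 0.0, 0.0]])
        np.testing.assert_allclose(site_af_likelihood(gls), [1, 0, 0], atol=1e-12)

    def test_two_certain_hets_peak_at_two(self):
        gls = np.zeros((2, 3))
        gls[:, 1] = 1
        L = site_af_likelihood(gls)
        assert L.argmax() == 2

    @pytest.mark.parametrize("n_ind", [2, 3, 4])
    def test_matches_enumeration_oracle(self, n_ind, rng):
        for _ in range(5):
            gls = rng.uniform(0, 1, size=(n_ind, 3))
            np.testing.assert_allclose(
                site_af_likelihood(gls), brute_force_af_likelihood(gls), atol=1e-10
            )

    def test_all_missing_site_is_flat(self):
        gls = np.ones((4, 3))
        L = site_af_likelihood(gls)
        np.testing.assert_allclose(L, 1.0, atol=1e-12)


class TestSFS:
    def test_certain_genotypes_equal_counting(self, small_certain_gl):
        gl, genotypes = small_certain_gl
        sfs = estimate_sfs(gl)
        hist = np.bincount(genotypes.sum(axis=1), minlength=2 * gl.n_individuals + 1)
        np.testing.assert_allclose(sfs.counts, hist, atol=1e-6)

    def test_em_loglik_nondecreasing(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=8,
                                            n_sites=2000, depth_mean=4, seed=2)
        sim = simulate_genotype_likelihoods(truth)
        sfs = estimate_sfs(sim.gl, tol=1e-10, max_iter=300)
        trace = np.asarray(sfs.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_recovers_realized_spectrum(self):
        # mean total-variation distance to the realized spectrum over replicates
        tvs = []
        for seed in (1, 2, 3):
            truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=20,
                                                n_sites=20000, depth_mean=10,
                                                seed=seed)
            sim = simulate_genotype_likelihoods(truth)
            sfs = estimate_sfs(sim.gl, tol=1e-7, max_iter=1000)
            realized = np.bincount(sim.true_genotypes.sum(axis=1), minlength=41)
            tvs.append(
                0.5 * np.abs(sfs.counts / sfs.n_sites
                             - realized / realized.sum()).sum()
            )
        assert np.mean(tvs) < 0.02

    def test_folding_preserves_total_and_halves_length(self):
        counts = np.array([5.0, 3, 2, 1, 2, 3, 5])  # symmetric, 2N=6
        sfs = SiteFrequencySpectrum(counts, 6)
        folded = fold_sfs(sfs)
        assert folded.counts.size == 4
        assert folded.n_sites == pytest.approx(sfs.n_sites)
        np.testing.assert_allclose(folded.counts, [10, 6, 4, 1])


class TestIntersectAndTheta:
    def test_intersection_matches_set_algebra(self, rng):
        lists = [list(rng.choice(100, size=60, replace=False)) for _ in range(6)]
        lists = [[f"s{v}" for v in lst] for lst in lists]
        expected = sorted(set.intersection(*(set(l) for l in lists)))
        assert intersect_sites(lists) == expected

    def test_simple_intersection(self):
        assert intersect_sites([["1", "2", "3"], ["2", "3", "4"]]) == ["2", "3"]
        with pytest.raises(ValueError, match="empty"):
            intersect_sites([["1"], ["2"]])

    def test_monomorphic_theta_is_zero(self):
        sfs = SiteFrequencySpectrum(np.array([10.0, 0, 0, 0, 0]), 4)
        assert theta_pi(sfs).theta_pi_total == 0

    def test_hand_example_n4(self):
        sfs = SiteFrequencySpectrum(np.array([0.0, 1, 1, 1, 0]), 4)
        est = theta_pi(sfs)
        assert est.theta_pi_total == pytest.approx((1 * 3 + 2 * 2 + 3 * 1) / 6)
        assert est.theta_pi_per_site == pytest.approx(1.6666667 / 3, rel=1e-6)

    def test_scaling_linearity(self):
        sfs = SiteFrequencySpectrum(np.array([2.0, 1, 1, 1, 1]), 4)
        scaled = SiteFrequencySpectrum(sfs.counts * 10, 4)
        assert theta_pi(scaled).theta_pi_total == pytest.approx(
            10 * theta_pi(sfs).theta_pi_total
        )
        assert theta_pi(scaled).theta_pi_per_site == pytest.approx(
            theta_pi(sfs).theta_pi_per_site
        )

    def test_brute_force_pairwise_difference_oracle(self, rng):
        # fully certain genotypes: theta-pi from the SFS must equal the mean
        # per-site difference count over all haplotype pairs
        genotypes = rng.integers(0, 3, size=(50, 6))
        gl = certain_gl(genotypes)
        est = theta_pi(estimate_sfs(gl))
        # expand to haplotypes: g copies of the derived allele in 2 slots
        hap = np.zeros((50, 12), dtype=int)
        for i in range(6):
            hap[:, 2 * i] = (genotypes[:, i] >= 1).astype(int)
            hap[:, 2 * i + 1] = (genotypes[:, i] == 2).astype(int)
        diffs = [
            (hap[:, a] != hap[:, b]).sum()
            for a, b in itertools.combinations(range(12), 2)
        ]
        assert est.theta_pi_total == pytest.approx(np.mean(diffs), abs=1e-6)


class TestHeterozygosity:
    def test_certainty_limit(self):
        gls = np.zeros((10, 3))
        gls[:4, 1] = 1
        gls[4:, 0] = 1
        assert individual_heterozygosity(gls) == pytest.approx(0.4, abs=1e-9)

    def test_all_hom_gives_zero(self):
        gls = np.zeros((10, 3))
        gls[:, 0] = 1
        assert individual_heterozygosity(gls) == pytest.approx(0.0, abs=1e-9)

    def test_all_missing_flagged(self):
        with pytest.warns(RuntimeWarning, match="no informative"):
            assert np.isnan(individual_heterozygosity(np.ones((5, 3))))

    def test_recovery_from_simulated_depth10(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=10,
                                            n_sites=5000, depth_mean=10, seed=3)
        sim = simulate_genotype_likelihoods(truth)
        i = 0
        true_het = (sim.true_genotypes[:, i] == 1).mean()
        est = individual_heterozygosity(sim.gl.likelihoods[:, i, :])
        assert est == pytest.approx(true_het, abs=0.02)


class TestInbreeding:
    def test_hwe_data_gives_near_zero_F(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=15,
                                            n_sites=10000, inbreeding=0.0,
                                            depth_mean=1e4, error_rate=0.0, seed=4)
        sim = simulate_genotype_likelihoods(truth)
        res = estimate_inbreeding(sim.gl)
        assert (res.F_per_individual < 0.02).all()

    def test_fully_homozygous_individual(self, rng):
        # one individual homozygous at every polymorphic site, rest at HWE
        genotypes = rng.integers(0, 3, size=(2000, 6))
        genotypes[:, 0] = np.where(genotypes[:, 0] == 1, 0, genotypes[:, 0])
        gl = certain_gl(genotypes)
        res = estimate_inbreeding(gl)
        assert res.F_per_individual[0] > 0.95

    def test_loglik_monotone(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=8,
                                            n_sites=2000, inbreeding=0.2,
                                            depth_mean=6, seed=5)
        sim = simulate_genotype_likelihoods(truth)
        res = estimate_inbreeding(sim.gl)
        trace = np.asarray(res.loglik_trace)
        # monotone within each EM stage (stage 2 restarts the schedule)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_parameter_recovery(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=20,
                                            n_sites=20000, inbreeding=0.3,
                                            depth_mean=10, seed=6)
        sim = simulate_genotype_likelihoods(truth)
        res = estimate_inbreeding(sim.gl)
        assert res.F_per_individual.mean() == pytest.approx(0.3, abs=0.05)


class TestGeneticDistance:
    def test_identical_and_opposite_certain_genotypes(self):
        genotypes = np.column_stack([
            np.zeros(20, dtype=int), np.zeros(20, dtype=int), np.full(20, 2)
        ])
        d = pairwise_genetic_distance(certain_gl(genotypes))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_matches_double_sum_oracle(self, rng):
        gls = rng.uniform(0.01, 1, size=(2, 3, 3))
        gl = GenotypeLikelihoodSet(["a", "b", "c"], ["s0", "s1"], gls)
        d = pairwise_genetic_distance(gl)
        post = gl.likelihoods / gl.likelihoods.sum(axis=2, keepdims=True)
        kernel = np.abs(np.subtract.outer(np.arange(3), np.arange(3))) / 2
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            manual = np.mean([
                sum(
                    post[s, i, g] * post[s, j, h] * kernel[g, h]
                    for g in range(3) for h in range(3)
                )
                for s in range(2)
            ])
            assert d.values[i, j] == pytest.approx(manual, abs=1e-12)

    def test_triangle_inequality_on_certain_data(self, rng):
        genotypes = rng.integers(0, 3, size=(100, 6))
        d = pairwise_genetic_distance(certain_gl(genotypes)).values
        n = 6
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPCA:
    def test_duplicate_individuals_have_identical_rows(self, rng):
        genotypes = rng.integers(0, 3, size=(500, 5))
        genotypes[:, 1] = genotypes[:, 0]
        res = gl_covariance_pca(certain_gl(genotypes))
        np.testing.assert_allclose(res.covariance[0], res.covariance[1], atol=1e-9)

    def test_two_demes_separate_on_pc1(self):
        truth = MetapopulationTruth.default(n_pops=2, n_ind_per_pop=10,
                                            n_sites=5000, fst_target=0.2,
                                            depth_mean=10, seed=8)
        sim = simulate_genotype_likelihoods(truth)
        res = gl_covariance_pca(sim.gl)
        pc1 = res.components[:, 0]
        assert max(pc1[:10]) < min(pc1[10:]) or min(pc1[:10]) > max(pc1[10:])

    def test_eigen_contract(self, rng):
        genotypes = rng.integers(0, 3, size=(400, 6))
        res = gl_covariance_pca(certain_gl(genotypes))
        np.testing.assert_allclose(res.covariance, res.covariance.T, atol=1e-12)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert np.isrealobj(res.eigenvalues)


class TestJointSFSAndFst:
    def test_certain_genotypes_give_exact_2d_histogram(self, rng):
        genotypes = rng.integers(0, 3, size=(200, 6))
        gl = certain_gl(genotypes)
        a = gl.subset_individuals(gl.individuals[:3])
        b = gl.subset_individuals(gl.individuals[3:])
        js = joint_sfs(a, b)
        d1 = genotypes[:, :3].sum(axis=1)
        d2 = genotypes[:, 3:].sum(axis=1)
        hist = np.zeros((7, 7))
        for x, y in zip(d1, d2):
            hist[x, y] += 1
        np.testing.assert_allclose(js.counts, hist, atol=1e-6)

    def test_marginals_match_1d_sfs(self):
        truth = MetapopulationTruth.default(n_pops=2, n_ind_per_pop=8,
                                            n_sites=4000, fst_target=0.1,
                                            depth_mean=8, seed=9)
        sim = simulate_genotype_likelihoods(truth)
        a = sim.gl.subset_individuals(sim.gl.individuals[:8])
        b = sim.gl.subset_individuals(sim.gl.individuals[8:])
        js = joint_sfs(a, b, tol=1e-8, max_iter=400)
        sfs_a = estimate_sfs(a, tol=1e-8, max_iter=400)
        assert np.abs(js.counts.sum(axis=1) - sfs_a.counts).max() < 0.01 * js.n_sites

    def test_fixed_differences_give_fst_one(self):
        counts = np.zeros((9, 9))
        counts[8, 0] = 100
        from landpop.popgen import JointSFS
        res = fst_from_joint_sfs(JointSFS(counts, (8, 8)))
        assert res.fst_weighted == pytest.approx(1.0)

    def test_panmixia_gives_near_zero_fst(self):
        truth = MetapopulationTruth.default(n_pops=2, n_ind_per_pop=15,
                                            n_sites=50000, fst_target=0.0,
                                            depth_mean=10, seed=10)
        sim = simulate_genotype_likelihoods(truth)
        a = sim.gl.subset_individuals(sim.gl.individuals[:15])
        b = sim.gl.subset_individuals(sim.gl.individuals[15:])
        res = fst_from_joint_sfs(joint_sfs(a, b, tol=1e-6, max_iter=200))
        assert abs(res.fst_weighted) < 0.01

    def test_no_variation_flagged_undefined(self):
        from landpop.popgen import JointSFS
        counts = np.zeros((5, 5))
        counts[0, 0] = 50
        res = fst_from_joint_sfs(JointSFS(counts, (4, 4)))
        assert not res.defined


class TestFstMatrix:
    @staticmethod
    def _locality_table(gl, assignment):
        import pandas as pd
        df = pd.DataFrame({
            "individual": gl.individuals,
            "locality": assignment,
            "lon": np.linspace(0, 1, len(gl.individuals)),
            "lat": np.zeros(len(gl.individuals)),
        })
        return LocalityTable.from_sample_sheet(df)

    def test_split_half_panmictic_deme_near_zero(self):
        truth = MetapopulationTruth.default(n_pops=1, n_ind_per_pop=20,
                                            n_sites=20000, fst_target=0.0,
                                            depth_mean=10, seed=11)
        sim = simulate_genotype_likelihoods(truth)
        loc = self._locality_table(sim.gl, ["A"] * 10 + ["B"] * 10)
        mat, raw = fst_matrix(sim.gl, loc)
        assert abs(raw[0, 1]) < 0.01
        assert mat.values[0, 1] >= 0

    def test_symmetry_and_zero_diagonal(self):
        truth = MetapopulationTruth.default(n_pops=3, n_ind_per_pop=5,
                                            n_sites=3000, fst_target=0.1,
                                            depth_mean=8, seed=12)
        sim = simulate_genotype_likelihoods(truth)
        loc = self._locality_table(sim.gl, sim.pop_labels)
        mat, _ = fst_matrix(sim.gl, loc)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.values), 0)
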