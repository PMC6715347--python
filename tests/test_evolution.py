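"""Population dynamics: mutation, mating lottery, recombination, regulation."""

import numpy as np
import pytest
from scipy import stats

from gamsig import (
    ConvergenceCriterion,
    EvolutionParams,
    KineticParams,
    MatingDeadlockError,
    PopulationState,
    calibrate_K,
    mutate_modifier,
    mutate_production,
    recombine_pair,
    recombine_pairs,
    regulate,
    run_to_steady_state,
    sample_matings,
    step_generation,
    symmetry_statistic,
)

KIN = KineticParams.symmetric(k_on=1.0, k_off=1.0, gamma=0.5, n_cost=1.0)


@pytest.fixture(scope="module")
def K():
    return calibrate_K(KIN)


class TestSymmetryStatistic:
    @pytest.mark.parametrize(
        "genotype, expected",
        [
            ((1.0, 1.0, 0.0, 0.0), 1.0),  # symmetric producer
            ((0.3, 0.3, 0.7, 0.7), 1.0),  # symmetric at any level
            ((1.0, 0.5, 0.0, 0.5), 0.5),
            ((1.0, 0.0, 0.0, 1.0), 0.0),  # fully polarized
        ],
    )
    def test_monomorphic_values(self, genotype, expected):
        nu = np.tile(genotype, (50, 1))
        assert symmetry_statistic(nu) == pytest.approx(expected)

    def test_two_complementary_types_fully_asymmetric(self):
        nu = np.vstack([np.tile([1, 0, 0, 1], (30, 1)), np.tile([0, 1, 1, 0], (30, 1))])
        assert symmetry_statistic(nu) == pytest.approx(0.0)

    def test_invariant_under_pair_relabeling(self):
        rng = np.random.default_rng(5)
        nu = rng.uniform(0, 0.5, (40, 4))
        relabeled = nu[:, [2, 3, 0, 1]]  # swap (L,R) <-> (l,r) in every cell
        assert symmetry_statistic(nu) == pytest.approx(symmetry_statistic(relabeled))

    def test_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            nu = rng.uniform(0, 0.5, (25, 4))
            assert 0.0 <= symmetry_statistic(nu) <= 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            symmetry_statistic(np.empty((0, 4)))


class TestMutateProduction:
    def test_no_mutation_when_mu_zero(self):
        params = EvolutionParams(N=10, mu=0.0)
        rng = np.random.default_rng(0)
        nu = np.tile([0.5, 0.5, 0.3, 0.2], (10, 1))
        np.testing.assert_array_equal(mutate_production(nu, params, rng), nu)

    def test_out_of_range_proposals_ignored(self):
        # gene pinned at the boundary: any accepted change must stay in [0, 1]
        params = EvolutionParams(N=200, mu=1.0, sigma=0.05)
        rng = np.random.default_rng(1)
        nu = np.tile([0.99, 0.005, 0.0, 0.9], (200, 1))
        out = mutate_production(nu, params, rng)
        assert (out >= 0).all() and (out <= 1).all()
        # genes whose proposal fell outside [0, 1] keep their previous value:
        # with sigma=0.05 around 0.99, accepted moves are all <= 1
        changed = out[:, 0] != 0.99
        assert (out[changed, 0] <= 1.0).all()

    def test_locus_cap_preserved(self):
        params = EvolutionParams(N=500, mu=1.0, sigma=0.3)
        rng = np.random.default_rng(2)
        nu = np.tile([0.6, 0.1, 0.4, 0.8], (500, 1))
        out = mutate_production(nu, params, rng)
        assert (out[:, 0] + out[:, 2] <= 1.0 + 1e-12).all()
        assert (out[:, 1] + out[:, 3] <= 1.0 + 1e-12).all()

    def test_single_genotype_shape(self):
        params = EvolutionParams(N=10, mu=1.0, sigma=0.01)
        rng = np.random.default_rng(3)
        g = mutate_production(np.array([0.5, 0.5, 0.2, 0.2]), params, rng)
        assert g.shape == (4,)


class TestMutateModifier:
    def test_unchanged_when_rate_zero(self):
        params = EvolutionParams(N=10, mu_rho=0.0)
        rng = np.random.default_rng(0)
        rho = np.full(10, 0.3)
        np.testing.assert_array_equal(mutate_modifier(rho, params, rng), rho)

    def test_clamped_to_valid_range(self):
        params = EvolutionParams(N=2000, mu_rho=1.0, sigma_rho=0.5)
        rng = np.random.default_rng(1)
        out = mutate_modifier(np.full(2000, 0.25), params, rng)
        assert (out >= 0.0).all() and (out <= 0.5).all()
        assert (out == 0.0).any() and (out == 0.5).any()  # both clamps exercised

    def test_long_run_drift_stays_in_range(self):
        params = EvolutionParams(N=100, mu_rho=0.05, sigma_rho=0.1)
        rng = np.random.default_rng(4)
        rho = np.full(100, 0.5)
        for _ in range(500):
            rho = mutate_modifier(rho, params, rng)
        assert (rho >= 0.0).all() and (rho <= 0.5).all()


class TestRecombination:
    def test_zero_rate_reproduces_parents(self):
        rng = np.random.default_rng(0)
        p1 = (np.array([1.0, 0.0, 0.0, 1.0]), 0.0)
        p2 = (np.array([0.0, 1.0, 1.0, 0.0]), 0.0)
        (o1, r1), (o2, r2) = recombine_pair(p1[0], p1[1], p2[0], p2[1], rng)
        np.testing.assert_array_equal(o1, p1[0])
        np.testing.assert_array_equal(o2, p2[0])

    @pytest.mark.parametrize("rho", [0.0, 0.1, 0.25, 0.5])
    def test_outcome_frequencies_match_multinomial(self, rho):
        # chi-square against the exact law {(1-r)^2, r^2, r(1-r), r(1-r)}
        rng = np.random.default_rng(17)
        n = 100_000
        nu = np.tile([[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]], (n, 1))
        rhos = np.full(2 * n, rho)
        pairs = np.arange(2 * n).reshape(n, 2)
        off_nu, off_rho = recombine_pairs(nu, rhos, pairs, rng)
        o1 = off_nu[0::2]
        # classify offspring 1: receptor locus always from parent 1
        lig_from_p2 = np.isclose(o1[:, 0], 0.0) & np.isclose(o1[:, 2], 1.0)
        # modifier origin is unobservable with equal rho; use distinct rho
        rhos2 = np.tile([0.1, 0.4], n)
        off_nu2, off_rho2 = recombine_pairs(nu, rhos2, pairs, np.random.default_rng(23))
        joint = 0.25  # (0.1 + 0.4) / 2
        lig2 = np.isclose(off_nu2[0::2][:, 0], 0.0)
        mod2 = np.isclose(off_rho2[0::2], 0.4)
        counts = np.zeros(4)
        counts[0] = np.sum(~lig2 & ~mod2)  # no recombination
        counts[1] = np.sum(~lig2 & mod2)  # modifier only (two crossovers)
        counts[2] = np.sum(lig2 & mod2)  # one crossover (ligand + modifier)
        counts[3] = np.sum(lig2 & ~mod2)  # one crossover (ligand only)
        expected = n * np.array(
            [(1 - joint) ** 2, joint**2, joint * (1 - joint), joint * (1 - joint)]
        )
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=3)
        # marginal probability that the ligand locus separates from the
        # receptor locus: the two single-crossover outcomes, 2*rho*(1-rho)
        marg = 2 * rho * (1 - rho)
        assert lig_from_p2.mean() == pytest.approx(marg, abs=4 * np.sqrt(0.25 / n) + 1e-12)

    def test_gene_content_conserved_within_pair(self):
        # recombination shuffles haplotypes between offspring, never creates
        rng = np.random.default_rng(9)
        nu = np.array([[0.7, 0.2, 0.1, 0.3], [0.4, 0.9, 0.5, 0.05]])
        rhos = np.array([0.5, 0.5])
        for _ in range(50):
            off_nu, off_rho = recombine_pairs(nu, rhos, np.array([[0, 1]]), rng)
            lig_parents = {(0.7, 0.1), (0.4, 0.5)}
            rec_parents = {(0.2, 0.3), (0.9, 0.05)}
            lig_off = {tuple(off_nu[i][[0, 2]]) for i in range(2)}
            rec_off = {tuple(off_nu[i][[1, 3]]) for i in range(2)}
            assert lig_off == lig_parents
            assert rec_off == rec_parents

    def test_free_recombination_uniform_over_configs(self):
        rng = np.random.default_rng(33)
        n = 40_000
        nu = np.tile([[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]], (n, 1))
        rhos = np.tile([0.5, 0.5], n)
        off_nu, off_rho = recombine_pairs(nu, rhos, np.arange(2 * n).reshape(n, 2), rng)
        lig2 = np.isclose(off_nu[0::2][:, 0], 0.0)
        assert lig2.mean() == pytest.approx(0.5, abs=0.01)


class TestRegulate:
    def test_exact_size_restored(self):
        rng = np.random.default_rng(0)
        nu = np.tile([1.0, 1.0, 0.0, 0.0], (50, 1))
        out_nu, out_rho = regulate(nu, np.zeros(50), 137, rng)
        assert out_nu.shape == (137, 4)
        assert out_rho.shape == (137,)

    def test_single_genotype_fixed(self):
        rng = np.random.default_rng(1)
        nu = np.tile([0.2, 0.8, 0.1, 0.1], (10, 1))
        out_nu, _ = regulate(nu, np.zeros(10), 100, rng)
        assert np.all(out_nu == [0.2, 0.8, 0.1, 0.1])

    def test_unbiased_resampling(self):
        # mean post-regulation frequency of a tagged genotype matches its
        # offspring frequency within 3 standard errors (binomial sampling)
        rng = np.random.default_rng(2)
        nu = np.vstack([np.tile([1.0, 0, 0, 0], (30, 1)), np.tile([0, 1.0, 0, 0], (70, 1))])
        freqs = []
        for _ in range(1000):
            out_nu, _ = regulate(nu, np.zeros(100), 100, rng)
            freqs.append(np.mean(out_nu[:, 0] == 1.0))
        se = np.sqrt(0.3 * 0.7 / 100 / 1000)
        assert np.mean(freqs) == pytest.approx(0.3, abs=3 * se)

    def test_empty_offspring_rejected(self):
        with pytest.raises(ValueError):
            regulate(np.empty((0, 4)), np.empty(0), 10, np.random.default_rng(0))


class TestMatingLottery:
    def test_quota_and_distinctness(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 40, seed=0)
        params = EvolutionParams(N=40, M=20, mu=0.0)
        pairs = sample_matings(pop, KIN, K, params)
        assert pairs.shape == (10, 2)
        flat = pairs.ravel()
        assert len(np.unique(flat)) == 20  # M distinct cells
        assert (pairs[:, 0] != pairs[:, 1]).all()

    def test_complementary_types_mate_heterotypically(self, K):
        # identical fully asymmetric cells cannot signal to each other at all
        pop = PopulationState.from_frequencies(
            [(1, 0, 0, 1), (0, 1, 1, 0)], [0.5, 0.5], 100, seed=1
        )
        params = EvolutionParams(N=100, M=50, mu=0.0)
        for _ in range(20):
            pairs = sample_matings(pop, KIN, K, params)
            t1 = pop.nu[pairs[:, 0], 0] == 1.0
            t2 = pop.nu[pairs[:, 1], 0] == 1.0
            assert (t1 != t2).all()  # every accepted pair is heterotypic

    def test_monomorphic_acceptance_rate_matches_closed_form(self, K):
        # Monte-Carlo acceptance frequency vs the saturating probability law
        from gamsig.evolution import population_signal_states, _pair_probabilities

        pop = PopulationState.monomorphic((1, 1, 0, 0), 30, seed=2)
        L, R, C = population_signal_states(pop.nu, KIN)
        p = float(_pair_probabilities(np.array([0]), np.array([1]), L, R, C, KIN, K)[0])
        rng = np.random.default_rng(3)
        n = 40_000
        accepted = (rng.random(n) < p).mean()
        assert accepted == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / n))

    def test_two_cells_always_pair(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 2, seed=4)
        params = EvolutionParams(N=2, M=2, mu=0.0)
        pairs = sample_matings(pop, KIN, K, params)
        assert sorted(pairs.ravel().tolist()) == [0, 1]

    def test_incompatible_population_aborts(self, K):
        # all cells at (1,0,0,1): no pair can signal, the population is unviable
        pop = PopulationState.monomorphic((1, 0, 0, 1), 20, seed=5)
        params = EvolutionParams(N=20, M=10, mu=0.0, mate_attempt_cap=20_000)
        with pytest.raises(MatingDeadlockError):
            sample_matings(pop, KIN, K, params)


class TestGenerationStep:
    def test_population_invariant_without_mutation(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 20, seed=0)
        params = EvolutionParams(N=20, M=20, mu=0.0, mu_rho=0.0)
        for _ in range(5):
            step_generation(pop, KIN, K, params)
        assert np.all(pop.nu == [1, 1, 0, 0])
        assert pop.generation == 5

    def test_population_size_constant(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 60, seed=1)
        params = EvolutionParams(N=60, M=30, mu=0.05, sigma=0.1, mu_rho=0.02)
        for _ in range(10):
            step_generation(pop, KIN, K, params)
            assert pop.size == 60
            assert (pop.nu[:, 0] + pop.nu[:, 2] <= 1 + 1e-12).all()
            assert (pop.nu[:, 1] + pop.nu[:, 3] <= 1 + 1e-12).all()
            assert (pop.rho >= 0).all() and (pop.rho <= 0.5).all()

    def test_seeded_determinism(self, K):
        runs = []
        for _ in range(2):
            pop = PopulationState.monomorphic((1, 1, 0, 0), 50, seed=1234)
            params = EvolutionParams(N=50, M=24, mu=0.05, sigma=0.1, mu_rho=0.01)
            for _ in range(15):
                step_generation(pop, KIN, K, params)
            runs.append((pop.nu.copy(), pop.rho.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_complementary_types_stay_balanced(self, K):
        # heterotypic-only mating yields exactly 1:1 offspring, so type
        # frequencies stay near 0.5, bounded by resampling drift
        pop = PopulationState.from_frequencies(
            [(1, 0, 0, 1), (0, 1, 1, 0)], [0.5, 0.5], 200, seed=7
        )
        params = EvolutionParams(N=200, M=100, mu=0.0)
        freqs = []
        for _ in range(300):
            step_generation(pop, KIN, K, params)
            freqs.append(np.mean(pop.nu[:, 0] == 1.0))
        freqs = np.asarray(freqs)
        # offspring pool is exactly balanced each generation; the only noise
        # is the binomial regulation step, sd = 0.5/sqrt(N)
        sd = 0.5 / np.sqrt(200)
        assert np.all(np.abs(freqs - 0.5) < 5 * sd)

    def test_neutral_drift_variance(self, K):
        # with selection switched off (identical genotypes, tagged via a
        # neutral rho marker) the per-generation change in marker frequency
        # is the sum of two sampling stages: choosing M maters out of N
        # without replacement (hypergeometric) and resampling N offspring
        # with replacement from the M (binomial)
        N, M = 200, 100
        params = EvolutionParams(N=N, M=M, mu=0.0, mu_rho=0.0)
        deltas = []
        for seed in range(100):
            pop = PopulationState.monomorphic((1, 1, 0, 0), N, seed=seed)
            pop.rho = np.where(np.arange(N) < N // 2, 0.0, 0.25)  # neutral tag
            step_generation(pop, KIN, K, params)
            deltas.append(np.mean(pop.rho == 0.25) - 0.5)
        var = np.var(deltas)
        expected = 0.25 * ((1 / M) * (N - M) / (N - 1) + 1 / N)
        assert expected * 0.6 < var < expected * 1.6


class TestRunToSteadyState:
    def test_converges_immediately_when_static(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 20, seed=0)
        params = EvolutionParams(N=20, M=10, mu=0.0, max_generations=5000)
        out = run_to_steady_state(pop, KIN, K, params)
        assert out.converged
        assert out.generations == params.convergence.window
        assert out.s_star == pytest.approx(1.0)

    def test_trajectory_bounded_by_cap(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 30, seed=1)
        params = EvolutionParams(
            N=30, M=14, mu=0.2, sigma=0.2, max_generations=150,
            convergence=ConvergenceCriterion(epsilon_s=1e-12),
        )
        out = run_to_steady_state(pop, KIN, K, params)
        assert out.generations <= 150
        assert len(out.trajectory) == out.generations + 1

    def test_reported_star_is_trailing_mean(self, K):
        pop = PopulationState.monomorphic((1, 1, 0, 0), 30, seed=2)
        params = EvolutionParams(
            N=30, M=14, mu=0.1, sigma=0.1, max_generations=80,
            convergence=ConvergenceCriterion(epsilon_s=1e-12, report_window=50),
        )
        out = run_to_steady_state(pop, KIN, K, params)
        assert out.s_star == pytest.approx(out.trajectory.s.iloc[-50:].mean())
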