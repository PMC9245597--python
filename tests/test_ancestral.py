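"""Simulator correctness: oracle agreement with the closed forms, unit
conversions under demography, and the panel engine's marginal law."""

import numpy as np
import pytest
from scipy import stats

from stratld import theory
from stratld.ancestral import (
    Demography,
    HaplotypeSampleConfig,
    effective_ne_pairwise,
    mc_corr_branch_length,
    mc_corr_pairwise_diff,
    pairwise_coal_times,
    simulate_pair,
    simulate_pair_demography,
    simulate_pairs,
    simulate_pairs_demography,
    simulate_panel,
)
from stratld.theory import TwoLocusParams


def _binom_3se(p, n):
    return 3.0 * np.sqrt(max(p * (1 - p), 1e-12) / n)


class TestPairSimulator:
    def test_fully_linked_loci_share_one_genealogy(self):
        reps = simulate_pairs(TwoLocusParams(rho=0.0, t_a=0.7), 2000, 1)
        np.testing.assert_array_equal(reps.T_A, reps.T_B)
        np.testing.assert_array_equal(reps.L_A, reps.L_B)
        assert not reps.uncoupled_at_ta.any()

    def test_marginal_coalescence_time_is_standard_exponential(self):
        # marginally each locus is a two-lineage Kingman coalescent: T ~ Exp(1)
        n = 40_000
        reps = simulate_pairs(TwoLocusParams(rho=2.0, t_a=0.5), n, 2)
        for t in (reps.T_A, reps.T_B):
            assert abs(t.mean() - 1.0) < 3.0 / np.sqrt(n)
        assert stats.kstest(reps.T_A, "expon").pvalue > 0.01

    def test_uncoupled_frequency_matches_uncoupling_probability(self):
        n = 100_000
        reps = simulate_pairs(TwoLocusParams(rho=1.0, t_a=1.0), n, 3)
        p = theory.p_uncoupled(1.0, 1.0)
        assert abs(reps.uncoupled_at_ta.mean() - p) < _binom_3se(p, n)

    def test_locus_exchangeability_at_ta0(self):
        reps = simulate_pairs(TwoLocusParams(rho=1.0, t_a=0.0), 20_000, 4)
        assert stats.ks_2samp(reps.T_A, reps.T_B).pvalue > 0.01

    def test_branch_length_accounting(self):
        g = simulate_pair(TwoLocusParams(rho=1.0, t_a=0.3), 5)
        assert g.L_A == pytest.approx(0.3 + 2 * g.T_A)
        assert g.L_B >= 0.3 and g.T_B > 0

    def test_same_seed_reproduces_different_seed_varies(self):
        p = TwoLocusParams(rho=1.5, t_a=0.2)
        a = simulate_pairs(p, 500, 42)
        b = simulate_pairs(p, 500, 42)
        c = simulate_pairs(p, 500, 43)
        np.testing.assert_array_equal(a.T_A, b.T_A)
        assert not np.array_equal(a.T_A, c.T_A)

    def test_invalid_seed_type_rejected(self):
        with pytest.raises(TypeError):
            simulate_pair(TwoLocusParams(rho=1.0), "not-a-seed")


class TestMonteCarloEstimators:
    def test_corr_is_exactly_one_without_recombination(self):
        assert mc_corr_branch_length(TwoLocusParams(rho=0.0, t_a=1.0), 100, 1) == (1.0, 0.0)

    def test_corr_branch_length_matches_closed_form(self):
        n = 50_000
        for seed, (rho, ta) in enumerate([(1.0, 0.0), (4.0, 0.25)]):
            r, se = mc_corr_branch_length(TwoLocusParams(rho=rho, t_a=ta), n, 10 + seed)
            assert abs(r - theory.corr_branch_length(rho, ta)) < 3.5 * se

    def test_corr_pairwise_diff_matches_closed_form(self):
        r, se = mc_corr_pairwise_diff(TwoLocusParams(rho=1.0, theta=0.4, t_a=0.0), 50_000, 20)
        assert abs(r - theory.corr_pairwise_diff(1.0, 0.4, 0.0)) < 3.5 * se

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mc_corr_branch_length(TwoLocusParams(rho=1.0), 5, 1)


class TestDemographyMode:
    def test_single_epoch_reduces_to_coalescent_units(self):
        ne = 10_000
        reps_g = simulate_pairs_demography(1e-4, 0.0, Demography.constant(ne), 10_000, 1)
        reps_c = simulate_pairs(TwoLocusParams(rho=4.0, t_a=0.0), 10_000, 2)
        assert stats.ks_2samp(reps_g.T_A / (2 * ne), reps_c.T_A).pvalue > 0.01

    def test_uncoupling_under_constant_demography_matches_theory(self):
        ne = 10_000
        n = 50_000
        reps = simulate_pairs_demography(1e-4, 500.0, Demography.constant(ne), n, 3)
        p = theory.p_uncoupled(4.0, 500.0 / (2 * ne))
        assert abs(reps.uncoupled_at_ta.mean() - p) < _binom_3se(p, n)

    def test_instantaneous_growth_coalescence_concentration(self):
        # recent Ne=1e6, ancient Ne=1e3 before 100 generations: the pair
        # almost surely survives the large epoch, then coalesces at rate
        # 1/2000 per generation.  Exact epoch integral as the oracle.
        dem = Demography([(0.0, 1e6), (100.0, 1e3)])
        n = 20_000
        t2 = pairwise_coal_times(dem, n, 4)
        p_recent = 1.0 - np.exp(-100.0 / 2e6)
        p_window = np.exp(-100.0 / 2e6) * (1.0 - np.exp(-1900.0 / 2e3))
        assert abs(np.mean(t2 < 100.0) - p_recent) < _binom_3se(p_recent, n)
        assert abs(np.mean((t2 >= 100.0) & (t2 < 2000.0)) - p_window) < _binom_3se(p_window, n)

    def test_empty_demography_rejected(self):
        with pytest.raises(ValueError):
            Demography([])
        with pytest.raises(ValueError):
            Demography([(10.0, 1e4)])  # first epoch must start at 0

    def test_single_replicate_api(self):
        g = simulate_pair_demography(1e-4, 200.0, Demography.constant(5000), 7)
        assert g.L_A == pytest.approx(200.0 + 2 * g.T_A)


class TestEffectiveNe:
    def test_constant_size_recovered(self):
        ne = effective_ne_pairwise(Demography.constant(10_000), 20_000, 1)
        # E[T2] = 2 Ne, sd(T2) = 2 Ne
        assert abs(ne - 10_000) < 3.0 * 10_000 / np.sqrt(20_000)

    def test_two_epoch_matches_survival_integral(self):
        dem = Demography([(0.0, 1e6), (100.0, 1e3)])
        n = 40_000
        # closed-form E[T2] by integrating the survival function epoch-wise
        s100 = np.exp(-100.0 / 2e6)
        expected = 2e6 * (1 - s100) + s100 * 2e3
        est = effective_ne_pairwise(dem, n, 2)
        sd = np.std(pairwise_coal_times(dem, n, 2)) / 2.0
        assert abs(est - expected / 2.0) < 3.0 * sd / np.sqrt(n)

    def test_single_replicate_is_half_draw(self):
        t2 = pairwise_coal_times(Demography.constant(1234.0), 1, 5)
        assert effective_ne_pairwise(Demography.constant(1234.0), 1, 5) == t2[0] / 2.0


class TestPanelEngine:
    def test_zero_mutation_rate_gives_empty_matrix(self):
        pan = simulate_panel(
            TwoLocusParams(rho=1.0, theta=1e-300),
            HaplotypeSampleConfig(n_modern=4),
            1,
        )
        assert pan.haps.n_sites == 0

    def test_fully_linked_loci_have_equal_mrca_times(self):
        pan = simulate_panel(
            TwoLocusParams(rho=0.0, theta=1.0),
            HaplotypeSampleConfig(n_modern=3, n_ancient=2, t_a=0.1),
            2,
        )
        assert pan.t_mrca_a == pytest.approx(pan.t_mrca_b)
        assert pan.L_a == pytest.approx(pan.L_b)

    def test_pair_mean_pairwise_difference_is_theta(self):
        # E[pi] = theta for two modern haplotypes at one locus
        theta = 1.0
        rng = np.random.default_rng(3)
        pis = []
        for _ in range(2000):
            pan = simulate_panel(
                TwoLocusParams(rho=1.0, theta=theta), HaplotypeSampleConfig(n_modern=2), rng
            )
            g = pan.haps.genotypes[:, pan.haps.chrom == "locusA"]
            pis.append(int((g[0] != g[1]).sum()))
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 3 * se

    def test_marginal_law_matches_pair_engine(self):
        p = TwoLocusParams(rho=1.0, theta=0.4, t_a=0.2)
        rng = np.random.default_rng(4)
        t_panel = [
            simulate_panel(p, HaplotypeSampleConfig(n_modern=1, n_ancient=1, t_a=0.2), rng).t_mrca_a
            - 0.2
            for _ in range(2000)
        ]
        t_pair = simulate_pairs(p, 2000, 5).T_A
        assert stats.ks_2samp(t_panel, t_pair).pvalue > 0.01

    def test_ancient_sample_times_recorded_in_generations(self):
        pan = simulate_panel(
            TwoLocusParams(rho=1.0, theta=0.5),
            HaplotypeSampleConfig(n_modern=2, n_ancient=2, t_a=0.05),
            6,
            ne_ref=10_000,
        )
        np.testing.assert_allclose(np.sort(np.unique(pan.haps.sample_times)), [0.0, 1000.0])

    def test_too_few_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeSampleConfig(n_modern=1)


class TestMsprimeCrossCheck:
    """Independent oracle: the same modern+ancient two-locus law simulated by
    an external coalescent simulator must agree with the closed form."""

    def test_branch_length_correlation_matches_external_simulator(self):
        msprime = pytest.importorskip("msprime")
        ne, r, age, n = 5000, 1e-4, 500, 30_000
        rho = 4 * ne * r
        samples = [
            msprime.SampleSet(1, time=0, ploidy=1),
            msprime.SampleSet(1, time=age, ploidy=1),
        ]
        la = np.empty(n)
        lb = np.empty(n)
        reps = msprime.sim_ancestry(
            samples=samples,
            population_size=ne,
            recombination_rate=r,
            sequence_length=2,
            discrete_genome=True,
            num_replicates=n,
            random_seed=11,
        )
        for i, ts in enumerate(reps):
            for tr in ts.trees():
                if tr.interval.left == 0:
                    la[i] = tr.total_branch_length
                if tr.interval.right == 2:
                    lb[i] = tr.total_branch_length
        c = np.corrcoef(la, lb)[0, 1]
        expected = theory.corr_branch_length(rho, age / (2 * ne))
        assert abs(c - expected) < 3.5 * (1 - c**2) / np.sqrt(n)
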