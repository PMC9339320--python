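"""Gamete sampling, progeny simulation, look-ahead recombination, and the
exactness of the Markov mosaic against enumeration oracles."""

import numpy as np
import pytest
from scipy import stats

from pvlas import (
    CrossSet,
    GeneticMap,
    GenotypeTensor,
    TraitModel,
    enumerate_gamete_distribution,
    gebv,
    lookahead_recomb,
    make_progeny,
    sample_gamete,
    sample_gametes,
    simulate_descendant_progeny,
)
from pvlas.errors import SizeError
from pvlas.meiosis import descendant_score_samples, haplotype_pool

from conftest import (
    empirical_tv_distance,
    enumerated_progeny_mean,
    random_three_locus_instance,
)


class TestSampleGamete:
    def test_no_recombination_returns_whole_parental_haplotype(self, rng):
        hap1 = np.array([0, 0, 0, 0])
        hap2 = np.array([1, 1, 1, 1])
        gmap = GeneticMap(recomb=np.zeros(3), chrom=[0] * 4)
        draws = sample_gametes(hap1, hap2, gmap, 2000, rng)
        whole = (draws == 0).all(axis=1) | (draws == 1).all(axis=1)
        assert whole.all()
        frac_hap1 = (draws == 0).all(axis=1).mean()
        assert frac_hap1 == pytest.approx(0.5, abs=0.05)

    def test_homozygous_parent_transmits_exactly(self, rng):
        hap = np.array([1, 0, 1])
        gmap = GeneticMap(recomb=[0.3, 0.1], chrom=[0, 0, 0])
        for _ in range(20):
            assert np.array_equal(sample_gamete(hap, hap, gmap, rng), hap)

    @pytest.mark.parametrize("seed", range(4))
    def test_mosaic_conservation(self, seed):
        rng = np.random.default_rng(seed)
        hap1 = rng.integers(0, 2, 8)
        hap2 = rng.integers(0, 2, 8)
        gmap = GeneticMap(recomb=rng.uniform(0, 0.5, 7), chrom=[0] * 8)
        draws = sample_gametes(hap1, hap2, gmap, 500, rng)
        ok = (draws == hap1) | (draws == hap2)
        assert ok.all()

    def test_independent_sources_at_half_recombination(self, rng):
        # with r = 0.5 the source (observable through opposite homozygous
        # haplotypes) must be independent across adjacent loci
        hap1 = np.zeros(3, dtype=int)
        hap2 = np.ones(3, dtype=int)
        gmap = GeneticMap(recomb=[0.5, 0.5], chrom=[0, 1, 2])
        draws = sample_gametes(hap1, hap2, gmap, 50_000, rng)
        for l in range(2):
            table = np.zeros((2, 2))
            for a in (0, 1):
                for b in (0, 1):
                    table[a, b] = np.sum((draws[:, l] == a) & (draws[:, l + 1] == b))
            _, p, _, _ = stats.chi2_contingency(table)
            assert p > 0.001


class TestEnumerationOracle:
    def test_single_locus_halves(self):
        gmap = GeneticMap(recomb=np.empty(0), chrom=[0])
        dist = enumerate_gamete_distribution(np.array([0]), np.array([1]), gmap)
        assert dist == {(0,): pytest.approx(0.5), (1,): pytest.approx(0.5)}
        merged = enumerate_gamete_distribution(np.array([1]), np.array([1]), gmap)
        assert merged == {(1,): pytest.approx(1.0)}

    def test_two_locus_chain_probabilities(self):
        gmap = GeneticMap(recomb=[0.1], chrom=[0, 0])
        dist = enumerate_gamete_distribution(np.array([0, 0]), np.array([1, 1]), gmap)
        assert dist[(0, 0)] == pytest.approx(0.45)
        assert dist[(0, 1)] == pytest.approx(0.05)
        assert dist[(1, 0)] == pytest.approx(0.05)
        assert dist[(1, 1)] == pytest.approx(0.45)

    @pytest.mark.parametrize("seed", range(3))
    def test_probabilities_sum_to_one(self, seed):
        hap1, hap2, gmap = random_three_locus_instance(seed)
        dist = enumerate_gamete_distribution(hap1, hap2, gmap)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_size_guard(self):
        gmap = GeneticMap(recomb=np.zeros(16), chrom=[0] * 17)
        with pytest.raises(SizeError):
            enumerate_gamete_distribution(np.zeros(17), np.ones(17), gmap)

    @pytest.mark.parametrize("seed", range(3))
    def test_sampler_matches_enumeration(self, seed):
        hap1, hap2, gmap = random_three_locus_instance(seed)
        rng = np.random.default_rng(1000 + seed)
        draws = sample_gametes(hap1, hap2, gmap, 20_000, rng)
        exact = enumerate_gamete_distribution(hap1, hap2, gmap)
        assert empirical_tv_distance(draws, exact) < 0.02


class TestLookaheadRecomb:
    def test_zero_for_first_two_offsets(self):
        gmap = GeneticMap(recomb=[0.1, 0.4], chrom=[0, 0, 0])
        for tau in (1, 2):
            assert np.all(lookahead_recomb(gmap, tau, S=10) == 0.0)

    def test_hand_evaluated_closed_form(self):
        gmap = GeneticMap(recomb=[0.1], chrom=[0, 0])
        assert lookahead_recomb(gmap, 3, S=10)[0] == pytest.approx(0.2439)

    def test_zero_map_stays_zero(self):
        gmap = GeneticMap(recomb=np.zeros(4), chrom=[0] * 5)
        for tau in (1, 3, 7):
            assert np.all(lookahead_recomb(gmap, tau, S=5) == 0.0)

    def test_monotone_in_tau_and_bounded(self):
        gmap = GeneticMap(recomb=[0.05, 0.3, 0.5], chrom=[0, 0, 0, 1])
        S = 7
        previous = lookahead_recomb(gmap, 3, S)
        for tau in range(4, 12):
            current = lookahead_recomb(gmap, tau, S)
            assert np.all(current >= previous - 1e-15)
            previous = current
        assert np.all(previous <= (S - 1) / S + 1e-15)


class TestMakeProgeny:
    def test_homozygous_loci_breed_true(self, rng):
        alleles = np.zeros((3, 2, 2), dtype=int)
        alleles[0] = 1  # both parents homozygous major at locus 0
        g = GenotypeTensor(alleles)
        gmap = GeneticMap(recomb=[0.2, 0.2], chrom=[0] * 3)
        progeny = make_progeny(g, (0, 1), 50, gmap, rng)
        assert progeny.generation == 1
        assert progeny.n_individuals == 50
        assert (progeny.alleles[0] == 1).all()
        assert (progeny.alleles[1:] == 0).all()

    def test_progeny_gebv_within_parental_mosaic_bounds(self, small_population, rng):
        founders, trait, gmap = small_population
        progeny = make_progeny(founders, (0, 3), 200, gmap, rng)
        w = trait.beta[:, None, None] * founders.alleles[:, :, [0, 3]]
        w = w.reshape(founders.n_loci, 4)
        lo = trait.mu + 2 * w.min(axis=1).sum()
        hi = trait.mu + 2 * w.max(axis=1).sum()
        v = gebv(progeny, trait)
        assert (v >= lo - 1e-9).all() and (v <= hi + 1e-9).all()

    def test_selfing_heterozygote_segregates_one_quarter_half_one_quarter(self, rng):
        alleles = np.zeros((1, 2, 1), dtype=int)
        alleles[0, 0, 0] = 1  # single heterozygous locus
        g = GenotypeTensor(alleles)
        gmap = GeneticMap(recomb=np.empty(0), chrom=[0])
        progeny = make_progeny(g, (0, 0), 4000, gmap, rng)
        dosage = progeny.alleles[0].sum(axis=0)
        freqs = [(dosage == d).mean() for d in (0, 1, 2)]
        assert freqs[0] == pytest.approx(0.25, abs=0.03)
        assert freqs[1] == pytest.approx(0.5, abs=0.03)
        assert freqs[2] == pytest.approx(0.25, abs=0.03)


class TestDescendantProgeny:
    def test_selfed_homozygote_is_degenerate_at_any_offset(self, rng):
        alleles = np.ones((4, 2, 3), dtype=int)
        alleles[:, :, 1:] = 0  # individuals 1,2 all-minor; individual 0 all-major
        g = GenotypeTensor(alleles)
        trait = TraitModel([1.0, -0.5, 2.0, 0.25], mu=1.0)
        gmap = GeneticMap(recomb=[0.3, 0.1, 0.5], chrom=[0, 0, 0, 1])
        crosses = CrossSet([(0, 0)])
        v0 = gebv(g, trait)[0]
        for tau in (1, 2, 3, 5):
            samples = simulate_descendant_progeny(g, crosses, tau, trait, gmap, 64, rng)
            np.testing.assert_allclose(samples, v0)

    def test_one_cross_no_recombination_is_uniform_over_four_sums(self, rng):
        rng_data = np.random.default_rng(5)
        alleles = rng_data.integers(0, 2, (5, 2, 2))
        g = GenotypeTensor(alleles)
        trait = TraitModel(rng_data.normal(size=5), mu=0.0)
        gmap = GeneticMap(recomb=np.zeros(4), chrom=[0] * 5)
        crosses = CrossSet([(0, 1)])
        w = trait.beta[:, None, None] * alleles
        hap_sums = w.sum(axis=0)  # (2, 2): haplotype score per (m, i)
        outcomes = np.array(
            [hap_sums[a, 0] + hap_sums[b, 1] for a in (0, 1) for b in (0, 1)]
        )
        samples = simulate_descendant_progeny(g, crosses, 1, trait, gmap, 8000, rng)
        # every sample is one of the 4 haplotype-pair sums ...
        assert np.isin(np.round(samples, 9), np.round(outcomes, 9)).all()
        # ... with observed frequency 1/4 each when outcome values are distinct
        if len(np.unique(np.round(outcomes, 9))) == 4:
            for outcome in outcomes:
                frac = np.isclose(samples, outcome).mean()
                assert frac == pytest.approx(0.25, abs=0.025)

    @pytest.mark.parametrize("tau", [2, 3, 5])
    def test_empirical_mean_matches_path_enumeration(self, tau):
        # 3-locus, 2-cross instance small enough for exact path enumeration
        rng_data = np.random.default_rng(7)
        hap_scores = rng_data.normal(size=(3, 2, 4))
        recomb = np.array([0.15, 0.4])
        crosses = CrossSet([(0, 1), (2, 3)])
        pool = haplotype_pool(hap_scores, crosses)
        exact_mean = enumerated_progeny_mean(pool, recomb, tau)
        rng = np.random.default_rng(900 + tau)
        samples = descendant_score_samples(
            hap_scores, recomb, crosses, tau, 20_000, rng
        )
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert samples.mean() == pytest.approx(exact_mean, abs=3 * se)

    def test_samples_bounded_by_selected_parent_potentials(self, small_population, rng):
        founders, trait, gmap = small_population
        crosses = CrossSet([(0, 2), (1, 1)])
        parents = [0, 1, 2]
        w = trait.beta[:, None, None] * founders.alleles[:, :, parents]
        w = w.reshape(founders.n_loci, -1)
        lo = trait.mu + 2 * w.min(axis=1).sum()
        hi = trait.mu + 2 * w.max(axis=1).sum()
        for tau in (1, 2, 4):
            samples = simulate_descendant_progeny(
                founders, crosses, tau, trait, gmap, 500, rng
            )
            assert (samples >= lo - 1e-9).all() and (samples <= hi + 1e-9).all()
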