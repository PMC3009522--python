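import numpy as np
import pytest

from mfge import (
    Chromosome,
    GAConfig,
    crossover,
    init_chromosome,
    migrate,
    mutate,
    population_similarity,
    run_ge,
    run_iteration,
    tournament_select,
)
from mfge.ensemble import FitnessValue
from mfge.mapping import GeneFrequencyMap


def uniform_map(n=20, seed=0):
    return GeneFrequencyMap([f"g{i}" for i in range(n)],
                            np.ones(n, dtype=int), seed=seed)


def weighted_map(mult, seed=0):
    return GeneFrequencyMap([f"g{i}" for i in range(len(mult))],
                            np.asarray(mult), seed=seed)


def fv(x, size_penalty=0.0):
    return FitnessValue(x, x, x - size_penalty)


def chrom(codes, size=15, fitness=None):
    slots = np.zeros(size, dtype=np.int64)
    slots[:len(codes)] = codes
    return Chromosome(slots, fitness)


class TestInitChromosome:
    def test_saturated_draw_distinct(self):
        rng = np.random.default_rng(0)
        c = init_chromosome(uniform_map(20), 15, 1.0, rng)
        assert c.subset_size == 15
        assert len(c.decode()) == 15

    def test_mean_size_in_operating_band(self):
        """fill_prob 0.4 on 15 slots gives mean subset size ~6, inside the
        2-10 band the engine is tuned for."""
        rng = np.random.default_rng(1)
        fmap = uniform_map(200)
        sizes = [init_chromosome(fmap, 15, 0.4, rng).subset_size
                 for _ in range(2000)]
        assert 2 < np.mean(sizes) < 10
        assert abs(np.mean(sizes) - 6.0) < 0.35

    def test_inclusion_tracks_scores(self):
        """Per-gene inclusion frequency increases with map multiplicity."""
        rng = np.random.default_rng(2)
        mult = np.arange(1, 21)
        fmap = weighted_map(mult)
        counts = np.zeros(21)
        for _ in range(4000):
            for code in init_chromosome(fmap, 15, 0.4, rng).decode():
                counts[code] += 1
        from scipy.stats import spearmanr
        rho, _ = spearmanr(mult, counts[1:])
        assert rho > 0.9

    def test_exhaustion_leaves_zeros(self):
        rng = np.random.default_rng(3)
        c = init_chromosome(uniform_map(4), 15, 1.0, rng)
        assert c.subset_size == 4
        assert (c.slots == 0).sum() == 11


class TestCrossover:
    def test_no_crossover_at_p_zero(self):
        rng = np.random.default_rng(0)
        a, b = chrom([1, 2]), chrom([3, 4])
        c, d = crossover(a, b, 0.0, rng)
        np.testing.assert_array_equal(c.slots, a.slots)
        np.testing.assert_array_equal(d.slots, b.slots)

    def test_tails_swapped(self):
        rng = np.random.default_rng(1)
        a, b = chrom([1, 2, 5, 6]), chrom([3, 4, 7, 8])
        c, d = crossover(a, b, 1.0, rng)
        assert len(c.slots) == len(a.slots) == len(d.slots)
        # union of offspring genes equals union of parent genes
        assert c.decode() | d.decode() <= a.decode() | b.decode()

    def test_duplicate_repair(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = chrom([1, 2, 9]), chrom([9, 4, 5])
            c, d = crossover(a, b, 1.0, rng)
            for off in (c, d):
                assert off.is_valid(15)


class TestMutate:
    def test_identity_at_p_zero(self):
        rng = np.random.default_rng(0)
        c = chrom([1, 2, 3])
        out = mutate(c, uniform_map(), 0.0, 0.25, rng)
        np.testing.assert_array_equal(out.slots, c.slots)

    def test_chained_law_expectation(self):
        """E[mutations] = p_m / (1 - p_chain) = 0.1/0.75 for (0.1, 0.25)."""
        from mfge.ga import mutation_count
        rng = np.random.default_rng(1)
        n = 30_000
        draws = np.array([mutation_count(0.1, 0.25, rng) for _ in range(n)])
        expected = 0.1 / 0.75
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se + 1e-12

    def test_mutated_genes_follow_map(self):
        rng = np.random.default_rng(5)
        mult = np.array([1, 1, 1, 1, 30])
        fmap = weighted_map(mult)
        hits = np.zeros(6)
        for _ in range(3000):
            out = mutate(chrom([1]), fmap, 1.0, 0.0, rng, empty_prob=0.0)
            new = out.decode() - {1}
            for code in new:
                hits[code] += 1
        assert hits[5] > hits[2] * 5

    def test_validity_fuzz(self):
        """Random operator chains keep chromosomes valid."""
        rng = np.random.default_rng(9)
        fmap = uniform_map(30)
        pop = [init_chromosome(fmap, 15, 0.4, rng) for _ in range(20)]
        for _ in range(300):
            i, j = rng.integers(len(pop), size=2)
            a, b = crossover(pop[i], pop[j], 0.7, rng)
            a = mutate(a, fmap, 0.3, 0.25, rng)
            b = mutate(b, fmap, 0.3, 0.25, rng)
            for c in (a, b):
                assert c.is_valid(15)
            pop[int(i)] = a
            pop[int(j)] = b


class TestSelectionMigration:
    def test_tournament_tie_prefers_smaller_subset(self):
        rng = np.random.default_rng(0)
        pop = [chrom([1, 2, 3], fitness=fv(0.5)),
               chrom([4], fitness=fv(0.5)),
               chrom([5, 6], fitness=fv(0.5))]
        # a large draw contains every candidate a.s.; equal fitness means
        # the smallest subset must win
        winners = {tournament_select(pop, 50, rng).decode() for _ in range(20)}
        assert winners == {frozenset({4})}

    def test_dominant_chromosome_usually_selected(self):
        rng = np.random.default_rng(1)
        pop = [chrom([i + 1], fitness=fv(0.1)) for i in range(10)]
        pop[3].fitness = fv(0.9)
        picks = sum(tournament_select(pop, 3, rng).decode() == frozenset({4})
                    for _ in range(2000))
        expect = 1 - (1 - 1 / 10) ** 3  # P(dominant in a 3-draw) = 0.271
        assert abs(picks / 2000 - expect) < 0.04

    def test_size_one_uniform(self):
        rng = np.random.default_rng(2)
        pop = [chrom([i + 1], fitness=fv(0.1 * i)) for i in range(5)]
        picks = {next(iter(tournament_select(pop, 1, rng).decode()))
                 for _ in range(200)}
        assert picks == {1, 2, 3, 4, 5}

    def test_migration_moves_best(self):
        a = [chrom([1], fitness=fv(0.9)), chrom([2], fitness=fv(0.2))]
        b = [chrom([3], fitness=fv(0.3)), chrom([4], fitness=fv(0.1))]
        out = migrate([a, b], count=1)
        assert len(out[0]) == 2 and len(out[1]) == 2
        assert any(c.decode() == frozenset({1}) for c in out[1])
        assert any(c.decode() == frozenset({3}) for c in out[0])


class TestSimilarity:
    def test_identical_population(self):
        pop = [chrom([1, 2]) for _ in range(5)]
        assert population_similarity(pop) == 1.0

    def test_disjoint_pair(self):
        assert population_similarity([chrom([1, 2]), chrom([3, 4])]) == 0.0

    def test_hand_jaccard(self):
        assert population_similarity(
            [chrom([1, 2]), chrom([2, 3])]
        ) == pytest.approx(1 / 3)

    def test_all_empty_is_one(self):
        assert population_similarity([chrom([]), chrom([])]) == 1.0


def _subset_reward_fitness(good=frozenset({1, 2})):
    """Deterministic toy fitness: fraction of the good pair present, with
    a mild size penalty so smaller supersets win ties."""
    def fn(subset):
        base = len(subset & good) / len(good)
        pen = 0.01 * len(subset - good)
        val = max(0.0, base - pen)
        return FitnessValue(val, val, val)
    return fn


class TestEvolutionLoops:
    def test_similarity_zero_terminates_immediately(self):
        cfg = GAConfig(iterations=1, population_size=10, niches=2,
                       similarity_threshold=0.0, max_generations=50, seed=0)
        rng = np.random.default_rng(0)
        _best, gen = run_iteration(_subset_reward_fitness(), uniform_map(20), cfg, rng)
        assert gen == 1

    def test_finds_planted_pair(self):
        cfg = GAConfig(iterations=1, population_size=20, niches=2,
                       max_generations=40, seed=0)
        fmap = weighted_map([10, 10] + [1] * 18)
        rng = np.random.default_rng(1)
        best, gen = run_iteration(_subset_reward_fitness(), fmap, cfg, rng)
        assert best.fitness.combined >= 0.9
        assert gen <= 40

    def test_elitism_monotone_best(self):
        """Best-ever fitness is non-decreasing: re-run and compare the
        reported best against a fresh evaluation of its subset."""
        cfg = GAConfig(iterations=1, population_size=10, niches=2,
                       max_generations=15, seed=3)
        fn = _subset_reward_fitness()
        rng = np.random.default_rng(3)
        best, _ = run_iteration(fn, uniform_map(10), cfg, rng)
        assert best.fitness.combined == pytest.approx(fn(best.decode()).combined)

    def test_run_ge_reproducible(self):
        cfg = GAConfig(iterations=4, population_size=10, niches=2,
                       max_generations=8, seed=17)
        fn = _subset_reward_fitness()
        c1 = run_ge(fn, uniform_map(15), cfg)
        c2 = run_ge(fn, uniform_map(15), cfg)
        assert [r.genes for r in c1.records] == [r.genes for r in c2.records]
        assert [r.termination_generation for r in c1.records] == \
               [r.termination_generation for r in c2.records]

    def test_run_ge_collects_per_iteration(self):
        cfg = GAConfig(iterations=5, population_size=10, niches=2,
                       max_generations=5, seed=2)
        coll = run_ge(_subset_reward_fitness(), uniform_map(15), cfg)
        assert len(coll) == 5
        for rec in coll.records:
            assert rec.termination_generation <= 5
            assert 0 < rec.size <= 15
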