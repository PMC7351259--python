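import numpy as np
import pytest

from snpbarcode.core import Barcode, fitness
from snpbarcode.evolve import (
    EvolutionConfig,
    mutate,
    replace,
    run_ga,
    run_htga,
    tournament_select,
    uniform_crossover,
)


class FixedBits:
    """Stub rng: returns scripted crossover bits, then defers to a real rng."""

    def __init__(self, bits):
        self.bits = np.asarray(bits)
        self.rng = np.random.default_rng(0)

    def integers(self, *args, **kwargs):
        if kwargs.get("size") == len(self.bits):
            return self.bits
        return self.rng.integers(*args, **kwargs)


class TestTournamentSelect:
    def test_higher_fitness_wins(self):
        pop = [Barcode((1,), (1,)), Barcode((2,), (2,))]
        rng = np.random.default_rng(0)
        # over many draws, the fitter chromosome must always be returned
        winners = {tournament_select(pop, [10, 3], rng) for _ in range(50)}
        assert winners <= {pop[0], pop[1]}
        assert pop[0] in winners

    def test_tie_goes_to_first_drawn(self):
        a, b = Barcode((1,), (1,)), Barcode((2,), (2,))

        class TwoDraws:
            def __init__(self):
                self.calls = 0

            def integers(self, *_args, **_kw):
                self.calls += 1
                return 1 if self.calls == 1 else 0

        assert tournament_select([a, b], [5, 5], TwoDraws()) is b

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select([], [], np.random.default_rng(0))

    def test_population_of_one(self):
        only = Barcode((3,), (2,))
        assert tournament_select([only], [0], np.random.default_rng(0)) is only


class TestUniformCrossover:
    def test_identical_parents_unchanged(self):
        p = Barcode((1, 5), (2, 3))
        c1, c2 = uniform_crossover(p, p, np.random.default_rng(0), 26)
        assert c1 == p and c2 == p

    def test_all_zero_bits_is_identity(self):
        p1 = Barcode((1, 8), (1, 3))
        p2 = Barcode((10, 17), (2, 1))
        c1, c2 = uniform_crossover(p1, p2, FixedBits([0, 0]), 26)
        assert (c1, c2) == (p1, p2)

    def test_paired_swap_of_first_slot(self):
        p1 = Barcode((1, 8), (1, 3))
        p2 = Barcode((10, 17), (2, 1))
        c1, c2 = uniform_crossover(p1, p2, FixedBits([1, 0]), 26)
        assert c1 == Barcode((10, 8), (2, 3))
        assert c2 == Barcode((1, 17), (1, 1))

    def test_unequal_order_rejected(self):
        with pytest.raises(ValueError):
            uniform_crossover(
                Barcode((1,), (1,)), Barcode((1, 2), (1, 2)),
                np.random.default_rng(0), 26,
            )

    def test_offspring_always_valid_when_parents_overlap(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            snps1 = tuple(rng.choice(8, size=3, replace=False) + 1)
            snps2 = tuple(rng.choice(8, size=3, replace=False) + 1)
            p1 = Barcode(snps1, tuple(rng.integers(1, 4, size=3)))
            p2 = Barcode(snps2, tuple(rng.integers(1, 4, size=3)))
            for child in uniform_crossover(p1, p2, rng, 8):
                assert len(set(child.snp_indices)) == 3


class TestMutate:
    def test_zero_rate_is_identity(self):
        b = Barcode((1, 2, 3), (1, 2, 3))
        assert mutate(b, 0.0, 26, np.random.default_rng(0)) == b

    def test_full_order_barcode_keeps_snp_permutation(self):
        b = Barcode((1, 2, 3, 4, 5), (1, 1, 1, 1, 1))
        out = mutate(b, 1.0, 5, np.random.default_rng(0))
        assert sorted(out.snp_indices) == [1, 2, 3, 4, 5]

    def test_element_mutation_rate_matches_probability(self):
        rng = np.random.default_rng(9)
        b = Barcode((1, 2, 3, 4), (1, 1, 1, 1))
        p_m = 0.05
        n_elements = 8
        trials = 10_000
        mutated = 0
        for _ in range(trials):
            out = mutate(b, p_m, 26, rng)
            mutated += sum(x != y for x, y in zip(out.snp_indices, b.snp_indices))
            # genotype redraw keeps the old value 1/3 of the time
            mutated += sum(
                x != y for x, y in zip(out.genotype_codes, b.genotype_codes)
            ) * 3 / 2
        rate = mutated / (trials * n_elements)
        assert abs(rate - p_m) < 0.005  # well inside a binomial 99% band


class TestReplace:
    def _pop(self, rows):
        return (
            [Barcode((s,), (g,)) for s, g, _ in rows],
            [f for *_, f in rows],
        )

    def test_worse_offspring_leave_population_unchanged(self):
        parents, pf = self._pop([(1, 1, 10), (2, 1, 8)])
        off, of = self._pop([(3, 1, 1), (4, 1, 0)])
        pop, fit = replace(parents, pf, off, of, 2)
        assert pop == parents and fit == pf

    def test_better_offspring_evicts_worst_parent(self):
        parents, pf = self._pop([(1, 1, 10), (2, 1, 2)])
        off, of = self._pop([(3, 1, 5)])
        pop, fit = replace(parents, pf, off, of, 2)
        assert fit == [10, 5]

    def test_duplicates_do_not_crowd_out_distinct_members(self):
        best = Barcode((1,), (1,))
        parents = [best, best, best]
        off = [Barcode((2,), (1,))]
        pop, fit = replace(parents, [9, 9, 9], off, [1], 3)
        assert off[0] in pop

    def test_best_fitness_never_decreases(self):
        rng = np.random.default_rng(14)
        parents = [Barcode((int(s),), (int(g),)) for s, g in
                   zip(rng.choice(26, 10, replace=False) + 1, rng.integers(1, 4, 10))]
        pf = list(rng.integers(-50, 51, 10))
        best = max(pf)
        for _ in range(20):
            off = [Barcode((int(rng.integers(1, 27)),), (int(rng.integers(1, 4)),))]
            of = [int(rng.integers(-50, 51))]
            parents, pf = replace(parents, pf, off, of, 10)
            assert pf[0] >= best
            best = pf[0]


class TestRuns:
    def test_invalid_config_rejected_before_evaluation(self):
        with pytest.raises(ValueError):
            EvolutionConfig(population_size=1)
        with pytest.raises(ValueError):
            EvolutionConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            EvolutionConfig(algorithm="annealing")

    def test_zero_iterations_returns_best_of_initial_population(self, small_cohort):
        config = EvolutionConfig(max_iterations=0, seed=5)
        result = run_htga(config, small_cohort)
        assert len(result.history) == 1
        assert result.best_fitness == result.history[0]
        assert result.evaluations == config.population_size

    def test_ga_and_htga_agree_at_zero_iterations(self, small_cohort):
        h = run_htga(EvolutionConfig(max_iterations=0, seed=5), small_cohort)
        g = run_ga(
            EvolutionConfig(max_iterations=0, seed=5, algorithm="ga"), small_cohort
        )
        assert h.best_barcode == g.best_barcode
        assert h.best_fitness == g.best_fitness

    def test_same_seed_same_result(self, small_cohort):
        config = EvolutionConfig(max_iterations=20, seed=7)
        a = run_htga(config, small_cohort)
        b = run_htga(config, small_cohort)
        assert a.best_barcode == b.best_barcode
        assert a.history == b.history
        assert a.evaluations == b.evaluations

    def test_history_non_decreasing_and_final_matches_best(self, small_cohort):
        result = run_htga(EvolutionConfig(max_iterations=30, seed=3), small_cohort)
        assert all(a <= b for a, b in zip(result.history, result.history[1:]))
        assert result.history[-1] == result.best_fitness
        assert result.best_fitness == fitness(small_cohort, result.best_barcode)

    def test_static_run_without_crossover_or_mutation(self, small_cohort):
        config = EvolutionConfig(
            max_iterations=10, crossover_rate=0.0, mutation_rate=0.0, seed=2
        )
        result = run_htga(config, small_cohort)
        zero_iter = run_htga(
            EvolutionConfig(max_iterations=0, crossover_rate=0.0,
                            mutation_rate=0.0, seed=2),
            small_cohort,
        )
        assert result.best_fitness == zero_iter.best_fitness

    def test_evaluation_budget_bookkeeping(self, small_cohort):
        """GA without the Taguchi step: M initial + M offspring per iteration."""
        M, T = 10, 5
        config = EvolutionConfig(
            population_size=M, max_iterations=T, algorithm="ga", seed=1
        )
        result = run_ga(config, small_cohort)
        assert result.evaluations == M + T * M

    def test_htga_evaluation_budget(self, small_cohort):
        """HTGA adds round(0.5*M*p_c) combines, each n_runs+1 evaluations."""
        M, T, p_c, m = 10, 4, 0.4, 2
        config = EvolutionConfig(
            population_size=M, max_iterations=T, crossover_rate=p_c,
            barcode_order=m, seed=1,
        )
        result = run_htga(config, small_cohort)
        combines = round(0.5 * M * p_c)
        per_iter = M + combines * (4 + 1 + 1)  # L4 runs + predicted + pool re-eval
        assert result.evaluations == M + T * per_iter

    def test_population_members_stay_valid(self, small_cohort):
        result = run_htga(
            EvolutionConfig(max_iterations=20, barcode_order=4, seed=6), small_cohort
        )
        b = result.best_barcode
        assert len(set(b.snp_indices)) == 4
        assert all(1 <= s <= small_cohort.n_snps for s in b.snp_indices)
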