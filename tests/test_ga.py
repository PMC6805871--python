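"""GA operators and the calibration loop (deterministic mock backends)."""

import numpy as np
import pytest
from scipy import stats

from kinecal.data import ObjectiveSpec
from kinecal.ga import (
    GAConfig,
    Individual,
    calibrate,
    crossover,
    fractional_error,
    initialize_population,
    inverse_rank_probabilities,
    mutate,
    ParameterSpec,
    percent_errors,
    rank_population,
    select_parents,
)


from _mocks import ConstantCurveBackend, make_dataset

SPECS4 = tuple(ParameterSpec(f"p{i}", 1e-2, 1e2, "log_uniform") for i in range(4))


class TestInitialization:
    def test_log_uniform_draws_match_analytic_cdf(self):
        pop = initialize_population(
            (ParameterSpec("k", 1e-2, 1e2, "log_uniform"),), 10_000, rng=5)
        draws = np.array([ind.params[0] for ind in pop])
        assert draws.min() >= 1e-2 and draws.max() <= 1e2
        stat = stats.kstest(np.log10(draws), stats.uniform(loc=-2, scale=4).cdf)
        assert stat.pvalue > 0.01

    def test_same_seed_identical_population(self):
        a = initialize_population(SPECS4, 50, rng=9)
        b = initialize_population(SPECS4, 50, rng=9)
        np.testing.assert_array_equal(
            np.array([i.params for i in a]), np.array([i.params for i in b]))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            initialize_population(SPECS4, 0, rng=0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpec("k", 2.0, 1.0)
        with pytest.raises(ValueError):
            ParameterSpec("k", -1.0, 1.0, "log_uniform")


class TestInverseRankSelection:
    def test_single_individual_gets_probability_one(self):
        np.testing.assert_allclose(inverse_rank_probabilities(1), [1.0])

    def test_two_individuals(self):
        np.testing.assert_allclose(inverse_rank_probabilities(2), [2 / 3, 1 / 3])

    def test_population_of_100_printed_probabilities(self):
        p = inverse_rank_probabilities(100)
        assert round(100 * p[0], 2) == 19.28
        assert round(100 * p[1], 2) == 9.64
        assert p.sum() == pytest.approx(1.0, rel=1e-12)

    def test_strategy1_elite_of_one_forces_self_recombination(self):
        pop = [Individual(id=i, params=np.zeros(1)) for i in range(5)]
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = select_parents(pop, strategy=1, elite_size=1, rng=rng)
            assert a.id == 0 and b.id == 0

    def test_strategy1_uniform_elite_frequencies(self):
        pop = [Individual(id=i, params=np.zeros(1)) for i in range(100)]
        rng = np.random.default_rng(1)
        draws = 50_000
        counts = np.zeros(100)
        for _ in range(draws):
            a, b = select_parents(pop, strategy=1, elite_size=10, rng=rng)
            counts[a.id] += 1
            counts[b.id] += 1
        freqs = counts / (2 * draws)
        se = np.sqrt(0.1 * 0.9 / (2 * draws))
        assert (np.abs(freqs[:10] - 0.1) < 3 * se).all()
        assert freqs[10:].sum() == 0

    def test_strategy2_first_rank_frequency(self):
        pop = [Individual(id=i, params=np.zeros(1)) for i in range(100)]
        rng = np.random.default_rng(2)
        draws = 50_000
        hits = 0
        for _ in range(draws):
            a, b = select_parents(pop, strategy=2, elite_size=10, rng=rng)
            assert a.id != b.id
            hits += (a.id == 0) + (b.id == 0)
        freq = hits / (2 * draws)
        # sampling without replacement slightly inflates the marginal; allow
        # 3 SE around the single-draw probability plus that inflation
        p1 = 0.1928
        se = np.sqrt(p1 * (1 - p1) / (2 * draws))
        assert abs(freq - p1) < 3 * se + 0.02

    def test_strategy2_needs_two_individuals(self):
        with pytest.raises(ValueError):
            select_parents([Individual(id=0, params=np.zeros(1))], 2, 1,
                           np.random.default_rng(0))


class TestCrossoverMutation:
    def test_single_point_children_are_prefix_suffix_combinations(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([10.0, 20, 30, 40])
        rng = np.random.default_rng(3)
        valid = {tuple(np.concatenate([a[:k], b[k:]])) for k in range(1, 4)}
        for _ in range(20):
            child = crossover(a, b, "single_point", rng)
            assert tuple(child) in valid

    def test_identical_parents_any_mode_identity(self):
        a = np.array([1.0, 2.0, 3.0])
        rng = np.random.default_rng(4)
        for mode in ("single_point", "multi_point"):
            np.testing.assert_array_equal(crossover(a, a.copy(), mode, rng), a)

    def test_multi_point_gene_frequency_is_half(self):
        a, b = np.zeros(10), np.ones(10)
        rng = np.random.default_rng(5)
        children = np.array([crossover(a, b, "multi_point", rng) for _ in range(10_000)])
        freq_a = 1 - children.mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert (np.abs(freq_a - 0.5) < 3 * se).all()

    def test_single_parameter_single_point_degenerates_to_coin_flip(self):
        rng = np.random.default_rng(6)
        picks = {crossover(np.array([1.0]), np.array([2.0]), "single_point", rng)[0]
                 for _ in range(50)}
        assert picks == {1.0, 2.0}

    def test_zero_probability_mutation_is_identity(self):
        v = np.array([1.0, 0.5, 2.0, 0.1])
        out = mutate(v, SPECS4, "redraw", 0.0, np.random.default_rng(7))
        np.testing.assert_array_equal(out, v)

    def test_factor_mutation_stays_within_ten_percent_and_bounds(self):
        rng = np.random.default_rng(8)
        v = np.full(4, 1.0)
        for _ in range(200):
            out = mutate(v, SPECS4, "factor", 1.0, rng, halfwidth=0.10)
            ratio = out / v
            assert (ratio >= 0.9 - 1e-12).all() and (ratio <= 1.1 + 1e-12).all()
        near_edge = np.full(4, 99.0)
        for _ in range(100):
            out = mutate(near_edge, SPECS4, "factor", 1.0, rng)
            assert (out <= 100.0).all()

    def test_full_redraw_matches_initialisation_distribution(self):
        spec = (ParameterSpec("k", 1e-2, 1e2, "log_uniform"),)
        rng = np.random.default_rng(9)
        mutants = np.array([mutate(np.array([1.0]), spec, "redraw", 1.0, rng)[0]
                            for _ in range(10_000)])
        stat = stats.kstest(np.log10(mutants), stats.uniform(loc=-2, scale=4).cdf)
        assert stat.pvalue > 0.01


class TestRanking:
    def _pop(self, fitnesses):
        pop = []
        for i, f in enumerate(fitnesses):
            ind = Individual(id=i, params=np.zeros(1))
            ind.fitness.values = {"SDA": f}
            pop.append(ind)
        return pop

    def test_strict_sort_ascending(self):
        ranked = rank_population(self._pop([3.0, 1.0, 2.0]), ["SDA"])
        assert [i.id for i in ranked] == [1, 2, 0]

    def test_ties_break_by_lower_id(self):
        ranked = rank_population(self._pop([2.0, 1.0, 1.0]), ["SDA"])
        assert [i.id for i in ranked] == [1, 2, 0]

    def test_failed_simulation_sentinels_rank_last(self):
        ranked = rank_population(self._pop([np.inf, 1.0, np.inf, 0.5]), ["SDA"])
        assert [i.id for i in ranked] == [3, 1, 0, 2]


def _quadratic_config(**overrides):
    defaults = dict(
        specs=SPECS4[:2],
        objectives=(ObjectiveSpec("SDA"),),
        population_size=12, elite_size=3, iterations=8, n_sims=2,
        strategy=1, seed=11,
    )
    defaults.update(overrides)
    return GAConfig(**defaults)


class TestCalibrationLoop:
    def test_elitism_makes_best_fitness_non_increasing(self):
        data = make_dataset([5.0, 0.5])
        res = calibrate(_quadratic_config(), ConstantCurveBackend(), data)
        best = res.best_per_iteration["SDA"].to_numpy()
        assert (np.diff(best) <= 0).all()

    def test_population_size_conserved_every_iteration(self):
        data = make_dataset([5.0, 0.5])
        res = calibrate(_quadratic_config(), ConstantCurveBackend(), data)
        counts = res.history.groupby("iteration")["id"].count()
        assert (counts == 12).all()

    def test_bounds_respected_after_every_operator(self):
        data = make_dataset([5.0, 0.5])
        res = calibrate(_quadratic_config(iterations=12), ConstantCurveBackend(), data)
        for name, spec in zip(("p0", "p1"), SPECS4[:2]):
            col = res.history[name]
            assert (col >= spec.lower).all() and (col <= spec.upper).all()

    def test_identical_seeds_bit_identical_results(self):
        data = make_dataset([5.0, 0.5])
        a = calibrate(_quadratic_config(), ConstantCurveBackend(), data)
        b = calibrate(_quadratic_config(), ConstantCurveBackend(), data)
        assert a.history.equals(b.history)
        np.testing.assert_array_equal(a.best.params, b.best.params)

    def test_converges_toward_quadratic_optimum(self):
        data = make_dataset([5.0, 0.5])
        res = calibrate(_quadratic_config(iterations=25, population_size=20),
                        ConstantCurveBackend(), data)
        assert np.abs(np.log10(res.best.params / np.array([5.0, 0.5]))).max() < 0.5

    def test_failing_backend_yields_sentinel_and_run_continues(self):
        class FlakyBackend(ConstantCurveBackend):
            def simulate(self, assignment, n_sims, times, seed):
                if assignment["p0"] > 1.0:
                    raise RuntimeError("boom")
                return super().simulate(assignment, n_sims, times, seed)

        data = make_dataset([0.5, 0.5])
        res = calibrate(_quadratic_config(), FlakyBackend(), data)
        assert np.isinf(res.history["SDA"]).any()
        assert np.isfinite(res.best.fitness.values["SDA"])

    def test_all_failing_backend_aborts(self):
        class DeadBackend:
            def simulate(self, *a, **k):
                raise RuntimeError("dead")

        data = make_dataset([5.0, 0.5])
        with pytest.raises(RuntimeError, match="failed"):
            calibrate(_quadratic_config(), DeadBackend(), data)

    def test_moga_runs_and_ranks_by_sum_of_ranks(self):
        data = make_dataset([5.0, 0.5])
        cfg = _quadratic_config(objectives=(ObjectiveSpec("SDA"), ObjectiveSpec("ADA")))
        res = calibrate(cfg, ConstantCurveBackend(), data)
        assert {"SDA", "ADA"} <= set(res.history.columns)
        assert res.best.fitness.combined_rank is not None


class TestFractionalError:
    def test_first_entry_maps_to_one(self):
        np.testing.assert_allclose(fractional_error([4.0, 2.0, 1.0]), [1.0, 0.5, 0.25])

    def test_constant_series_all_ones(self):
        np.testing.assert_allclose(fractional_error([3.0, 3.0, 3.0]), [1.0, 1.0, 1.0])

    def test_zero_first_entry_is_an_error(self):
        with pytest.raises(ValueError):
            fractional_error([0.0, 1.0])

    def test_percent_errors_signed(self):
        np.testing.assert_allclose(
            percent_errors([6.0, 0.015], [5.0, 0.03]), [20.0, -50.0])
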