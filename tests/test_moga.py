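"""GA machinery: operators, non-dominated sorting (vs a brute-force oracle),
elitism, determinism and reporting.  Evaluation here uses cheap synthetic
objective functions — the expensive ionic-model evaluations are exercised in
the integration and acceptance suites."""

import numpy as np
import pytest

from cardiofit.ionic_model import ParameterVector
from cardiofit.moga import (GAConfig, Individual, crossover, crowding_distance,
                            init_population, mutate, nondominated_sort,
                            run_ga, run_with_restarts, select_best,
                            variability_report)
from cardiofit.objectives import ObjectiveValues

BOUNDS = {n: (0.0, 1.0) for n in ("a", "b", "c", "d")}


def _cfg(**kw):
    base = dict(population_size=20, max_generations=15, seed=7,
                fitted_parameters=tuple(BOUNDS), bounds=BOUNDS)
    base.update(kw)
    return GAConfig(**base)


def _sphere_evaluator(center=None):
    """f_ap = squared distance to the optimum, f_rm = L1 distance."""
    def ev(g):
        c = center if center is not None else np.full(len(g), 0.37)
        d = g - c
        return ObjectiveValues(float(d @ d), float(np.abs(d).sum()),
                               float(np.sqrt(d @ d)))
    return ev


def _inds(objs):
    out = []
    for fa, fr in objs:
        out.append(Individual(np.zeros(1),
                              ObjectiveValues(float(fa), float(fr), 0.0)))
    return out


def _brute_force_ranks(keys):
    """Peel non-dominated layers by direct definition."""
    remaining = set(range(len(keys)))
    ranks = {}
    r = 0
    while remaining:
        front = {i for i in remaining
                 if not any(all(keys[j][m] <= keys[i][m] for m in range(2))
                            and any(keys[j][m] < keys[i][m] for m in range(2))
                            for j in remaining if j != i)}
        for i in front:
            ranks[i] = r
        remaining -= front
        r += 1
    return [ranks[i] for i in range(len(keys))]


class TestNondominatedSort:
    def test_single_individual_is_rank_zero(self):
        pop = _inds([(1.0, 1.0)])
        fronts = nondominated_sort(pop)
        assert fronts == [[0]] and pop[0].rank == 0

    def test_hand_checked_dominance(self):
        pop = _inds([(1, 2), (2, 1), (3, 3)])
        nondominated_sort(pop)
        assert [i.rank for i in pop] == [0, 0, 1]

    @pytest.mark.parametrize("n", [20, 50, 200])
    def test_matches_brute_force_oracle(self, n, rng):
        objs = rng.integers(0, 12, size=(n, 2)).astype(float)  # ties included
        pop = _inds(objs)
        nondominated_sort(pop)
        assert [i.rank for i in pop] == _brute_force_ranks([tuple(o) for o in objs])

    def test_unevaluated_individual_rejected(self):
        with pytest.raises(ValueError):
            nondominated_sort([Individual(np.zeros(1))])

    def test_single_objective_mode_ranks_by_f_ap(self):
        pop = _inds([(3.0, 0.0), (1.0, 9.0), (2.0, 5.0)])
        nondominated_sort(pop, n_obj=1)
        assert [i.rank for i in pop] == [2, 0, 1]


class TestOperators:
    def test_crossover_rate_zero_copies_parents(self, rng):
        a, b = Individual(np.array([0.1, 0.9])), Individual(np.array([0.5, 0.2]))
        c1, c2 = crossover(a, b, 0.0, rng)
        assert np.array_equal(c1.genome, a.genome)
        assert np.array_equal(c2.genome, b.genome)

    def test_identical_parents_give_identical_children(self, rng):
        a = Individual(np.array([0.3, 0.3, 0.3]))
        c1, c2 = crossover(a, Individual(a.genome.copy()), 1.0, rng)
        assert np.allclose(c1.genome, a.genome)
        assert np.allclose(c2.genome, a.genome)

    def test_empirical_crossover_rate(self, rng):
        a, b = Individual(np.array([0.0])), Individual(np.array([1.0]))
        n, hits = 10_000, 0
        for _ in range(n):
            c1, _ = crossover(a, b, 0.8, rng)
            hits += c1.genome[0] != 0.0
        sd = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - 0.8) < 3 * sd

    def test_mutation_rate_zero_is_identity(self, rng):
        lo, hi = np.zeros(4), np.ones(4)
        g = Individual(np.full(4, 0.5))
        assert np.array_equal(mutate(g, 0.0, 0.05, lo, hi, rng).genome, g.genome)

    def test_mutation_respects_bounds(self, rng):
        lo, hi = np.zeros(4), np.ones(4)
        g = Individual(np.array([0.0, 1.0, 0.5, 0.999]))
        for _ in range(2000):
            out = mutate(g, 1.0, 0.5, lo, hi, rng).genome
            assert np.all(out >= lo) and np.all(out <= hi)

    def test_empirical_mutation_rate(self, rng):
        lo, hi = np.zeros(8), np.ones(8)
        g = Individual(np.full(8, 0.5))
        n = 10_000
        flips = sum(int(np.sum(mutate(g, 0.01, 0.05, lo, hi, rng).genome != 0.5))
                    for _ in range(n))
        total = n * 8
        sd = np.sqrt(0.01 * 0.99 * total)
        assert abs(flips - 0.01 * total) < 3 * sd


class TestInitPopulation:
    def test_deterministic_for_fixed_seed(self):
        cfg = _cfg()
        p1 = init_population(cfg, np.random.default_rng(5))
        p2 = init_population(cfg, np.random.default_rng(5))
        assert all(np.array_equal(a.genome, b.genome) for a, b in zip(p1, p2))

    def test_all_within_bounds_and_seed_included(self):
        cfg = _cfg()
        seed_ind = np.array([0.1, 0.2, 0.3, 0.4])
        pop = init_population(cfg, np.random.default_rng(0), seed_ind)
        assert np.array_equal(pop[0].genome, seed_ind)
        for ind in pop:
            assert np.all(ind.genome >= 0.0) and np.all(ind.genome <= 1.0)

    def test_empirical_mean_is_interval_midpoint(self):
        cfg = _cfg(population_size=10_000, bounds={"a": (2.0, 6.0)},
                   fitted_parameters=("a",))
        pop = init_population(cfg, np.random.default_rng(2))
        vals = np.array([i.genome[0] for i in pop])
        # mean of U(2,6) is 4, sd of the mean = width/sqrt(12 n)
        assert abs(vals.mean() - 4.0) < 3 * 4.0 / np.sqrt(12 * len(vals))

    def test_inverted_bounds_sorted_with_warning(self):
        cfg = _cfg(bounds={"a": (1.0, 0.0)}, fitted_parameters=("a",))
        with pytest.warns(UserWarning, match="sorting"):
            lo, hi = cfg.resolved_bounds()
        assert lo[0] == 0.0 and hi[0] == 1.0


class TestSelectBest:
    def test_minimizes_f_ap(self):
        front = _inds([(1.0, 5.0), (2.0, 1.0)])
        assert select_best(front) is front[0]

    def test_singleton(self):
        front = _inds([(4.0, 4.0)])
        assert select_best(front) is front[0]

    def test_tie_broken_by_f_rm(self):
        front = _inds([(1.0, 5.0), (1.0, 2.0)])
        assert select_best(front) is front[1]

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestRunGa:
    def test_same_seed_reproduces_result_exactly(self):
        cfg = _cfg()
        r1 = run_ga(None, cfg, evaluator=_sphere_evaluator())
        r2 = run_ga(None, cfg, evaluator=_sphere_evaluator())
        assert np.array_equal(r1.best.genome, r2.best.genome)
        assert r1.history.equals(r2.history)

    def test_elitism_makes_best_f_ap_non_increasing(self):
        r = run_ga(None, _cfg(max_generations=25), evaluator=_sphere_evaluator())
        best = r.history["best_f_ap"].to_numpy()
        assert np.all(np.diff(best) <= 1e-15)

    def test_every_survivor_within_bounds(self):
        r = run_ga(None, _cfg(), evaluator=_sphere_evaluator())
        for ind in r.population:
            assert np.all(ind.genome >= 0.0) and np.all(ind.genome <= 1.0)

    def test_converges_toward_optimum(self):
        r = run_ga(None, _cfg(max_generations=40, population_size=30),
                   evaluator=_sphere_evaluator())
        assert r.best.objectives.f_ap < 1e-3

    def test_selected_best_lies_on_first_front(self):
        r = run_ga(None, _cfg(), evaluator=_sphere_evaluator())
        assert r.best.rank == 0
        assert r.best in r.front

    def test_all_penalized_initial_population_aborts(self):
        def bad(_):
            return ObjectiveValues(1e6, 1e6, 1e6, penalized=True)
        with pytest.raises(RuntimeError, match="initial population"):
            run_ga(None, _cfg(), evaluator=bad)


class TestRestarts:
    def test_single_restart_equals_plain_run(self):
        cfg = _cfg()
        plain = run_ga(None, cfg, evaluator=_sphere_evaluator())
        chained = run_with_restarts(None, cfg, n_restarts=1,
                                    evaluator=_sphere_evaluator())
        assert np.array_equal(plain.best.genome, chained.best.genome)

    def test_chained_best_never_worse_than_first_run(self):
        cfg = _cfg(max_generations=8)
        res = run_with_restarts(None, cfg, n_restarts=3,
                                evaluator=_sphere_evaluator())
        assert (res.best.objectives.f_ap
                <= res.per_run_best[0].objectives.f_ap + 1e-15)


class TestVariabilityReport:
    def _result(self, genome, cfg):
        ind = Individual(np.asarray(genome, float),
                         ObjectiveValues(0.0, 0.0, 0.0))
        import pandas as pd
        from cardiofit.moga import ParetoResult
        return ParetoResult([ind], [ind], ind, pd.DataFrame(), cfg, 1, 1, 0.0)

    def test_identical_runs_have_zero_sd(self, control):
        cfg = GAConfig(population_size=4, fitted_parameters=("g_Na", "g_Ks"),
                       bounds={"g_Na": (5, 20), "g_Ks": (0.02, 0.6)})
        runs = [self._result([10.0, 0.1], cfg) for _ in range(3)]
        rep = variability_report(runs, control)
        assert np.allclose(rep["sd"], 0.0)

    def test_control_values_normalize_to_one(self, control):
        cfg = GAConfig(population_size=4, fitted_parameters=("g_Na",),
                       bounds={"g_Na": (5, 20)})
        runs = [self._result([control.g_Na], cfg) for _ in range(2)]
        assert variability_report(runs, control)["mean"].iloc[0] == pytest.approx(1.0)

    def test_fewer_than_two_runs_rejected(self, control):
        cfg = GAConfig(population_size=4, fitted_parameters=("g_Na",),
                       bounds={"g_Na": (5, 20)})
        with pytest.raises(ValueError):
            variability_report([self._result([10.0], cfg)], control)
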