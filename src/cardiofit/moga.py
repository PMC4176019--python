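"""Elitist multi-objective genetic algorithm (NSGA-II-style) for conductance fitting.

The population lives in the space of the fitted parameter subset, each gene
bounded by its physiological range.  Variation operators:

* crossover (rate 0.8): per-parameter arithmetic blend ``alpha*a + (1-alpha)*b``
  with alpha ~ U(-spread, 1+spread) drawn per parameter and clipped to bounds
  (extending the blend beyond the parents keeps the population from collapsing
  prematurely on correlated-parameter ridges);
* mutation (rate 0.01 per gene): additive zero-mean Gaussian, sigma annealed
  geometrically from 5% to 0.1% of the bound width over the run, clipped back
  into bounds.

Survivor selection is elitist: parents and children are pooled, ranked by
non-domination (Deb's fast non-dominated sort) and crowding distance, and the
best N survive.  Termination on a generation cap or wall-time limit,
whichever comes first.  Everything is driven by one seeded generator, so a
run is fully reproducible from (seed, config, target).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ionic_model import ParameterVector
from .objectives import (EvalConfig, ObjectiveValues, TargetDataset,
                         evaluate_individual)

__all__ = [
    "Individual", "GAConfig", "ParetoResult", "RestartResult",
    "init_population", "nondominated_sort", "crowding_distance",
    "crossover", "mutate", "run_ga", "run_with_restarts", "select_best",
    "variability_report", "DEFAULT_FITTED_PARAMETERS",
]

#: the eight bounded parameters fitted by default (the bounds table's usable rows)
DEFAULT_FITTED_PARAMETERS = (
    "g_Na", "g_to", "g_Ks", "g_K1", "g_Kr", "g_CaL", "a_rel", "c_rel",
)


@dataclass
class Individual:
    """One candidate solution: genome over the fitted subset + scores."""

    genome: np.ndarray
    objectives: ObjectiveValues | None = None
    rank: int | None = None
    crowding: float = 0.0

    def key(self, n_obj: int) -> tuple:
        o = self.objectives
        if o is None:
            raise ValueError("individual not evaluated")
        return (o.f_ap,) if n_obj == 1 else (o.f_ap, o.f_rm)


def _default_bounds() -> dict[str, tuple[float, float]]:
    from .fixtures import search_bounds
    return search_bounds()


@dataclass
class GAConfig:
    """GA hyper-parameters; defaults follow the published protocol."""

    population_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    mutation_sigma: float = 0.05       # fraction of each bound's width (initial)
    mutation_sigma_final: float = 0.001  # sigma annealed here by the last generation
    crossover_spread: float = 0.5      # blend extension beyond the parents (BLX)
    max_generations: int = 100
    max_wall_time_s: float = 86400.0
    seed: int = 0
    objectives: str = "ap+rm"          # "ap" | "ap+rm"
    fitted_parameters: tuple = DEFAULT_FITTED_PARAMETERS
    bounds: Mapping[str, tuple[float, float]] | None = None
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        if self.objectives not in ("ap", "ap+rm"):
            raise ValueError(f"unknown objectives mode {self.objectives!r}")

    @property
    def n_objectives(self) -> int:
        return 1 if self.objectives == "ap" else 2

    def sigma_at(self, generation: int) -> float:
        """Geometrically annealed mutation sigma (coarse early, fine late)."""
        if self.mutation_sigma_final is None or self.max_generations <= 1:
            return self.mutation_sigma
        frac = (generation - 1) / (self.max_generations - 1)
        ratio = self.mutation_sigma_final / self.mutation_sigma
        return self.mutation_sigma * ratio ** min(max(frac, 0.0), 1.0)

    def resolved_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) arrays over the fitted subset, sanitized (lo < hi)."""
        table = dict(self.bounds) if self.bounds is not None else _default_bounds()
        lo, hi = [], []
        for name in self.fitted_parameters:
            if name not in table:
                raise KeyError(f"no bounds configured for parameter {name!r}")
            a, b = table[name]
            if a > b:
                warnings.warn(f"bounds for {name} given as (min>max); sorting")
                a, b = b, a
            if a == b:
                warnings.warn(f"degenerate bounds for {name}; parameter frozen")
            lo.append(a)
            hi.append(b)
        return np.asarray(lo, float), np.asarray(hi, float)


def init_population(config: GAConfig, rng: np.random.Generator,
                    seed_individual: np.ndarray | None = None,
                    seed_spread: float | None = None) -> list[Individual]:
    """Random genomes within bounds, uniform by default.

    With a ``seed_individual`` (restart chaining) the seed is included
    verbatim; when ``seed_spread`` is given the remaining individuals are
    drawn as Gaussian perturbations of the seed (sigma = seed_spread * bound
    width, clipped) — the previous best serves as the initial parameter
    values of the new run — otherwise they are uniform over the full range.
    """
    lo, hi = config.resolved_bounds()
    pop = []
    if seed_individual is not None:
        g = np.clip(np.asarray(seed_individual, float), lo, hi)
        pop.append(Individual(g))
    while len(pop) < config.population_size:
        if seed_individual is not None and seed_spread is not None:
            g = np.clip(pop[0].genome
                        + rng.normal(0.0, seed_spread * (hi - lo)), lo, hi)
            pop.append(Individual(g))
        else:
            pop.append(Individual(rng.uniform(lo, hi)))
    return pop


def _dominates(a: tuple, b: tuple) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def nondominated_sort(population: Sequence[Individual],
                      n_obj: int = 2) -> list[list[int]]:
    """Deb's fast non-dominated sort; assigns ranks, returns front index lists."""
    keys = [ind.key(n_obj) for ind in population]
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(keys[i], keys[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(keys[j], keys[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = [[i for i in range(n) if dom_count[i] == 0]]
    for i in fronts[0]:
        population[i].rank = 0
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    population[j].rank = len(fronts)
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(population: Sequence[Individual], front: Sequence[int],
                      n_obj: int = 2) -> None:
    """Assign NSGA-II crowding distances to the members of one front."""
    for i in front:
        population[i].crowding = 0.0
    for m in range(n_obj):
        vals = sorted(front, key=lambda i: population[i].key(n_obj)[m])
        vmin = population[vals[0]].key(n_obj)[m]
        vmax = population[vals[-1]].key(n_obj)[m]
        population[vals[0]].crowding = np.inf
        population[vals[-1]].crowding = np.inf
        if vmax == vmin:
            continue
        for a, b, c in zip(vals[:-2], vals[1:-1], vals[2:]):
            population[b].crowding += (
                population[c].key(n_obj)[m] - population[a].key(n_obj)[m]
            ) / (vmax - vmin)


def crossover(parent_a: Individual, parent_b: Individual, rate: float,
              rng: np.random.Generator, spread: float = 0.0,
              lo: np.ndarray | None = None,
              hi: np.ndarray | None = None) -> tuple[Individual, Individual]:
    """Arithmetic-blend crossover with per-parameter mixing coefficients.

    ``spread`` > 0 extends the blend beyond the parents (alpha drawn from
    U(-spread, 1+spread), BLX-style, clipped to bounds): a purely
    interpolating blend shrinks the population hull every generation and
    stalls on correlated-parameter ridges.
    """
    a, b = parent_a.genome, parent_b.genome
    if rng.random() < rate:
        alpha = rng.uniform(-spread, 1.0 + spread, size=a.shape)
        c1 = alpha * a + (1.0 - alpha) * b
        c2 = alpha * b + (1.0 - alpha) * a
        if spread > 0.0 and lo is not None:
            c1 = np.clip(c1, lo, hi)
            c2 = np.clip(c2, lo, hi)
    else:
        c1, c2 = a.copy(), b.copy()
    return Individual(c1), Individual(c2)


def mutate(ind: Individual, rate: float, sigma_frac: float,
           lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator) -> Individual:
    """Per-gene Gaussian perturbation (sigma = sigma_frac * width), clipped."""
    g = ind.genome.copy()
    mask = rng.random(g.shape) < rate
    if mask.any():
        g[mask] += rng.normal(0.0, sigma_frac * (hi - lo)[mask])
        g = np.clip(g, lo, hi)
    return Individual(g)


def _tournament(population: list[Individual], rng: np.random.Generator) -> Individual:
    i, j = rng.integers(len(population)), rng.integers(len(population))
    a, b = population[i], population[j]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    return a if a.crowding >= b.crowding else b


@dataclass
class ParetoResult:
    """Final population, first front, selected best and run history."""

    population: list[Individual]
    front: list[Individual]
    best: Individual
    history: pd.DataFrame
    config: GAConfig
    generations_run: int
    evaluations: int
    wall_time_s: float

    def best_parameters(self, control: ParameterVector | None = None) -> ParameterVector:
        control = control or ParameterVector.control()
        return control.with_subset(self.config.fitted_parameters, self.best.genome)


def select_best(front: Sequence[Individual]) -> Individual:
    """Least AP error on the first front; ties broken by f_rm then by index."""
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    def k(item):
        idx, ind = item
        o = ind.objectives
        frm = o.f_rm if np.isfinite(o.f_rm) else np.inf
        return (o.f_ap, frm, idx)
    return min(enumerate(front), key=k)[1]


Evaluator = Callable[[np.ndarray], ObjectiveValues]


def _make_evaluator(target: TargetDataset, config: GAConfig,
                    eval_config: EvalConfig | None,
                    control: ParameterVector) -> Evaluator:
    ec = eval_config or EvalConfig()
    ec = replace(ec, objectives=config.objectives) if ec.objectives != config.objectives else ec

    def ev(genome: np.ndarray) -> ObjectiveValues:
        p = control.with_subset(config.fitted_parameters, genome)
        return evaluate_individual(p, target, ec)

    return ev


def _evaluate_all(pop: list[Individual], evaluator: Evaluator, map_fn) -> int:
    todo = [ind for ind in pop if ind.objectives is None]
    # results gathered in submission order: concurrency never changes output
    for ind, obj in zip(todo, map_fn(evaluator, [i.genome for i in todo])):
        ind.objectives = obj
    return len(todo)


def run_ga(target: TargetDataset, config: GAConfig,
           eval_config: EvalConfig | None = None,
           evaluator: Evaluator | None = None,
           map_fn: Callable = None,
           control: ParameterVector | None = None,
           seed_individual: np.ndarray | None = None,
           seed_spread: float | None = None,
           rng: np.random.Generator | None = None) -> ParetoResult:
    """One elitist GA run.

    ``evaluator`` may be injected (testing, model-to-model experiments);
    by default individuals are scored with :func:`evaluate_individual` on the
    TNNP model.  ``map_fn`` maps the evaluator over genomes and may execute
    concurrently as long as it preserves order (e.g. ``joblib.Parallel``);
    the default is the serial built-in ``map``.
    """
    t_start = time.perf_counter()
    control = control or ParameterVector.control()
    rng = rng or np.random.default_rng(config.seed)
    evaluator = evaluator or _make_evaluator(target, config, eval_config, control)
    map_fn = map_fn or (lambda f, xs: list(map(f, xs)))
    lo, hi = config.resolved_bounds()
    n_obj = config.n_objectives

    pop = init_population(config, rng, seed_individual, seed_spread)
    n_eval = _evaluate_all(pop, evaluator, map_fn)
    if all(ind.objectives.penalized for ind in pop):
        raise RuntimeError(
            "every individual of the initial population failed to simulate; "
            "check bounds and stimulus settings")

    history = []
    gen = 0
    for gen in range(1, config.max_generations + 1):
        fronts = nondominated_sort(pop, n_obj)
        for fr in fronts:
            crowding_distance(pop, fr, n_obj)

        sigma = config.sigma_at(gen)
        children: list[Individual] = []
        while len(children) < config.population_size:
            pa, pb = _tournament(pop, rng), _tournament(pop, rng)
            c1, c2 = crossover(pa, pb, config.crossover_rate, rng,
                               config.crossover_spread, lo, hi)
            children.append(mutate(c1, config.mutation_rate, sigma, lo, hi, rng))
            children.append(mutate(c2, config.mutation_rate, sigma, lo, hi, rng))
        n_eval += _evaluate_all(children, evaluator, map_fn)

        pool = pop + children
        fronts = nondominated_sort(pool, n_obj)
        survivors: list[Individual] = []
        for fr in fronts:
            crowding_distance(pool, fr, n_obj)
            if len(survivors) + len(fr) <= config.population_size:
                survivors.extend(pool[i] for i in fr)
            else:
                rest = sorted(fr, key=lambda i: -pool[i].crowding)
                survivors.extend(
                    pool[i] for i in rest[: config.population_size - len(survivors)])
                break
        pop = survivors

        first = [ind for ind in pop if ind.rank == 0]
        b = select_best(first)
        history.append({
            "generation": gen,
            "best_f_ap": b.objectives.f_ap,
            "best_f_rm": b.objectives.f_rm,
            "best_rmse_mv": b.objectives.rmse_mv,
            "front_size": len(first),
            "evaluations": n_eval,
        })
        if time.perf_counter() - t_start > config.max_wall_time_s:
            break

    fronts = nondominated_sort(pop, n_obj)
    front = [pop[i] for i in fronts[0]]
    best = select_best(front)
    return ParetoResult(pop, front, best, pd.DataFrame(history), config,
                        gen, n_eval, time.perf_counter() - t_start)


@dataclass
class RestartResult:
    """Chained-restart outcome: last run, overall best, per-run bests."""

    final: ParetoResult
    best: Individual
    per_run_best: list[Individual]


def run_with_restarts(target: TargetDataset, config: GAConfig,
                      n_restarts: int | None = None,
                      seed_spread: float | None = None,
                      **kwargs) -> RestartResult:
    """Chain GA runs, each restart initialized from the previous best.

    The first run starts from a uniform random population; every later run
    includes the previous best solution in its initial population.  By
    default the rest of each restart population is drawn uniformly over the
    full range (fresh diversity measurably outperforms a local cloud here);
    ``seed_spread`` switches to Gaussian perturbations of the seed.  The
    mutation-sigma annealing restarts with each run, giving repeated
    coarse-to-fine refinement cycles.
    """
    n_restarts = n_restarts or config.n_restarts
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(config.seed)
    seed_ind = None
    bests, result = [], None
    for _ in range(n_restarts):
        result = run_ga(target, config, seed_individual=seed_ind,
                        seed_spread=seed_spread, rng=rng, **kwargs)
        bests.append(result.best)
        seed_ind = result.best.genome
    overall = min(bests, key=lambda b: b.objectives.f_ap)
    return RestartResult(result, overall, bests)


def variability_report(results: Sequence[ParetoResult],
                       control: ParameterVector) -> pd.DataFrame:
    """Across-run mean and SD of the selected-best parameters, normalized by
    the control value of each parameter (the Fig-4B-style summary)."""
    if len(results) < 2:
        raise ValueError("need at least two runs to report variability")
    names = results[0].config.fitted_parameters
    if any(r.config.fitted_parameters != names for r in results):
        raise ValueError("all runs must fit the same parameter subset")
    genomes = np.array([r.best.genome for r in results])
    ctrl = np.array([getattr(control, n) for n in names])
    return pd.DataFrame({
        "mean": genomes.mean(axis=0) / ctrl,
        "sd": genomes.std(axis=0, ddof=1) / ctrl,
    }, index=list(names))
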