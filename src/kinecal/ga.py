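"""The genetic algorithm: operators, search strategies and the iteration loop.

A candidate model ("individual") is a vector of free rate parameters.  Each
iteration simulates every new candidate ``n_sims`` times, scores the ensemble
against the replicated data with the configured objective(s), ranks the
population, and produces the next generation by selection, recombination and
mutation.  Three strategies are provided:

1. *elitist*: the top-E individuals (and their cached fitness — their
   simulations are never repeated) carry over unchanged; parents are drawn
   uniformly from that elite, self-recombination allowed; single-point
   crossover; per-parameter redraw mutation with probability 0.30.
2. *non-elitist inverse-rank*: two distinct parents drawn from the whole
   population with probability proportional to 1/rank; single-point
   crossover; redraw mutation 0.30.  Elitism optional.
3. like 2 but multi-point crossover and factor mutation: with probability
   0.20 a parameter is multiplied by a uniform factor in a +-10% interval
   centred on its old value (clipped to bounds).

Multiple objectives are combined by unweighted sum of ranks (see
:mod:`kinecal.moga`).  Reproducibility: one root seed spawns independent
named streams for initialisation, selection, crossover, mutation and
simulation, and each candidate's simulation seed is derived from
(root seed, iteration, candidate id) so neither evaluation order nor worker
count can change any result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import ExperimentalData, FitnessRecord, ObjectiveSpec, SimulationEnsemble
from .moga import rank_order, sum_of_ranks
from .objectives.algebraic import aggregate_objective
from .objectives.equivalence import (
    EquivalenceSettings,
    build_rejection_matrix,
    iterative_score,
)

__all__ = [
    "ParameterSpec",
    "Individual",
    "GAConfig",
    "CalibrationResult",
    "initialize_population",
    "inverse_rank_probabilities",
    "select_parents",
    "crossover",
    "mutate",
    "rank_population",
    "score_ensemble",
    "calibrate",
    "fractional_error",
    "percent_errors",
]

#: fitness assigned to candidates whose simulation failed; always ranks last
FAILED_FITNESS = math.inf


@dataclass(frozen=True)
class ParameterSpec:
    """One free parameter: bounds and the law used to draw fresh values."""

    name: str
    lower: float
    upper: float
    law: str = "log_uniform"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.law not in ("uniform", "log_uniform"):
            raise ValueError(f"{self.name}: law must be 'uniform' or 'log_uniform'")
        if self.law == "log_uniform" and self.lower <= 0:
            raise ValueError(f"{self.name}: log_uniform requires a positive lower bound")

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.law == "uniform":
            return rng.uniform(self.lower, self.upper, size)
        return np.exp(rng.uniform(np.log(self.lower), np.log(self.upper), size))

    def clip(self, value: float) -> float:
        return float(min(max(value, self.lower), self.upper))


@dataclass
class Individual:
    """One candidate parameter vector with its fitness record and lineage."""

    id: int
    params: np.ndarray
    fitness: FitnessRecord = field(default_factory=FitnessRecord)
    parents: tuple[int, ...] = ()
    born: int = 0

    @property
    def evaluated(self) -> bool:
        return bool(self.fitness.values)


@dataclass(frozen=True)
class GAConfig:
    """Calibration configuration.

    ``crossover``/``mutation``/``mutation_prob`` default to the convention of
    the chosen strategy and only need to be set to override it.
    """

    specs: tuple[ParameterSpec, ...]
    objectives: tuple[ObjectiveSpec, ...]
    population_size: int = 100
    elite_size: int = 10
    iterations: int = 100
    n_sims: int = 10
    strategy: int = 1
    crossover: str | None = None          # single_point | multi_point
    mutation: str | None = None           # redraw | factor
    mutation_prob: float | None = None
    mutation_halfwidth: float = 0.10
    elitism: bool | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "specs", tuple(self.specs))
        object.__setattr__(self, "objectives", tuple(self.objectives))
        if not self.specs:
            raise ValueError("at least one free parameter required")
        if not self.objectives:
            raise ValueError("at least one objective required")
        if self.strategy not in (1, 2, 3):
            raise ValueError("strategy must be 1, 2 or 3")
        if not 1 <= self.elite_size < self.population_size:
            raise ValueError("need 1 <= elite_size < population_size")
        if self.iterations < 1 or self.n_sims < 1:
            raise ValueError("iterations and n_sims must be >= 1")
        p = self.resolved_mutation_prob
        if not 0.0 <= p <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")

    @property
    def resolved_crossover(self) -> str:
        if self.crossover is not None:
            return self.crossover
        return "multi_point" if self.strategy == 3 else "single_point"

    @property
    def resolved_mutation(self) -> str:
        if self.mutation is not None:
            return self.mutation
        return "factor" if self.strategy == 3 else "redraw"

    @property
    def resolved_mutation_prob(self) -> float:
        if self.mutation_prob is not None:
            return self.mutation_prob
        return 0.20 if self.strategy == 3 else 0.30

    @property
    def resolved_elitism(self) -> bool:
        if self.elitism is not None:
            return self.elitism
        return self.strategy == 1

    @property
    def objective_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.objectives)


# ---------------------------------------------------------------------------
# operators


def initialize_population(
    specs: Sequence[ParameterSpec], population_size: int, rng: np.random.Generator | int
) -> list[Individual]:
    """Draw each parameter independently per its sampling law."""
    if population_size < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pop = []
    for i in range(population_size):
        params = np.array([spec.draw(rng) for spec in specs], dtype=float)
        pop.append(Individual(id=i, params=params, born=0))
    return pop


def inverse_rank_probabilities(population_size: int) -> np.ndarray:
    """Selection probabilities p_i = 1 / (r_i * sum_j 1/r_j), r_i = 1..R."""
    if population_size < 1:
        raise ValueError("population size must be >= 1")
    ranks = np.arange(1, population_size + 1, dtype=float)
    harmonic = (1.0 / ranks).sum()
    return 1.0 / (ranks * harmonic)


def select_parents(
    ranked: Sequence[Individual],
    strategy: int,
    elite_size: int,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Pick two parents from a ranked (best-first) population.

    Strategy 1 draws both uniformly from the top-``elite_size`` individuals
    with replacement (self-recombination allowed).  Strategies 2 and 3 draw
    two *distinct* parents from the whole population with inverse-rank
    probabilities.
    """
    if not ranked:
        raise ValueError("empty population")
    if strategy == 1:
        elite = ranked[: min(elite_size, len(ranked))]
        i, j = rng.integers(0, len(elite), size=2)
        return elite[int(i)], elite[int(j)]
    if len(ranked) < 2:
        raise ValueError("inverse-rank selection needs at least two individuals")
    probs = inverse_rank_probabilities(len(ranked))
    i, j = rng.choice(len(ranked), size=2, replace=False, p=probs)
    return ranked[int(i)], ranked[int(j)]


def crossover(
    a: np.ndarray, b: np.ndarray, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Recombine two parameter vectors.

    ``single_point``: one cut at a uniform interior index, head from the
    first parent, tail from the second.  ``multi_point``: each parameter
    independently from either parent with probability 1/2.  A single free
    parameter degenerates to a coin flip between the parents.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must share the parameter layout")
    d = a.size
    if mode == "single_point":
        if d == 1:
            return (a if rng.random() < 0.5 else b).copy()
        k = int(rng.integers(1, d))
        return np.concatenate([a[:k], b[k:]])
    if mode == "multi_point":
        take_a = rng.random(d) < 0.5
        return np.where(take_a, a, b)
    raise ValueError(f"unknown crossover mode {mode!r}")


def mutate(
    child: np.ndarray,
    specs: Sequence[ParameterSpec],
    mode: str,
    prob: float,
    rng: np.random.Generator,
    halfwidth: float = 0.10,
) -> np.ndarray:
    """Per-parameter Bernoulli mutation.

    ``redraw``: with probability ``prob`` replace the value by a fresh draw
    from its sampling law.  ``factor``: with probability ``prob`` multiply by
    a uniform factor in [1-halfwidth, 1+halfwidth], then clip to bounds.
    """
    out = np.asarray(child, dtype=float).copy()
    hit = rng.random(out.size) < prob
    for k, spec in enumerate(specs):
        if not hit[k]:
            continue
        if mode == "redraw":
            out[k] = spec.draw(rng)
        elif mode == "factor":
            out[k] = spec.clip(out[k] * rng.uniform(1.0 - halfwidth, 1.0 + halfwidth))
        else:
            raise ValueError(f"unknown mutation mode {mode!r}")
    return out


def rank_population(
    pop: Sequence[Individual], objective_names: Sequence[str]
) -> list[Individual]:
    """Best-first ordering by sum of per-objective ranks, ties by id.

    Also writes per-objective ranks and the combined rank into each
    individual's fitness record.  Failed-simulation sentinels rank last.
    """
    fm = np.array([ind.fitness.fitness_vector(objective_names) for ind in pop])
    ids = np.array([ind.id for ind in pop])
    combined = sum_of_ranks(fm)
    order = rank_order(fm, ids)
    from scipy.stats import rankdata

    for k, name in enumerate(objective_names):
        col_ranks = rankdata(fm[:, k], method="min")
        for ind, r in zip(pop, col_ranks):
            ind.fitness.ranks[name] = int(r)
    for ind, c in zip(pop, combined):
        ind.fitness.combined_rank = float(c)
    return [pop[i] for i in order]


def score_ensemble(
    objectives: Sequence[ObjectiveSpec],
    data: ExperimentalData,
    sims: SimulationEnsemble | None,
) -> dict[str, float]:
    """Evaluate every configured objective; a missing ensemble scores the
    failed-simulation sentinel on all of them."""
    if sims is None:
        return {o.name: FAILED_FITNESS for o in objectives}
    values: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for obj in objectives:
            if obj.is_equivalence_test:
                settings = EquivalenceSettings(
                    test=obj.name, alpha=obj.alpha, range_mode=obj.range_mode,
                    range_value=obj.range_value, band=obj.band,
                )
                values[obj.name] = float(
                    iterative_score(build_rejection_matrix(settings, data, sims))
                )
            else:
                values[obj.name] = aggregate_objective(obj.name, data, sims)
    return values


# ---------------------------------------------------------------------------
# the calibration loop


@dataclass
class CalibrationResult:
    """Everything a calibration run produced.

    ``history`` has one row per individual per iteration (parameters, every
    objective value, combined rank); ``best_per_iteration`` tracks the
    population-best value of each objective.
    """

    config: GAConfig
    best: Individual
    final_population: list[Individual]
    history: pd.DataFrame
    best_per_iteration: pd.DataFrame
    seed: int

    @property
    def best_params(self) -> pd.Series:
        return pd.Series(self.best.params, index=[s.name for s in self.config.specs])

    def elite_mean_fitness(self, objective: str | None = None) -> np.ndarray:
        """Mean fitness of the elite (top-E) individuals per iteration."""
        name = objective or self.config.objective_names[0]
        E = self.config.elite_size
        groups = self.history.sort_values(["iteration", "combined_rank", "id"]).groupby("iteration")
        return np.array([g.head(E)[name].mean() for _, g in groups])

    def fractional_error(self, objective: str | None = None) -> np.ndarray:
        return fractional_error(self.elite_mean_fitness(objective))


def fractional_error(series: Sequence[float]) -> np.ndarray:
    """Series normalised by its first entry (first iteration maps to 1)."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if arr[0] == 0:
        raise ValueError("fractional error undefined: first entry is zero")
    return arr / arr[0]


def percent_errors(found: Sequence[float], true: Sequence[float]) -> np.ndarray:
    """Signed percent error per parameter: (found/true - 1) * 100."""
    found = np.asarray(found, dtype=float)
    true = np.asarray(true, dtype=float)
    return (found / true - 1.0) * 100.0


def _candidate_sim_seed(root: int, iteration: int, cand_id: int) -> int:
    """Stable per-candidate simulation seed: independent of evaluation order."""
    ss = np.random.SeedSequence([int(root) & 0x7FFFFFFF, iteration, cand_id])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def calibrate(
    config: GAConfig,
    backend,
    data: ExperimentalData,
    workers: int = 1,
    callback: Callable[[int, list[Individual]], None] | None = None,
) -> CalibrationResult:
    """Run the genetic algorithm against replicated experimental data.

    ``backend`` maps (parameter assignment, n_sims, times, seed) to an
    aligned :class:`SimulationEnsemble` (see :mod:`kinecal.orchestration`).
    A backend failure for a candidate assigns the sentinel fitness and the
    run continues; if an entire iteration fails the calibration aborts.

    Fully reproducible from ``config.seed``: operator draws come from named
    child streams and candidate simulation seeds depend only on (root seed,
    iteration, candidate id), so results are identical for any ``workers``.
    """
    from .orchestration import dispatch  # local import to avoid a cycle

    root = np.random.SeedSequence(config.seed)
    init_rng, select_rng, cross_rng, mut_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    names = config.objective_names
    spec_names = [s.name for s in config.specs]
    single_objective = len(names) == 1

    pop = initialize_population(config.specs, config.population_size, init_rng)
    next_id = config.population_size
    history_rows: list[dict] = []
    best_rows: list[dict] = []
    running_best = {name: math.inf for name in names}

    for iteration in range(1, config.iterations + 1):
        fresh = [ind for ind in pop if not ind.evaluated]
        jobs = [
            (ind.id, dict(zip(spec_names, ind.params)), config.n_sims,
             _candidate_sim_seed(config.seed, ind.born, ind.id))
            for ind in fresh
        ]
        results = dispatch(_SimulationTask(backend, data.times), jobs, workers=workers)
        n_failed = 0
        for ind, (ok, ens) in zip(fresh, results):
            if not ok:
                n_failed += 1
                ens = None
            ind.fitness.values = score_ensemble(config.objectives, data, ens)
        if fresh and n_failed == len(fresh) and all(
            not math.isfinite(ind.fitness.values[names[0]]) for ind in pop
        ):
            raise RuntimeError(
                f"iteration {iteration}: every candidate simulation failed"
            )

        ranked = rank_population(pop, names)
        for ind in ranked:
            row = {"iteration": iteration, "id": ind.id,
                   "combined_rank": ind.fitness.combined_rank}
            row.update(dict(zip(spec_names, ind.params)))
            row.update(ind.fitness.values)
            history_rows.append(row)
        iter_best = {name: min(ind.fitness.values[name] for ind in ranked) for name in names}
        for name in names:
            running_best[name] = min(running_best[name], iter_best[name])
        best_rows.append({"iteration": iteration, **iter_best,
                          **{f"running_best_{k}": v for k, v in running_best.items()}})

        # exact elitism invariant: with cached elite fitness the population
        # best of a single objective can never regress
        if config.resolved_elitism and single_objective and iteration > 1:
            assert iter_best[names[0]] <= best_rows[-2][names[0]] + 0.0, \
                "elitism violated: best fitness increased"

        if callback is not None:
            callback(iteration, ranked)
        if iteration == config.iterations:
            pop = ranked
            break

        # next generation
        n_carry = config.elite_size if config.resolved_elitism else 0
        new_pop = list(ranked[:n_carry])
        while len(new_pop) < config.population_size:
            pa, pb = select_parents(ranked, config.strategy, config.elite_size, select_rng)
            child = crossover(pa.params, pb.params, config.resolved_crossover, cross_rng)
            child = mutate(child, config.specs, config.resolved_mutation,
                           config.resolved_mutation_prob, mut_rng,
                           config.mutation_halfwidth)
            new_pop.append(Individual(id=next_id, params=child,
                                      parents=(pa.id, pb.id), born=iteration))
            next_id += 1
        pop = new_pop

    history = pd.DataFrame(history_rows)
    best_df = pd.DataFrame(best_rows)
    return CalibrationResult(
        config=config, best=pop[0], final_population=pop,
        history=history, best_per_iteration=best_df, seed=config.seed,
    )


class _SimulationTask:
    """Picklable per-candidate simulation job for the dispatch pool."""

    def __init__(self, backend, times: np.ndarray):
        self.backend = backend
        self.times = np.asarray(times, dtype=float)

    def __call__(self, job):
        cand_id, assignment, n_sims, seed = job
        return self.backend.simulate(assignment, n_sims, self.times, seed)
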