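"""Model/Results front end for calibrations, in the style of statsmodels.

:class:`KineticCalibration` binds the replicated data, a simulator backend
and the search configuration; :meth:`KineticCalibration.fit` runs the
genetic algorithm and returns :class:`CalibrationResults`, which carries the
recovered parameters, the convergence history, diagnostics and the
uncertainty procedures.

Example
-------
>>> from kinecal import KineticCalibration
>>> from kinecal.ssa import aguilera_network, generate_synthetic_dataset
>>> net = aguilera_network()
>>> data = generate_synthetic_dataset(net, n_replicates=10, seed=7)
>>> model = KineticCalibration.from_network(
...     data, net, bounds=(1e-2, 1e2), objectives=["TOST"],
...     population_size=50, iterations=30)
>>> results = model.fit(seed=1)
>>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExperimentalData, ObjectiveSpec
from .ga import (
    CalibrationResult,
    GAConfig,
    ParameterSpec,
    calibrate,
    percent_errors,
)
from .moga import objective_correlation
from .orchestration import BuiltinSSABackend
from .ssa import ReactionNetwork
from .uncertainty import (
    UncertaintyReport,
    bootstrap_calibrations,
    jackknife_calibrations,
)

__all__ = ["KineticCalibration", "CalibrationResults"]


def _as_objective(obj) -> ObjectiveSpec:
    return obj if isinstance(obj, ObjectiveSpec) else ObjectiveSpec(name=str(obj))


class KineticCalibration:
    """A calibration problem: data + simulator backend + search space.

    Parameters
    ----------
    data : ExperimentalData
        Replicated measurements on the target time grid.
    backend : object
        Anything with ``simulate(assignment, n_sims, times, seed)``.
    param_specs : sequence of ParameterSpec
        The free parameters with bounds and sampling law.
    objectives : sequence of str or ObjectiveSpec
        One id gives a single-objective GA; several combine by sum of ranks.
    """

    def __init__(
        self,
        data: ExperimentalData,
        backend,
        param_specs: Sequence[ParameterSpec],
        objectives: Sequence = ("SDA",),
        strategy: int = 1,
        population_size: int = 100,
        elite_size: int = 10,
        iterations: int = 100,
        n_sims: int = 10,
        **config_overrides,
    ):
        self.data = data
        self.backend = backend
        self._base_config = GAConfig(
            specs=tuple(param_specs),
            objectives=tuple(_as_objective(o) for o in objectives),
            population_size=population_size,
            elite_size=elite_size,
            iterations=iterations,
            n_sims=n_sims,
            strategy=strategy,
            **config_overrides,
        )

    @classmethod
    def from_network(
        cls,
        data: ExperimentalData,
        network: ReactionNetwork,
        free_parameters: Sequence[str] | None = None,
        bounds: tuple[float, float] | Mapping[str, tuple[float, float]] = (1e-2, 1e2),
        law: str = "log_uniform",
        max_events: int = 1_000_000,
        **kwargs,
    ) -> "KineticCalibration":
        """Build from a mass-action network simulated with the built-in engine.

        By default every rate parameter of the network is free, searched on a
        log-uniform law between the given bounds.
        """
        names = list(free_parameters) if free_parameters else list(network.parameters)
        specs = []
        for name in names:
            lo, hi = bounds[name] if isinstance(bounds, Mapping) else bounds
            specs.append(ParameterSpec(name, lo, hi, law))
        backend = BuiltinSSABackend(network, max_events=max_events)
        return cls(data, backend, specs, **kwargs)

    @property
    def param_names(self) -> list[str]:
        return [s.name for s in self._base_config.specs]

    def config(self, seed: int = 0) -> GAConfig:
        return replace(self._base_config, seed=int(seed))

    def fit(self, seed: int = 0, workers: int = 1) -> "CalibrationResults":
        """Run the genetic algorithm; deterministic given ``seed``."""
        raw = calibrate(self.config(seed), self.backend, self.data, workers=workers)
        return CalibrationResults(self, raw)

    def jackknife(self, seed: int = 0, unit: str = "replicate",
                  workers: int = 1) -> UncertaintyReport:
        return jackknife_calibrations(self.data, self.config(seed), self.backend,
                                      unit=unit, workers=workers)

    def bootstrap(self, seed: int = 0, n_runs: int = 20, level: float = 0.90,
                  workers: int = 1, point: pd.Series | None = None) -> UncertaintyReport:
        return bootstrap_calibrations(self.data, self.config(seed), self.backend,
                                      n_runs=n_runs, level=level, workers=workers,
                                      point=point)


class CalibrationResults:
    """Fitted-calibration results: estimates, convergence and diagnostics."""

    def __init__(self, model: KineticCalibration, raw: CalibrationResult):
        self.model = model
        self.raw = raw

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """Best model's parameter vector."""
        return self.raw.best_params

    @property
    def fitness(self) -> pd.Series:
        """Best model's value for every configured objective."""
        return pd.Series(self.raw.best.fitness.values)

    @property
    def objective_names(self) -> tuple[str, ...]:
        return self.raw.config.objective_names

    @property
    def history(self) -> pd.DataFrame:
        return self.raw.history

    @property
    def best_per_iteration(self) -> pd.DataFrame:
        return self.raw.best_per_iteration

    def percent_errors(self, true_params: Mapping[str, float]) -> pd.Series:
        """Signed percent error of each recovered rate against known truth."""
        true = pd.Series(true_params).reindex(self.params.index)
        return pd.Series(percent_errors(self.params.to_numpy(), true.to_numpy()),
                         index=self.params.index)

    def fractional_error(self, objective: str | None = None) -> np.ndarray:
        """Elite mean fitness normalised by its first-iteration value."""
        return self.raw.fractional_error(objective)

    def objective_correlation(self, method: str = "spearman",
                              iteration: int = 1) -> pd.DataFrame:
        """Correlation between objectives over the population of one iteration."""
        names = list(self.objective_names)
        sub = self.history[self.history["iteration"] == iteration]
        fm = sub[names].to_numpy()
        finite = np.all(np.isfinite(fm), axis=1)
        return objective_correlation(fm[finite], names, method=method)

    # -- uncertainty -------------------------------------------------------

    def bootstrap(self, n_runs: int = 20, level: float = 0.90, seed: int | None = None,
                  workers: int = 1) -> UncertaintyReport:
        return self.model.bootstrap(
            seed=self.raw.seed if seed is None else seed,
            n_runs=n_runs, level=level, workers=workers, point=self.params)

    def jackknife(self, unit: str = "replicate", seed: int | None = None,
                  workers: int = 1) -> UncertaintyReport:
        return self.model.jackknife(
            seed=self.raw.seed if seed is None else seed, unit=unit, workers=workers)

    # -- presentation ------------------------------------------------------

    def summary(self, true_params: Mapping[str, float] | None = None) -> str:
        cfg = self.raw.config
        lines = [
            "Kinetic model calibration (genetic algorithm)",
            "=" * 58,
            f"strategy:        {cfg.strategy} "
            f"({'elitist' if cfg.resolved_elitism else 'non-elitist'}, "
            f"{cfg.resolved_crossover} crossover, "
            f"{cfg.resolved_mutation} mutation p={cfg.resolved_mutation_prob:g})",
            f"objectives:      {', '.join(cfg.objective_names)}",
            f"population:      {cfg.population_size} (elite {cfg.elite_size}), "
            f"{cfg.iterations} iterations, {cfg.n_sims} sims/candidate",
            f"data:            {self.model.data.m} replicates x "
            f"{self.model.data.times.size} timepoints x "
            f"{len(self.model.data.observables)} observables",
            f"seed:            {self.raw.seed}",
            "-" * 58,
        ]
        table = pd.DataFrame({"estimate": self.params})
        if true_params is not None:
            table["true"] = pd.Series(true_params).reindex(self.params.index)
            table["pct_error"] = self.percent_errors(true_params).round(2)
        lines.append(table.to_string())
        lines.append("-" * 58)
        lines.append("best fitness:    "
                     + ", ".join(f"{k}={v:g}" for k, v in self.fitness.items()))
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Per-iteration population TSV + best-model parameter file."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(directory / "population_history.tsv", sep="\t", index=False)
        self.params.rename("value").to_csv(directory / "best_parameters.tsv", sep="\t")
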