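"""The nine algebraic fitness functions, evaluated per (observable, timepoint) cell.

Notation: a cell holds the m experimental replicate values ``exp_i`` and the
n simulated values ``sim_j`` for one observable at one timepoint; ``x̄_exp``
is the replicate mean and ``σ_exp`` the sample standard deviation (divisor
m−1).  All objectives are non-negative, vanish on a perfect fit (where
defined), and are summed over all cells to produce a model's fitness.

Definitions (per cell):

====== ==========================================================
SDA    (x̄_exp − x̄_sim)²
ADA    |x̄_exp − x̄_sim|
PWSD   (1/mn) Σ_i Σ_j (exp_i − sim_j)²
APWSD  (1/mn) Σ_i Σ_j |exp_i − sim_j|
NPWSD  (1/mn) Σ_i Σ_j ((exp_i − sim_j)/exp_i)²
ANPWSD (1/mn) Σ_i Σ_j |(exp_i − sim_j)/exp_i|
SSQ    Σ_i Σ_j (exp_i − sim_j)²
CHISQ  Σ_i Σ_j ((exp_i − sim_j)/σ_exp)²
MNSE   Σ_i Σ_j ((exp_i − sim_j)/x̄_exp)²
====== ==========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..data import ExperimentalData, SimulationEnsemble, check_aligned

__all__ = [
    "ALGEBRAIC_NAMES",
    "CellSample",
    "DegenerateCellError",
    "cell_objective",
    "aggregate_objective",
]

ALGEBRAIC_NAMES = ("SDA", "ADA", "PWSD", "APWSD", "NPWSD", "ANPWSD", "SSQ", "CHISQ", "MNSE")


class DegenerateCellError(ValueError):
    """A cell lacks the dispersion or mean the objective divides by."""


@dataclass(frozen=True)
class CellSample:
    """One (observable, timepoint) cell: m experimental and n simulated values."""

    exp: np.ndarray
    sim: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "exp", np.asarray(self.exp, dtype=float).ravel())
        object.__setattr__(self, "sim", np.asarray(self.sim, dtype=float).ravel())
        if self.exp.size < 1 or self.sim.size < 1:
            raise ValueError("cell needs at least one experimental and one simulated value")

    @property
    def m(self) -> int:
        return self.exp.size

    @property
    def n(self) -> int:
        return self.sim.size

    @property
    def mean_exp(self) -> float:
        return float(self.exp.mean())

    @property
    def sigma_exp(self) -> float:
        """Sample standard deviation of the replicates (divisor m−1)."""
        if self.m < 2:
            raise DegenerateCellError("sigma_exp requires at least two replicates")
        return float(self.exp.std(ddof=1))


def cell_objective(name: str, cell: CellSample) -> float:
    """Evaluate one algebraic objective on one cell."""
    exp, sim = cell.exp, cell.sim
    diff = exp[:, None] - sim[None, :]
    mn = cell.m * cell.n
    if name == "SDA":
        return float((exp.mean() - sim.mean()) ** 2)
    if name == "ADA":
        return float(abs(exp.mean() - sim.mean()))
    if name == "PWSD":
        return float((diff**2).sum() / mn)
    if name == "APWSD":
        return float(np.abs(diff).sum() / mn)
    if name in ("NPWSD", "ANPWSD"):
        keep = exp != 0.0
        n_kept = int(keep.sum()) * cell.n
        if n_kept == 0:
            warnings.warn("all exp values zero in normalised objective; cell contributes 0",
                          stacklevel=2)
            return 0.0
        rel = diff[keep] / exp[keep, None]
        term = rel**2 if name == "NPWSD" else np.abs(rel)
        return float(term.sum() / n_kept)
    if name == "SSQ":
        return float((diff**2).sum())
    if name == "CHISQ":
        sigma = cell.sigma_exp
        if sigma == 0.0:
            raise DegenerateCellError("CHISQ undefined: zero replicate dispersion")
        return float(((diff / sigma) ** 2).sum())
    if name == "MNSE":
        mean = cell.mean_exp
        if mean == 0.0:
            raise DegenerateCellError("MNSE undefined: zero replicate mean")
        return float(((diff / mean) ** 2).sum())
    raise ValueError(f"unknown algebraic objective {name!r}")


def aggregate_objective(
    name: str,
    data: ExperimentalData,
    sims: SimulationEnsemble,
    diagnostics: dict | None = None,
) -> float:
    """Sum of :func:`cell_objective` over every (observable, timepoint) cell.

    Cells where the objective is degenerate (zero dispersion for CHISQ, zero
    mean for MNSE, all-zero replicates for the normalised deviations)
    contribute 0 and are counted in ``diagnostics['skipped_cells']``.
    """
    check_aligned(data, sims)
    total = 0.0
    skipped: list[tuple[str, int]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v, obs in enumerate(data.observables):
            for t in range(data.times.size):
                cell = CellSample(data.values[:, t, v], sims.values[:, t, v])
                try:
                    total += cell_objective(name, cell)
                except DegenerateCellError:
                    skipped.append((obs, t))
    if diagnostics is not None:
        diagnostics["skipped_cells"] = skipped
    return total


def per_observable_objective(
    name: str, data: ExperimentalData, sims: SimulationEnsemble
) -> dict[str, float]:
    """Diagnostic breakdown: aggregate restricted to each observable."""
    check_aligned(data, sims)
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v, obs in enumerate(data.observables):
            total = 0.0
            for t in range(data.times.size):
                cell = CellSample(data.values[:, t, v], sims.values[:, t, v])
                try:
                    total += cell_objective(name, cell)
                except DegenerateCellError:
                    pass
            out[obs] = total
    return out
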