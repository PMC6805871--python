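"""Shared domain containers: replicated experimental data and simulation ensembles.

Both containers hold a dense tensor indexed (replicate/run, timepoint, observable)
over a common time grid.  Fitness functions score the two tensors cell by cell,
where a *cell* is one (observable, timepoint) pair holding the m experimental
replicate values and the n simulated run values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentalData",
    "SimulationEnsemble",
    "ObjectiveSpec",
    "FitnessRecord",
    "read_experimental_table",
    "write_experimental_table",
    "align_to_times",
]

#: objective identifiers accepted throughout the package
OBJECTIVE_NAMES = (
    "SDA", "ADA", "PWSD", "APWSD", "NPWSD", "ANPWSD", "SSQ", "CHISQ", "MNSE",
    "TOST", "DUT", "WMWET",
)


class DataValidationError(ValueError):
    """Raised when a container or table violates a structural invariant."""


class AlignmentError(ValueError):
    """Raised when simulation and data time grids cannot be matched."""


def _validate_grid(observables: Sequence[str], times: np.ndarray) -> None:
    if len(set(observables)) != len(observables):
        raise DataValidationError("duplicate observable names")
    if times.ndim != 1 or times.size == 0:
        raise DataValidationError("time grid must be a non-empty 1-d array")
    if np.any(np.diff(times) <= 0):
        raise DataValidationError("time grid must be strictly increasing")
    if not np.all(np.isfinite(times)):
        raise DataValidationError("time grid must be finite")


@dataclass(frozen=True)
class ExperimentalData:
    """Replicated measurements on a fixed time grid.

    Parameters
    ----------
    observables : list of str
        Names of the measured variables (columns of the tensor).
    times : ndarray, shape (T,)
        Strictly increasing sampling times, in model time units.
    values : ndarray, shape (m, T, V)
        Non-negative abundances; replicate x timepoint x observable.
    """

    observables: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "observables", tuple(self.observables))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_grid(self.observables, self.times)
        if self.values.ndim != 3:
            raise DataValidationError("values must be a (m, T, V) tensor")
        m, T, V = self.values.shape
        if m < 1:
            raise DataValidationError("need at least one replicate")
        if T != self.times.size or V != len(self.observables):
            raise DataValidationError(
                f"tensor shape {self.values.shape} does not match "
                f"{self.times.size} times x {len(self.observables)} observables"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("values must be finite")

    @property
    def m(self) -> int:
        """Number of replicates."""
        return self.values.shape[0]

    def cell(self, observable: str, time_index: int) -> np.ndarray:
        """The m replicate values for one (observable, timepoint)."""
        return self.values[:, time_index, self.observables.index(observable)]

    def drop_timepoint(self, index: int) -> "ExperimentalData":
        keep = [i for i in range(self.times.size) if i != index]
        return ExperimentalData(self.observables, self.times[keep], self.values[:, keep, :])

    def drop_replicate(self, index: int) -> "ExperimentalData":
        keep = [i for i in range(self.m) if i != index]
        if not keep:
            raise DataValidationError("cannot drop the only replicate")
        return ExperimentalData(self.observables, self.times, self.values[keep])

    def resample_replicates(self, indices: Sequence[int]) -> "ExperimentalData":
        """Bootstrap helper: new dataset from replicate indices drawn with replacement."""
        return ExperimentalData(self.observables, self.times, self.values[list(indices)])


@dataclass(frozen=True)
class SimulationEnsemble:
    """n stochastic runs of one candidate model, on the same grid as the data."""

    observables: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "observables", tuple(self.observables))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_grid(self.observables, self.times)
        if self.values.ndim != 3:
            raise DataValidationError("values must be a (n, T, V) tensor")
        n, T, V = self.values.shape
        if n < 1 or T != self.times.size or V != len(self.observables):
            raise DataValidationError("ensemble tensor shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("ensemble values must be finite")
        if np.any(self.values < 0):
            raise DataValidationError("ensemble values must be non-negative")

    @property
    def n(self) -> int:
        """Number of stochastic runs."""
        return self.values.shape[0]


def check_aligned(data: ExperimentalData, sims: SimulationEnsemble) -> None:
    """Assert the two containers share observables and time grid exactly."""
    if data.observables != sims.observables:
        raise AlignmentError(
            f"observable mismatch: {data.observables} vs {sims.observables}"
        )
    if data.times.shape != sims.times.shape or not np.array_equal(data.times, sims.times):
        raise AlignmentError("time-grid mismatch between data and simulations")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One configured fitness function.

    ``name`` is one of the nine algebraic acronyms (SDA, ADA, PWSD, APWSD,
    NPWSD, ANPWSD, SSQ, CHISQ, MNSE) or an iterative equivalence test
    (TOST, DUT, WMWET).  ``settings`` carries test-specific options:
    ``alpha`` (significance level), ``range_mode``/``range_value``
    (sd_multiple k or absolute epsilon for TOST/DUT) and ``band``
    (probability pair for WMWET).
    """

    name: str
    alpha: float = 0.05
    range_mode: str = "sd_multiple"   # "sd_multiple" | "absolute"
    range_value: float = 1.0
    band: tuple[float, float] = (0.19, 0.76)

    def __post_init__(self):
        if self.name not in OBJECTIVE_NAMES:
            raise DataValidationError(f"unknown objective {self.name!r}")
        if not 0.0 < self.alpha < 1.0:
            raise DataValidationError("alpha must lie in (0, 1)")
        if self.range_mode not in ("sd_multiple", "absolute"):
            raise DataValidationError("range_mode must be sd_multiple or absolute")
        if self.range_value < 0:
            raise DataValidationError("equivalence range must be non-negative")
        lo, hi = self.band
        if not (0.0 < lo < 0.5 < hi < 1.0):
            raise DataValidationError("band must satisfy 0 < p_lo < 0.5 < p_hi < 1")

    @property
    def is_equivalence_test(self) -> bool:
        return self.name in ("TOST", "DUT", "WMWET")


@dataclass
class FitnessRecord:
    """Per-objective fitness values and ranks for one candidate."""

    values: dict[str, float] = field(default_factory=dict)
    ranks: dict[str, int] = field(default_factory=dict)
    combined_rank: float | None = None

    def fitness_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# table ingestion


def _pivot_long(df: pd.DataFrame, time_column: str, replicate_column: str) -> ExperimentalData:
    observables = [c for c in df.columns if c not in (time_column, replicate_column)]
    reps = list(dict.fromkeys(df[replicate_column]))
    times = np.array(sorted(dict.fromkeys(df[time_column])), dtype=float)
    tensor = np.full((len(reps), times.size, len(observables)), np.nan)
    tindex = {t: i for i, t in enumerate(times)}
    rindex = {r: i for i, r in enumerate(reps)}
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        key = (row[replicate_column], row[time_column])
        if key in seen:
            raise DataValidationError(f"duplicate (replicate, time) pair {key}")
        seen.add(key)
        tensor[rindex[key[0]], tindex[float(key[1])], :] = [row[v] for v in observables]
    if np.any(np.isnan(tensor)):
        raise DataValidationError("missing cells: not every replicate covers every time")
    return ExperimentalData(tuple(observables), times, tensor)


def _pivot_stacked(df: pd.DataFrame, time_column: str) -> ExperimentalData:
    """Repeated time blocks, one block per replicate, in file order."""
    observables = [c for c in df.columns if c != time_column]
    times_all = df[time_column].to_numpy(dtype=float)
    # the first strictly-increasing run defines the grid
    block_end = times_all.size
    for i in range(1, times_all.size):
        if times_all[i] <= times_all[i - 1]:
            block_end = i
            break
    times = times_all[:block_end]
    if times_all.size % block_end != 0:
        raise DataValidationError("stacked table: replicate blocks have unequal length")
    m = times_all.size // block_end
    if not np.array_equal(times_all, np.tile(times, m)):
        raise DataValidationError("stacked table: replicate blocks disagree on the time grid")
    tensor = df[observables].to_numpy(dtype=float).reshape(m, block_end, len(observables))
    return ExperimentalData(tuple(observables), times, tensor)


def read_experimental_table(
    path: str | Path,
    dialect: str = "auto",
    time_column: str = "time",
    replicate_column: str = "replicate",
    sep: str | None = None,
) -> ExperimentalData:
    """Read a delimited replicate x time x observable table.

    Two encodings are accepted: ``long`` (an explicit replicate column) and
    ``stacked`` (the time column repeats once per replicate, blocks in file
    order).  ``auto`` picks ``long`` when the replicate column is present.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise DataValidationError(f"cannot parse {path}: {exc}") from exc
    if time_column not in df.columns:
        raise DataValidationError(f"no {time_column!r} column in {path}")
    value_cols = [c for c in df.columns if c not in (time_column, replicate_column)]
    bad = [c for c in value_cols + [time_column] if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise DataValidationError(f"non-numeric column(s) {bad} in {path}")
    if df[value_cols].isna().any().any() or df[time_column].isna().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise DataValidationError(f"missing cells at rows {rows} in {path}")
    if dialect == "auto":
        dialect = "long" if replicate_column in df.columns else "stacked"
    if dialect == "long":
        if replicate_column not in df.columns:
            raise DataValidationError(f"long dialect needs a {replicate_column!r} column")
        return _pivot_long(df, time_column, replicate_column)
    if dialect == "stacked":
        return _pivot_stacked(df, time_column)
    raise DataValidationError(f"unknown dialect {dialect!r}")


def write_experimental_table(
    data: ExperimentalData,
    path: str | Path,
    time_column: str = "time",
    replicate_column: str = "replicate",
) -> None:
    """Write in the long dialect; inverse of :func:`read_experimental_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    rows = []
    for r in range(data.m):
        for t, tv in enumerate(data.times):
            row = {replicate_column: r + 1, time_column: tv}
            row.update({v: data.values[r, t, k] for k, v in enumerate(data.observables)})
            rows.append(row)
    # shortest-repr floats + round_trip parsing make write/read the identity
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def align_to_times(
    traj: SimulationEnsemble, target_times: Sequence[float], tol: float = 1e-9
) -> SimulationEnsemble:
    """Subset an ensemble to ``target_times`` by exact matching within ``tol``.

    No interpolation: every returned value is one of the input samples.
    """
    target = np.asarray(target_times, dtype=float)
    idx = np.empty(target.size, dtype=int)
    missing = []
    for k, t in enumerate(target):
        j = int(np.argmin(np.abs(traj.times - t)))
        if abs(traj.times[j] - t) <= tol:
            idx[k] = j
        else:
            missing.append(float(t))
    if missing:
        raise AlignmentError(f"no trajectory sample within tol={tol} of times {missing}")
    return SimulationEnsemble(traj.observables, traj.times[idx], traj.values[:, idx, :])
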