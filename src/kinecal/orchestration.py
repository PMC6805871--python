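"""Simulator backends, model templating, output parsing and job dispatch.

The calibration loop only requires an object with a ``simulate(assignment,
n_sims, times, seed) -> SimulationEnsemble`` method.  Two backends ship:

* :class:`BuiltinSSABackend` — the in-process Gillespie engine; used by all
  tests and the recovery benchmarks.
* :class:`CommandBackend` — an adapter for external stochastic simulators
  (KaSim, BNG2, NFsim, ...) driven through a command template with
  ``{model}``, ``{seed}`` and ``{output}`` slots.  Free parameters are
  annotated in the model text as ``__FREE__<name>`` placeholders and
  substituted at full precision before each run.

Dispatch runs a batch of jobs either serially or on a multiprocessing pool;
results are keyed by batch position, never by completion order, so worker
count cannot change any downstream number.  A SLURM adapter is specified as
an interface stub only.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import SimulationEnsemble, align_to_times
from .ssa import ReactionNetwork, simulate_ensemble

__all__ = [
    "render_model",
    "parse_sim_table",
    "dispatch",
    "BuiltinSSABackend",
    "CommandBackend",
    "SlurmAdapter",
    "TemplatingError",
    "ParseError",
]

PLACEHOLDER = re.compile(r"__FREE__([A-Za-z_]\w*)")


class TemplatingError(ValueError):
    """Placeholder inventory and parameter assignment disagree."""


class ParseError(ValueError):
    """A simulator output table could not be parsed."""


def render_model(template: str, assignment: Mapping[str, float]) -> str:
    """Substitute every ``__FREE__<name>`` placeholder with its value.

    Values are written in scientific notation at 17 significant digits (the
    exact decimal of the binary double), so the simulator sees precisely the
    calibrated value.  Unknown placeholders and unused assignments are both
    errors, listed by name.
    """
    found = set(PLACEHOLDER.findall(template))
    missing = sorted(found - set(assignment))
    unused = sorted(set(assignment) - found)
    if missing or unused:
        raise TemplatingError(
            f"template/assignment mismatch: missing value for {missing}, "
            f"unused assignment {unused}"
        )

    def _sub(match: re.Match) -> str:
        return np.format_float_scientific(
            float(assignment[match.group(1)]), precision=16, unique=False
        )

    return PLACEHOLDER.sub(_sub, template)


def parse_sim_table(text: str, dialect: str = "tsv"):
    """Parse one simulator output table into (times, observables, values).

    Dialects: ``gdat`` (whitespace-separated, header line starting with
    ``#``, first column time), ``kasim_csv`` (comma-separated, possibly
    quoted header, first column the time tracker), ``tsv`` (plain
    tab-separated header + time column).  Returns ``times`` (T,), the
    observable names and a (T, V) value matrix.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty simulator output")
    if dialect == "gdat":
        header = lines[0]
        if not header.lstrip().startswith("#"):
            raise ParseError("gdat header must start with '#' (line 1)")
        columns = header.lstrip("#").split()
        splitter: Callable[[str], list[str]] = str.split
        body = lines[1:]
    elif dialect == "kasim_csv":
        columns = [c.strip().strip("'\"") for c in lines[0].lstrip("#").split(",")]
        splitter = lambda ln: [f.strip().strip("'\"") for f in ln.split(",")]  # noqa: E731
        body = lines[1:]
    elif dialect == "tsv":
        columns = lines[0].split("\t")
        splitter = lambda ln: ln.split("\t")  # noqa: E731
        body = lines[1:]
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    if len(columns) < 2:
        raise ParseError("need a time column and at least one observable (line 1)")
    rows = []
    for lineno, ln in enumerate(body, start=2):
        fields = splitter(ln)
        if len(fields) != len(columns):
            raise ParseError(
                f"line {lineno}: {len(fields)} fields under a {len(columns)}-column header"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from exc
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ParseError("no data rows")
    return arr[:, 0], tuple(columns[1:]), arr[:, 1:]


# ---------------------------------------------------------------------------
# dispatch


def dispatch(
    fn: Callable,
    jobs: Sequence,
    workers: int = 1,
    fail_fast: bool = False,
) -> list[tuple[bool, object]]:
    """Run ``fn`` over ``jobs``; results in batch order as (ok, value | exception).

    ``workers=1`` is exactly serial execution.  A failing job yields
    ``(False, exception)`` and the batch continues unless ``fail_fast``.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    results: list[tuple[bool, object]] = []
    if workers == 1 or len(jobs) <= 1:
        for job in jobs:
            try:
                results.append((True, fn(job)))
            except Exception as exc:  # noqa: BLE001 - sentinel per contract
                if fail_fast:
                    raise
                results.append((False, exc))
        return results
    import multiprocessing as mp

    with mp.get_context("spawn").Pool(workers) as pool:
        for ok_exc in pool.map(_Guard(fn, fail_fast), jobs):
            results.append(ok_exc)
    if fail_fast:
        for ok, val in results:
            if not ok:
                raise val  # type: ignore[misc]
    return results


class _Guard:
    """Wrap a job function so worker exceptions travel back as values."""

    def __init__(self, fn: Callable, fail_fast: bool):
        self.fn = fn
        self.fail_fast = fail_fast

    def __call__(self, job):
        try:
            return True, self.fn(job)
        except Exception as exc:  # noqa: BLE001
            return False, exc


# ---------------------------------------------------------------------------
# backends


@dataclass(frozen=True)
class BuiltinSSABackend:
    """In-process Gillespie backend over a mass-action network."""

    network: ReactionNetwork
    max_events: int = 1_000_000

    def simulate(
        self, assignment: Mapping[str, float], n_sims: int,
        times: Sequence[float], seed: int,
    ) -> SimulationEnsemble:
        net = self.network.with_parameters(assignment)
        return simulate_ensemble(net, n_sims, times, seed, max_events=self.max_events)


@dataclass(frozen=True)
class CommandBackend:
    """External-simulator adapter: render model, invoke command, parse output.

    ``command`` is a template with ``{model}``, ``{seed}`` and ``{output}``
    slots, executed once per stochastic run.  The parsed trajectory is
    aligned to the experimental grid by exact time matching (simulators are
    required to emit the experimental time points).
    """

    command: str
    model_template: str
    output_dialect: str = "gdat"
    observables: tuple[str, ...] | None = None
    align_tol: float = 1e-9

    @property
    def available(self) -> bool:
        exe = self.command.split()[0]
        return shutil.which(exe) is not None

    def simulate(
        self, assignment: Mapping[str, float], n_sims: int,
        times: Sequence[float], seed: int,
    ) -> SimulationEnsemble:
        times = np.asarray(times, dtype=float)
        model_text = render_model(self.model_template, assignment)
        run_seeds = np.random.SeedSequence(int(seed)).generate_state(n_sims, dtype=np.uint32)
        runs = []
        with tempfile.TemporaryDirectory(prefix="kinecal_") as tmp:
            model_path = Path(tmp) / "model.txt"
            model_path.write_text(model_text)
            for j, rs in enumerate(run_seeds):
                out_path = Path(tmp) / f"run_{j}.out"
                cmd = self.command.format(model=model_path, seed=int(rs), output=out_path)
                proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
                if proc.returncode != 0:
                    raise RuntimeError(
                        f"simulator exited with {proc.returncode}: {proc.stderr.strip()}"
                    )
                t, obs, vals = parse_sim_table(out_path.read_text(), self.output_dialect)
                if self.observables is not None:
                    keep = [obs.index(o) for o in self.observables]
                    obs = tuple(self.observables)
                    vals = vals[:, keep]
                ens = SimulationEnsemble(obs, t, vals[None, :, :])
                runs.append(align_to_times(ens, times, self.align_tol).values[0])
        return SimulationEnsemble(obs, times, np.stack(runs))


@dataclass(frozen=True)
class SlurmAdapter:
    """Interface stub for cluster dispatch.

    The contract a real integration must honour: render one submission per
    job from ``submit_template`` (slots ``{command}``, ``{job_name}``),
    submit with ``sbatch``, poll ``squeue``/``sacct`` until completion, then
    collect outputs keyed by job identity.  This stub only documents the
    contract; calling :meth:`dispatch` raises.
    """

    submit_template: str = "sbatch --wrap '{command}' --job-name {job_name}"
    poll_seconds: float = 5.0

    @property
    def available(self) -> bool:
        return False

    def dispatch(self, fn, jobs, workers: int = 1):
        raise NotImplementedError(
            "SLURM dispatch is an interface stub; use kinecal.orchestration.dispatch "
            "with a local worker pool instead"
        )
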