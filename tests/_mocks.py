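"""Shared deterministic mock backends for fast GA-level tests."""

import numpy as np

from kinecal.data import ExperimentalData, SimulationEnsemble


class ConstantCurveBackend:
    """Deterministic mock: each observable's value equals one parameter,
    constant in time and across runs.  SDA then has a unique optimum at the
    data means, making convergence assertions exact."""

    def __init__(self, n_obs=2):
        self.n_obs = n_obs

    def simulate(self, assignment, n_sims, times, seed):
        vals = np.array([assignment[f"p{i}"] for i in range(self.n_obs)])
        tensor = np.tile(vals, (n_sims, len(times), 1))
        obs = tuple(f"x{i}" for i in range(self.n_obs))
        return SimulationEnsemble(obs, times, tensor)


def make_dataset(targets, times=(0.0, 1.0, 2.0), m=3):
    targets = np.asarray(targets, dtype=float)
    vals = np.tile(targets, (m, len(times), 1))
    obs = tuple(f"x{i}" for i in range(targets.size))
    return ExperimentalData(obs, np.asarray(times), vals)
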