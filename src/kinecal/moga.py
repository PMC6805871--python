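"""Multi-objective combination by unweighted sum of per-objective ranks.

Each objective is ranked ascending (minimisation, ties share the minimum
"competition" rank) and an individual's combined score is the plain sum of
its ranks — no weights, no Pareto archiving.  With a single objective this
reduces exactly to that objective's ranking.  The correlation diagnostic
helps pick non-redundant objective bundles: strongly correlated objectives
add little to a combined search.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "sum_of_ranks",
    "rank_order",
    "objective_correlation",
    "PRESET_OBJECTIVE_BUNDLES",
]

#: named multi-objective bundles selected for low mutual correlation
PRESET_OBJECTIVE_BUNDLES: dict[str, tuple[str, ...]] = {
    "duo": ("CHISQ", "WMWET"),
    "trio": ("ANPWSD", "WMWET", "PWSD"),
    "quartet": ("CHISQ", "WMWET", "SDA", "NPWSD"),
}


def sum_of_ranks(fitness_matrix: np.ndarray) -> np.ndarray:
    """Combined score per individual: sum of ascending per-objective ranks.

    ``fitness_matrix`` has shape (individuals, objectives); every objective
    is minimised.  Ties share the minimum rank.  Non-finite entries
    (failed-simulation sentinels) rank last in their objective.
    """
    fm = np.asarray(fitness_matrix, dtype=float)
    if fm.ndim != 2 or fm.size == 0:
        raise ValueError("fitness matrix must be non-empty and 2-d")
    ranks = np.column_stack([rankdata(fm[:, k], method="min") for k in range(fm.shape[1])])
    return ranks.sum(axis=1).astype(float)


def rank_order(fitness_matrix: np.ndarray, ids: np.ndarray | None = None) -> np.ndarray:
    """Indices that sort individuals by combined score, ties broken by id."""
    combined = sum_of_ranks(fitness_matrix)
    if ids is None:
        ids = np.arange(combined.size)
    return np.lexsort((np.asarray(ids), combined))


def objective_correlation(
    fitness_matrix: np.ndarray,
    objective_names: list[str] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Objective x objective correlation matrix (pearson, spearman or kendall).

    Zero-variance objective columns yield undefined correlations, reported
    as NaN with a warning.
    """
    fm = np.asarray(fitness_matrix, dtype=float)
    if fm.ndim != 2 or fm.shape[0] < 3:
        raise ValueError("need at least 3 individuals for a correlation matrix")
    if not np.all(np.isfinite(fm)):
        raise ValueError("fitness matrix must be finite for correlation analysis")
    if method not in ("pearson", "spearman", "kendall"):
        raise ValueError(f"unknown correlation method {method!r}")
    names = objective_names or [f"obj{k}" for k in range(fm.shape[1])]
    df = pd.DataFrame(fm, columns=names)
    constant = [c for c in names if df[c].nunique() == 1]
    if constant:
        warnings.warn(f"zero-variance objective(s) {constant}: correlations undefined",
                      stacklevel=2)
    corr = df.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr
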