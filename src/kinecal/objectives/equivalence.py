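"""Iterative equivalence tests: TOST, Double Mann-Whitney U-test, Wellek's test.

A difference test asks whether two samples differ; an equivalence test asks
whether they differ by LESS than a stated margin.  Calibration of stochastic
models benefits from the latter: a candidate is good when its simulations are
*equivalent* to the replicated data at every observable and timepoint.

Each test yields one boolean verdict per (observable, timepoint) cell; the
verdicts form a rejection matrix and the fitness is the count of cells where
equivalence was NOT established.  A perfect model scores 0 and a completely
wrong one scores V*T (number of observables times timepoints), so the score
is a discrete minimisable objective with known bounds.

Test constructions
------------------
TOST   two one-sided Welch t-tests: shift the simulated sample down and up by
       the margin eps and require BOTH one-sided tests to reject (shifted-down
       sample significantly below the data AND shifted-up sample significantly
       above it).
DUT    the nonparametric analogue built from two one-sided Mann-Whitney U
       tests on the margin-shifted samples (exact null distribution for
       m*n <= 400, tie/continuity-corrected normal approximation beyond).
WMWET  Wellek's Mann-Whitney equivalence test: is pi = P(sim > exp) inside a
       probability band around 1/2?  Uses the U-statistic variance estimate
       from pair/triple concordance and a critical bound from the alpha
       quantile of the noncentral chi-squared distribution with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from ..data import ExperimentalData, SimulationEnsemble, check_aligned

__all__ = [
    "EQUIVALENCE_NAMES",
    "EquivalenceSettings",
    "RejectionMatrix",
    "InsufficientReplicatesError",
    "tost_cell",
    "dut_counts",
    "dut_cell",
    "wmwet_cell",
    "build_rejection_matrix",
    "iterative_score",
]

EQUIVALENCE_NAMES = ("TOST", "DUT", "WMWET")


class InsufficientReplicatesError(ValueError):
    """The test needs at least two values on each side."""


@dataclass(frozen=True)
class EquivalenceSettings:
    """Configuration of one equivalence test.

    ``range_mode='sd_multiple'`` takes the margin as ``range_value`` sample
    standard deviations of the experimental replicates of each cell (default
    one SD); ``'absolute'`` uses ``range_value`` directly.  ``band`` is the
    (p_lo, p_hi) equivalence band on P(sim > exp) for WMWET.
    """

    test: str = "TOST"
    alpha: float = 0.05
    range_mode: str = "sd_multiple"
    range_value: float = 1.0
    band: tuple[float, float] = (0.19, 0.76)

    def __post_init__(self):
        if self.test not in EQUIVALENCE_NAMES:
            raise ValueError(f"unknown equivalence test {self.test!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.range_mode not in ("sd_multiple", "absolute"):
            raise ValueError("range_mode must be 'sd_multiple' or 'absolute'")
        if self.range_value < 0:
            raise ValueError("equivalence range must be non-negative")
        lo, hi = self.band
        if not (0.0 < lo < 0.5 < hi < 1.0):
            raise ValueError("band must satisfy 0 < p_lo < 0.5 < p_hi < 1")


@dataclass(frozen=True)
class RejectionMatrix:
    """Observable x timepoint grid of verdicts; True = equivalence NOT established."""

    observables: tuple[str, ...]
    times: np.ndarray
    failed: np.ndarray          # (V, T) boolean
    untestable: np.ndarray      # (V, T) boolean; untestable cells also count as failed

    @property
    def n_cells(self) -> int:
        return int(self.failed.size)

    @property
    def n_failed(self) -> int:
        return int(self.failed.sum())


def iterative_score(mat: RejectionMatrix) -> int:
    """Count of cells where equivalence was not established (0 = perfect model)."""
    return mat.n_failed


# ---------------------------------------------------------------------------
# TOST


def _welch_one_sided_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """One-sided p-value of the Welch (unequal-variance) two-sample t-test.

    ``alternative='less'`` tests H1: mean(a) < mean(b).
    Degenerate dispersion (both samples constant) yields p = 0 when the means
    are strictly ordered per the alternative, else p = 1.
    """
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    delta = a.mean() - b.mean()
    if se2 == 0.0:
        ordered = delta < 0 if alternative == "less" else delta > 0
        return 0.0 if ordered else 1.0
    t = delta / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(stats.t.cdf(t, df) if alternative == "less" else stats.t.sf(t, df))


def tost_cell(exp: np.ndarray, sim: np.ndarray, epsilon: float, alpha: float = 0.05) -> bool:
    """Two one-sided t-tests on one cell; True when equivalence is established.

    The simulated sample is shifted down and up by ``epsilon``; equivalence
    holds only when the down-shifted sample tests significantly smaller than
    the data AND the up-shifted sample tests significantly larger, both
    one-sided Welch t-tests at level ``alpha``.  A zero margin can never
    declare equivalence.
    """
    exp = np.asarray(exp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if exp.size < 2 or sim.size < 2:
        raise InsufficientReplicatesError("TOST requires m >= 2 and n >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    p_lower = _welch_one_sided_p(sim - epsilon, exp, "less")
    p_upper = _welch_one_sided_p(sim + epsilon, exp, "greater")
    return p_lower <= alpha and p_upper <= alpha


# ---------------------------------------------------------------------------
# DUT


def dut_counts(exp: np.ndarray, shifted_sim: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney counting step: how often experimental values exceed the
    shifted simulated values (ties weighted 0.5 per pair).

    Returns (U_exp, U_sims) with U_exp + U_sims = m*n exactly.
    """
    exp = np.asarray(exp, dtype=float)
    shifted_sim = np.asarray(shifted_sim, dtype=float)
    diff = exp[:, None] - shifted_sim[None, :]
    u_exp = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    return u_exp, exp.size * shifted_sim.size - u_exp


@lru_cache(maxsize=64)
def _u_null_sf(m: int, n: int) -> np.ndarray:
    """Exact null survival function of the Mann-Whitney U statistic.

    ``sf[u] = P(U >= u)`` for u = 0..mn under the no-tie null, computed from
    the standard recurrence for the number of arrangements with a given U.
    """
    # Gaussian-binomial DP: counts[u] = number of merge orderings with U = u,
    # i.e. partitions of u into at most n parts each <= m
    dp = np.zeros((n + 1, m * n + 1))
    dp[0, 0] = 1.0
    for parts in range(1, n + 1):
        for u in range(m * n + 1):
            dp[parts, u] = dp[parts - 1, u]
            if u >= parts:
                dp[parts, u] += dp[parts, u - parts]
            if u >= parts + m:
                dp[parts, u] -= dp[parts - 1, u - parts - m]
    counts = dp[n]
    sf = np.cumsum(counts[::-1])[::-1] / counts.sum()
    return sf


def _u_one_sided_p(u: float, m: int, n: int) -> float:
    """P(U >= u) under the null; exact for m*n <= 400, else normal approximation
    with continuity correction."""
    mn = m * n
    if mn <= 400:
        sf = _u_null_sf(m, n)
        k = int(np.ceil(u - 1e-12))
        k = min(max(k, 0), mn)
        return float(sf[k])
    mu = mn / 2.0
    sigma = np.sqrt(mn * (m + n + 1) / 12.0)
    return float(stats.norm.sf((u - mu - 0.5) / sigma))


def dut_cell(exp: np.ndarray, sim: np.ndarray, epsilon: float, alpha: float = 0.05) -> bool:
    """Double Mann-Whitney U-test on one cell; True when equivalent.

    Equivalence requires the data to test stochastically greater than the
    down-shifted simulations AND stochastically smaller than the up-shifted
    simulations, both one-sided U-tests at level ``alpha``.
    """
    exp = np.asarray(exp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if exp.size < 2 or sim.size < 2:
        raise InsufficientReplicatesError("DUT requires m >= 2 and n >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    m, n = exp.size, sim.size
    u_exp_down, _ = dut_counts(exp, sim - epsilon)       # exp above down-shifted sims
    _, u_sims_up = dut_counts(exp, sim + epsilon)        # up-shifted sims above exp
    p_down = _u_one_sided_p(u_exp_down, m, n)
    p_up = _u_one_sided_p(u_sims_up, m, n)
    return p_down <= alpha and p_up <= alpha


# ---------------------------------------------------------------------------
# WMWET (Wellek's Mann-Whitney equivalence test)


def _wellek_statistics(sim: np.ndarray, exp: np.ndarray) -> tuple[float, float]:
    """(pi_hat, sigma_hat) of Wellek's construction with X = sim, Y = exp.

    pi_hat estimates P(sim > exp) (ties weighted 1/2); sigma_hat is the
    square root of the U-statistic variance estimate built from the triple
    concordance probabilities P(X1>Y, X2>Y) and P(X>Y1, X>Y2).
    """
    n, m = sim.size, exp.size
    h = np.where(sim[:, None] > exp[None, :], 1.0,
                 np.where(sim[:, None] == exp[None, :], 0.5, 0.0))  # (n, m)
    pi_hat = float(h.mean())
    col = h.sum(axis=0)   # per exp value: how many sims above it
    row = h.sum(axis=1)   # per sim value: how many exps below it
    pi_xxy = float(((col**2 - (h**2).sum(axis=0)).sum()) / (n * (n - 1) * m))
    pi_xyy = float(((row**2 - (h**2).sum(axis=1)).sum()) / (n * m * (m - 1)))
    var = (pi_hat - (m + n - 1) * pi_hat**2 + (n - 1) * pi_xxy + (m - 1) * pi_xyy) / (m * n)
    return pi_hat, float(np.sqrt(max(var, 0.0)))


def wmwet_cell(
    exp: np.ndarray,
    sim: np.ndarray,
    band: tuple[float, float] = (0.19, 0.76),
    alpha: float = 0.05,
) -> bool:
    """Wellek's nonparametric equivalence test on one cell; True when equivalent.

    Declares equivalence when the standardised distance of pi_hat from the
    band centre falls below the critical bound sqrt of the alpha quantile of
    the noncentral chi-squared distribution with 1 df and noncentrality
    ((p_hi - p_lo) / (2 sigma_hat))^2.  With zero dispersion the verdict
    degenerates to whether pi_hat lies strictly inside the band.
    """
    exp = np.asarray(exp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if exp.size < 2 or sim.size < 2:
        raise InsufficientReplicatesError("WMWET requires m >= 2 and n >= 2")
    p_lo, p_hi = band
    if not (0.0 < p_lo < 0.5 < p_hi < 1.0):
        raise ValueError("band must satisfy 0 < p_lo < 0.5 < p_hi < 1")
    pi_hat, sigma_hat = _wellek_statistics(sim, exp)
    centre = 0.5 * (p_lo + p_hi)
    halfwidth = 0.5 * (p_hi - p_lo)
    if sigma_hat == 0.0:
        return bool(p_lo < pi_hat < p_hi)
    ncp = (halfwidth / sigma_hat) ** 2
    crit = np.sqrt(stats.ncx2.ppf(alpha, df=1, nc=ncp))
    if not np.isfinite(crit):
        # large-noncentrality limit of the noncentral chi-square quantile
        crit = max(np.sqrt(ncp) + stats.norm.ppf(alpha), 0.0)
    return bool(abs(pi_hat - centre) / sigma_hat < crit)


# ---------------------------------------------------------------------------
# rejection matrix


def _cell_margin(exp: np.ndarray, settings: EquivalenceSettings) -> float:
    if settings.range_mode == "absolute":
        return settings.range_value
    if exp.size < 2:
        raise InsufficientReplicatesError("sd-based margin needs >= 2 replicates")
    return settings.range_value * float(np.asarray(exp, dtype=float).std(ddof=1))


def build_rejection_matrix(
    settings: EquivalenceSettings,
    data: ExperimentalData,
    sims: SimulationEnsemble,
    method: str = "vectorized",
) -> RejectionMatrix:
    """Run the configured test on every (observable, timepoint) cell.

    Untestable cells (too few replicates for the test or for an sd-based
    margin) are recorded as such and count as failed, preserving the score's
    upper bound V*T.  ``method='cell'`` evaluates the per-cell functions in
    a plain loop; ``'vectorized'`` computes the identical verdicts over the
    whole grid at once (regression-tested equal).
    """
    check_aligned(data, sims)
    if method == "vectorized" and data.m >= 2 and sims.n >= 2:
        return _build_rejection_matrix_vectorized(settings, data, sims)
    V, T = len(data.observables), data.times.size
    failed = np.zeros((V, T), dtype=bool)
    untestable = np.zeros((V, T), dtype=bool)
    for v in range(V):
        for t in range(T):
            exp = data.values[:, t, v]
            sim = sims.values[:, t, v]
            try:
                if settings.test == "WMWET":
                    ok = wmwet_cell(exp, sim, settings.band, settings.alpha)
                else:
                    eps = _cell_margin(exp, settings)
                    if settings.test == "TOST":
                        ok = tost_cell(exp, sim, eps, settings.alpha)
                    else:
                        ok = dut_cell(exp, sim, eps, settings.alpha)
                failed[v, t] = not ok
            except InsufficientReplicatesError:
                failed[v, t] = True
                untestable[v, t] = True
    if untestable.any():
        warnings.warn(
            f"{int(untestable.sum())} untestable cell(s) counted as failed",
            stacklevel=2,
        )
    return RejectionMatrix(data.observables, data.times, failed, untestable)


def _build_rejection_matrix_vectorized(
    settings: EquivalenceSettings,
    data: ExperimentalData,
    sims: SimulationEnsemble,
) -> RejectionMatrix:
    """Whole-grid evaluation; verdict-identical to the per-cell loop."""
    exp = np.moveaxis(data.values, 0, 2)    # (T, V, m)
    sim = np.moveaxis(sims.values, 0, 2)    # (T, V, n)
    m, n = data.m, sims.n
    alpha = settings.alpha
    if settings.test == "TOST":
        mean_e, mean_s = exp.mean(axis=2), sim.mean(axis=2)
        var_e, var_s = exp.var(axis=2, ddof=1), sim.var(axis=2, ddof=1)
        eps = (settings.range_value * np.sqrt(var_e)
               if settings.range_mode == "sd_multiple" else
               np.full_like(mean_e, settings.range_value))
        delta = mean_s - mean_e
        se2 = var_s / n + var_e / m
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((var_s / n) ** 2 / (n - 1) + (var_e / m) ** 2 / (m - 1))
            se = np.sqrt(se2)
            p_lo = stats.t.cdf((delta - eps) / se, df)
            p_hi = stats.t.sf((delta + eps) / se, df)
        ok = (p_lo <= alpha) & (p_hi <= alpha)
        degenerate = se2 == 0.0
        ok = np.where(degenerate, np.abs(delta) < eps, ok)
        failed = ~ok
    elif settings.test == "DUT":
        var_e = exp.var(axis=2, ddof=1)
        eps = (settings.range_value * np.sqrt(var_e)
               if settings.range_mode == "sd_multiple" else
               np.full(exp.shape[:2], settings.range_value))
        d_down = exp[:, :, :, None] - (sim[:, :, None, :] - eps[:, :, None, None])
        u_down = (d_down > 0).sum(axis=(2, 3)) + 0.5 * (d_down == 0).sum(axis=(2, 3))
        d_up = exp[:, :, :, None] - (sim[:, :, None, :] + eps[:, :, None, None])
        u_up = (d_up < 0).sum(axis=(2, 3)) + 0.5 * (d_up == 0).sum(axis=(2, 3))
        if m * n <= 400:
            sf = _u_null_sf(m, n)
            k_down = np.clip(np.ceil(u_down - 1e-12).astype(int), 0, m * n)
            k_up = np.clip(np.ceil(u_up - 1e-12).astype(int), 0, m * n)
            p_down, p_up = sf[k_down], sf[k_up]
        else:
            mu = m * n / 2.0
            sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
            p_down = stats.norm.sf((u_down - mu - 0.5) / sigma)
            p_up = stats.norm.sf((u_up - mu - 0.5) / sigma)
        failed = ~((p_down <= alpha) & (p_up <= alpha))
    else:  # WMWET
        h = np.where(sim[:, :, :, None] > exp[:, :, None, :], 1.0,
                     np.where(sim[:, :, :, None] == exp[:, :, None, :], 0.5, 0.0))
        pi_hat = h.mean(axis=(2, 3))
        col = h.sum(axis=2)          # (T, V, m)
        row = h.sum(axis=3)          # (T, V, n)
        h2 = h**2
        pi_xxy = (col**2 - h2.sum(axis=2)).sum(axis=2) / (n * (n - 1) * m)
        pi_xyy = (row**2 - h2.sum(axis=3)).sum(axis=2) / (n * m * (m - 1))
        var = (pi_hat - (m + n - 1) * pi_hat**2 + (n - 1) * pi_xxy
               + (m - 1) * pi_xyy) / (m * n)
        sigma_hat = np.sqrt(np.maximum(var, 0.0))
        p_lo, p_hi = settings.band
        centre, halfwidth = 0.5 * (p_lo + p_hi), 0.5 * (p_hi - p_lo)
        ok = np.zeros_like(pi_hat, dtype=bool)
        degenerate = sigma_hat == 0.0
        ok[degenerate] = (p_lo < pi_hat[degenerate]) & (pi_hat[degenerate] < p_hi)
        if (~degenerate).any():
            s = sigma_hat[~degenerate]
            ncp = (halfwidth / s) ** 2
            with np.errstate(over="ignore"):
                crit = np.sqrt(stats.ncx2.ppf(alpha, 1, ncp))
            bad = ~np.isfinite(crit)
            crit[bad] = np.maximum(np.sqrt(ncp[bad]) + stats.norm.ppf(alpha), 0.0)
            ok[~degenerate] = np.abs(pi_hat[~degenerate] - centre) / s < crit
        failed = ~ok
    return RejectionMatrix(
        data.observables, data.times, np.ascontiguousarray(failed.T),
        np.zeros((len(data.observables), data.times.size), dtype=bool),
    )
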