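"""Equivalence tests: verdicts against independent oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from kinecal.data import ExperimentalData, SimulationEnsemble
from kinecal.objectives.equivalence import (
    EquivalenceSettings,
    InsufficientReplicatesError,
    build_rejection_matrix,
    dut_cell,
    dut_counts,
    iterative_score,
    tost_cell,
    wmwet_cell,
)


def wellek_reference(exp, sim, band, alpha):
    """Independent brute-force evaluation of Wellek's Mann-Whitney equivalence
    test: plain triple loops over the pair/triple concordance indicators and
    the noncentral chi-squared critical bound.  Shares no code with the
    package implementation."""
    x = [float(v) for v in sim]   # X = simulated
    y = [float(v) for v in exp]   # Y = experimental
    n, m = len(x), len(y)

    def h(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    w = sum(h(xi, yj) for xi in x for yj in y) / (n * m)
    pi_xxy = sum(
        h(x[i1], y[j]) * h(x[i2], y[j])
        for i1 in range(n) for i2 in range(n) if i1 != i2 for j in range(m)
    ) / (n * (n - 1) * m)
    pi_xyy = sum(
        h(x[i], y[j1]) * h(x[i], y[j2])
        for i in range(n) for j1 in range(m) for j2 in range(m) if j1 != j2
    ) / (n * m * (m - 1))
    var = (w - (m + n - 1) * w**2 + (n - 1) * pi_xxy + (m - 1) * pi_xyy) / (m * n)
    sigma = max(var, 0.0) ** 0.5
    p_lo, p_hi = band
    if sigma == 0.0:
        return p_lo < w < p_hi
    ncp = ((p_hi - p_lo) / (2 * sigma)) ** 2
    crit = float(np.sqrt(stats.ncx2.ppf(alpha, 1, ncp)))
    return abs(w - (p_lo + p_hi) / 2) / sigma < crit


class TestTOST:
    def test_identical_tight_samples_equivalent(self):
        e = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        assert tost_cell(e, e, epsilon=0.5, alpha=0.05)

    def test_large_shift_not_equivalent(self):
        e = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        assert not tost_cell(e, e + 10.0, epsilon=0.5, alpha=0.05)

    def test_zero_margin_never_equivalent(self):
        e = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        assert not tost_cell(e, e, epsilon=0.0, alpha=0.05)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            tost_cell([1.0], [1.0, 2.0], 0.5)

    def test_matches_statsmodels_ttost(self, rng):
        """Verdict equals statsmodels' unequal-variance TOST at the same level."""
        ttost_ind = pytest.importorskip("statsmodels.stats.weightstats").ttost_ind
        for _ in range(50):
            exp = rng.normal(10, 1, rng.integers(3, 12))
            sim = rng.normal(10 + rng.normal(0, 1), 1, rng.integers(3, 12))
            eps = rng.uniform(0.1, 3.0)
            p, _, _ = ttost_ind(sim, exp, -eps, eps, usevar="unequal")
            assert tost_cell(exp, sim, eps, 0.05) == (p <= 0.05)

    def test_translation_invariance(self, rng):
        exp = rng.normal(50, 4, 8)
        sim = rng.normal(51, 4, 9)
        for shift in (-17.3, 0.0, 1234.5):
            assert tost_cell(exp, sim, 2.0) == tost_cell(exp + shift, sim + shift, 2.0)


class TestDUT:
    @pytest.mark.parametrize(
        "exp, sim, expected",
        [([3, 5], [4], (1.0, 1.0)), ([4], [4], (0.5, 0.5)), ([5, 6], [1, 2], (4.0, 0.0))],
    )
    def test_counting_examples(self, exp, sim, expected):
        assert dut_counts(np.array(exp, float), np.array(sim, float)) == expected

    def test_counts_sum_to_mn(self, rng):
        for _ in range(50):
            exp = rng.integers(0, 5, rng.integers(1, 9)).astype(float)
            sim = rng.integers(0, 5, rng.integers(1, 9)).astype(float)
            u_exp, u_sims = dut_counts(exp, sim)
            assert u_exp + u_sims == exp.size * sim.size

    def test_identical_samples_equivalent_at_one_sd(self):
        exp = np.array([10, 11, 9, 10.5, 9.5, 10.2, 9.8, 10.1, 9.9, 10.0])
        eps = exp.std(ddof=1)
        assert dut_cell(exp, exp.copy(), eps, 0.05)

    def test_separation_beyond_margin_not_equivalent(self):
        exp = np.array([10, 11, 9, 10.5, 9.5, 10.2, 9.8, 10.1, 9.9, 10.0])
        assert not dut_cell(exp, exp + 100.0, 1.0, 0.05)

    def test_verdict_matches_scipy_exact_u_tests(self, rng):
        """On tie-free data the verdict is exactly two scipy one-sided exact
        U-tests on the shifted samples."""
        for _ in range(30):
            exp = rng.normal(20, 2, 8)
            sim = rng.normal(20 + rng.normal(0, 1), 2, 9)
            eps = rng.uniform(0.5, 5.0)
            p_down = stats.mannwhitneyu(exp, sim - eps, alternative="greater",
                                        method="exact").pvalue
            p_up = stats.mannwhitneyu(sim + eps, exp, alternative="greater",
                                      method="exact").pvalue
            assert dut_cell(exp, sim, eps, 0.05) == (p_down <= 0.05 and p_up <= 0.05)

    def test_u_ceiling(self):
        u_exp, u_sims = dut_counts(np.arange(10) + 100.0, np.arange(10.0))
        assert u_exp == 100.0 and u_sims == 0.0


class TestWMWET:
    #: fixed tie-free vector pairs cross-validating the port against the
    #: independent reference construction
    FIXED_PAIRS = [
        (np.array([1, 3, 5, 7, 9, 11, 13, 15, 17, 19.0]),
         np.array([2, 4, 6, 8, 10, 12, 14, 16, 18, 20.0])),
        (np.array([10.2, 9.8, 10.5, 9.5, 10.1, 9.9, 10.3, 9.7]),
         np.array([10.4, 9.6, 10.0, 10.6, 9.4, 10.05, 9.95, 10.15])),
        (np.array([5.1, 6.2, 4.8, 5.5, 5.9, 6.05]),
         np.array([8.1, 9.2, 7.8, 8.5, 8.9, 9.05])),
        (np.array([100.0, 102.0, 98.0, 101.0, 99.0]),
         np.array([100.5, 101.5, 98.5, 100.25, 99.75, 100.75])),
        (np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5]),
         np.array([6.0, 7.0, 8.0, 1.0, 2.0, 3.0, 4.0, 5.0])),
        (np.array([3.0, 3.1, 2.9, 3.05, 2.95, 3.2, 2.8, 3.15, 2.85, 3.02]),
         np.array([3.4, 3.5, 3.3, 3.45, 3.35, 3.6, 3.25, 3.55, 3.28, 3.42])),
    ]

    @pytest.mark.parametrize("pair_index", range(len(FIXED_PAIRS)))
    def test_port_reproduces_reference_verdicts(self, pair_index):
        exp, sim = self.FIXED_PAIRS[pair_index]
        band, alpha = (0.19, 0.76), 0.05
        assert wmwet_cell(exp, sim, band, alpha) == wellek_reference(exp, sim, band, alpha)

    def test_reference_agreement_on_random_cells(self, rng):
        agree = 0
        for _ in range(40):
            exp = rng.normal(10, 1, rng.integers(4, 10))
            sim = rng.normal(10 + rng.normal(0, 0.5), 1, rng.integers(4, 10))
            got = wmwet_cell(exp, sim, (0.19, 0.76), 0.05)
            assert got == wellek_reference(exp, sim, (0.19, 0.76), 0.05)
            agree += 1
        assert agree == 40

    def test_complete_separation_not_equivalent(self):
        exp = np.arange(10.0)
        assert not wmwet_cell(exp, exp + 100.0, (0.19, 0.76), 0.05)

    def test_degenerate_constant_vectors_equivalent(self):
        v = np.full(6, 3.0)
        assert wmwet_cell(v, v.copy(), (0.19, 0.76), 0.05)


class TestRejectionMatrix:
    def _containers(self, rng, V=10, T=10, offset=0.0):
        times = np.arange(float(T))
        obs = tuple(f"v{k}" for k in range(V))
        data = ExperimentalData(obs, times, rng.normal(50, 5, (10, T, V)))
        sims = SimulationEnsemble(
            obs, times, np.abs(rng.normal(50 + offset, 5, (10, T, V))))
        return data, sims

    def test_grid_has_one_cell_per_observable_timepoint(self, rng):
        data, sims = self._containers(rng)
        mat = build_rejection_matrix(EquivalenceSettings(test="TOST"), data, sims)
        assert mat.n_cells == 100

    def test_score_bounds_all_pass_and_all_fail(self, rng):
        data, sims = self._containers(rng)
        generous = EquivalenceSettings(test="TOST", range_mode="absolute",
                                       range_value=1e6)
        assert iterative_score(build_rejection_matrix(generous, data, sims)) == 0
        hopeless_data, hopeless_sims = self._containers(rng, offset=1e5)
        tight = EquivalenceSettings(test="TOST", range_mode="absolute",
                                    range_value=1e-12)
        assert iterative_score(
            build_rejection_matrix(tight, hopeless_data, hopeless_sims)) == 100

    @pytest.mark.parametrize("test", ["TOST", "DUT", "WMWET"])
    def test_vectorized_equals_per_cell_loop(self, rng, test):
        for offset in (0.0, 3.0):
            data, sims = self._containers(rng, V=3, T=5, offset=offset)
            st = EquivalenceSettings(test=test)
            a = build_rejection_matrix(st, data, sims, method="cell").failed
            b = build_rejection_matrix(st, data, sims, method="vectorized").failed
            np.testing.assert_array_equal(a, b)

    def test_invariant_under_observable_permutation(self, rng):
        data, sims = self._containers(rng, V=4, T=6, offset=1.0)
        st = EquivalenceSettings(test="TOST")
        direct = build_rejection_matrix(st, data, sims).failed
        perm = [2, 0, 3, 1]
        data_p = ExperimentalData(tuple(data.observables[i] for i in perm),
                                  data.times, data.values[:, :, perm])
        sims_p = SimulationEnsemble(data_p.observables, sims.times,
                                    sims.values[:, :, perm])
        permuted = build_rejection_matrix(st, data_p, sims_p).failed
        np.testing.assert_array_equal(direct[perm, :], permuted)

    def test_margin_widening_is_monotone(self, rng):
        """Widening epsilon never increases the score on fixed data/sims."""
        data, sims = self._containers(rng, V=2, T=8, offset=2.0)
        for test in ("TOST", "DUT"):
            scores = []
            for k in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
                st = EquivalenceSettings(test=test, range_value=k)
                scores.append(iterative_score(build_rejection_matrix(st, data, sims)))
            assert scores == sorted(scores, reverse=True)

    def test_untestable_cells_count_as_failed(self, rng):
        times = np.arange(3.0)
        data = ExperimentalData(("a",), times, rng.normal(5, 1, (1, 3, 1)))
        sims = SimulationEnsemble(("a",), times, np.abs(rng.normal(5, 1, (4, 3, 1))))
        with pytest.warns(UserWarning, match="untestable"):
            mat = build_rejection_matrix(EquivalenceSettings(test="TOST"), data, sims)
        assert mat.untestable.all() and mat.n_failed == 3

    def test_three_failures_score_three(self, rng):
        data, sims = self._containers(rng, V=1, T=10)
        st = EquivalenceSettings(test="TOST", range_mode="absolute", range_value=1e6)
        mat = build_rejection_matrix(st, data, sims)
        forced = mat.failed.copy()
        forced[0, [1, 4, 7]] = True
        from kinecal.objectives.equivalence import RejectionMatrix
        assert iterative_score(
            RejectionMatrix(mat.observables, mat.times, forced, mat.untestable)) == 3
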