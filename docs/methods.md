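# Methods

`kinecal` calibrates stochastic kinetic models against replicated time-series
data with a genetic algorithm whose fitness functions include statistical
*equivalence tests*.  This note documents the model of the data, the tests,
the search, the synthetic benchmark, and the numerical and design choices a
maintainer or user should know about.

## The data model and the cell decomposition

Experimental data are a tensor of non-negative abundances indexed
(replicate i = 1..m, timepoint t = 1..T, observable v = 1..V) on a strictly
increasing time grid; an ensemble of n stochastic simulations of one
candidate parameter set has the same (T, V) layout.  All fitness functions
decompose over *cells*: one (observable, timepoint) pair holding the m
experimental values `exp_i` and the n simulated values `sim_j`.  Replicate
dispersion σ_exp is always the sample standard deviation (divisor m−1).
Cell scores are summed over all cells without weights; a per-observable
breakdown is available for diagnostics.  Simulators must emit the
experimental time points: alignment is exact matching within a tolerance
(default 1e-9), and interpolation is deliberately not offered because it
would silently smooth stochastic trajectories.

## Algebraic objectives

Nine classical error functions are evaluated per cell (SDA, ADA, PWSD,
APWSD, NPWSD, ANPWSD, SSQ, CHISQ, MNSE; formulas in the README and the
module docstring).  All are non-negative and vanish on a perfect fit where
defined.  Degenerate cells are handled explicitly rather than propagating
infinities:

* CHISQ with σ_exp = 0 and MNSE with x̄_exp = 0 raise at the cell level; in
  whole-dataset aggregation such cells contribute 0 and are counted in a
  diagnostics log.
* NPWSD/ANPWSD terms with exp_i = 0 are dropped and the 1/(mn) divisor is
  reduced to the retained-term count; a cell whose replicates are all zero
  contributes 0 with a warning.  No pseudocounts are invented; this is a
  documented divergence risk against other implementations.

Exact identities used as regression tests: SSQ = mn·PWSD per cell, and
SDA ≤ PWSD (variance decomposition).

## Equivalence tests and the iterative score

A difference test can only ever fail to find a difference; an equivalence
test positively establishes that two distributions differ by *less* than a
margin.  Each test produces one verdict per cell; the *rejection matrix*
collects them and the fitness is the count of cells where equivalence was
not established — an integer in [0, V·T], minimised by the GA.  Untestable
cells (fewer than two values on either side, or an sd-based margin with a
single replicate) count as failed so the bounds hold.  No multiple-testing
correction is applied across cells: the score deliberately counts raw
verdicts.

**TOST.**  The simulated sample is shifted down and up by the margin ε;
equivalence requires the down-shifted sample to test significantly smaller
than the data *and* the up-shifted sample significantly larger, both
one-sided Welch (unequal-variance) t-tests at level α (default 0.05).
Welch rather than pooled variance is a robustness choice and a possible
divergence from other implementations.  With zero dispersion on both sides
the verdict degenerates to |x̄_sim − x̄_exp| < ε; a zero margin can never
declare equivalence.

**DUT.**  The nonparametric analogue: U statistics are counted with ties
weighted ½ per pair (U_exp + U_sims = mn exactly), and each one-sided
p-value comes from the exact null distribution of U (Gaussian-binomial
recurrence) whenever mn ≤ 400, otherwise from the normal approximation with
continuity correction.  The exact/approximate switch is logged in the code
path, not configurable.

**WMWET.**  Wellek's Mann-Whitney test for equivalence asks whether
π = P(sim > exp) lies inside a probability band (p_lo, p_hi) around ½.  The
estimator π̂ counts ties as ½; its variance estimate comes from the pair and
triple concordance statistics

    σ̂² = [π̂ − (m+n−1)π̂² + (n−1)π̂_xxy + (m−1)π̂_xyy] / (mn),

and equivalence is declared when |π̂ − c|/σ̂ falls below the square root of
the α-quantile of the noncentral χ²(1) distribution with noncentrality
((p_hi − p_lo)/(2σ̂))², where c is the band centre.  The default band
(0.19, 0.76) follows the published use of the test.  When σ̂ = 0 the verdict
degenerates to p_lo < π̂ < p_hi.  For extreme noncentralities where the
χ² quantile overflows, the large-noncentrality limit √ncp + z_α is used.
The implementation is validated against an independently coded brute-force
version of the same construction on fixed vector pairs.

**Margins.**  For TOST/DUT the default margin is one sample standard
deviation of the experimental replicates of that cell (`range_mode
"sd_multiple"`, k = 1); an absolute ε is also supported.  Widening the
margin can only decrease the score (regression-tested monotonicity).

## The genetic algorithm

A candidate ("individual") is one vector of free parameters, each declared
with bounds and a sampling law (uniform or log-uniform).  Per iteration,
every new candidate is simulated n_sims times (default 10), scored, and the
population is ranked; ranking is by unweighted sum of per-objective ranks
(minimum/"competition" rank on ties), which for a single objective reduces
to that objective's ordering.  Rank ties break by individual id, so runs
are deterministic.  Failed simulations carry a +∞ sentinel and rank last.

* **Strategy 1 (default, elitist):** the top-E individuals (default 10)
  carry over unchanged *with their cached fitness* — their simulations are
  never repeated.  Both parents are drawn uniformly from the elite
  (self-recombination allowed), recombined at a single uniform cut point,
  and each parameter is redrawn from its sampling law with probability 0.30.
* **Strategy 2:** two *distinct* parents from the whole population with
  inverse-rank probabilities p_i = 1/(r_i Σ_j 1/r_j); otherwise as
  strategy 1; elitism off by default but available.
* **Strategy 3:** as strategy 2 but multi-point crossover (each gene from
  either parent with probability ½) and factor mutation: with probability
  0.20 a parameter is multiplied by a uniform factor in [0.9, 1.1], then
  clipped to bounds.

Mutation is per-parameter Bernoulli.  Under strategy 1 with a single
objective, the population-best fitness is non-increasing by construction;
this is asserted on every run.  RNG discipline: one root seed spawns
independent streams for initialisation, selection, crossover and mutation,
and each candidate's simulation seed is derived from (root seed, iteration
born, candidate id), so neither evaluation order nor worker count can
change any number (serial and multiprocessing dispatch are bit-identical).

## Built-in simulator and the synthetic benchmark

The built-in engine implements the Gillespie direct method for mass-action
networks with integer copy numbers (propensity = rate × falling factorial
of reactant counts; linear propensity scan, numba-compiled).  It is exact,
deterministic per seed, and adequate for networks of desk-scale size; no
tau-leaping, delays or rule-based semantics (external simulators own those
via the command adapter).

The benchmark is the two-species gene-expression cascade: transcription at
rate r1_v (zero order), mRNA decay r2_k1, translation r3_k1 (first order in
mRNA), protein decay r4_k1, with true rates (5, 0.03, 0.1, 0.03) and
stationary means mRNA = r1_v/r2_k1 = 166.7, protein = r1_v·r3_k1/(r2_k1·r4_k1)
= 555.6 (closed forms used as simulator oracles at 3-standard-error
tolerance).  The synthetic-data generator simulates this network from
empty initial conditions (mRNA = Protein = 0) and treats 10 independent
runs as experimental replicates, both species observed.

**Observation grid.**  The default grid is t = 0, 10, …, 200.  The window
covers the transient and the stationary regime; the 10-unit sampling
interval is chosen below a third of the slowest relaxation time
(1/k = 33 time units for the decay rates) so the transient cells constrain
the decay rates.  This matters: with 20-unit spacing we measured that the
equivalence score cannot separate the true rates from a "fast-relaxation
ridge" (all four rates scaled up ~10× with both ratios preserved, so
stationary levels match and only under-sampled transient cells disagree) —
ridge candidates then score as well as the truth and calibration returns
order-of-magnitude rate errors even at large GA budgets.

What the generator does **not** emulate: measurement noise on top of the
process stochasticity, missing observations, unit conversion, or
between-replicate batch effects.  Passing recovery tests therefore shows
that the engine can invert its own generative process, not that it is
robust to real measurement error.

## Parameter-recovery behaviour and its limits

The recovery experiment (10 replicates, all four rates free, log-uniform
search in [1e-2, 1e2], strategy 1 with population 50, 30 iterations, 10
simulations per candidate — problem sizes chosen to keep a full benchmark
run in the minutes range on one CPU) recovers the mRNA parameters r1_v and
r2_k1 to roughly tens of percent with the equivalence-test objectives, but
per-parameter precision is fundamentally limited by the statistics of the
score itself: with m = n = 10 and a one-standard-deviation margin, a
*perfect* candidate passes each TOST cell with probability only ≈ 0.38
(pass requires the ensemble-mean offset to stay below
ε − t_crit·SE ≈ 0.22 σ while that offset fluctuates with SD ≈ 0.45 σ).
Even the true rates therefore fail ~60% of cells, and the integer score's
run-to-run noise (SD ≈ 2–3 cells) is as large as the systematic advantage
of near-true candidates.  Seen from parameter space, the same bound makes
each cell's pass region a needle: a relative rate error δ shifts a transient
cell mean by roughly (k·t)·δ·mean, so with σ/mean of a few percent the pass
window is only ±2–3% in the rate — equivalence objectives are all-or-nothing
within a few percent of truth and flat outside.  The search must therefore
*land* inside the needle (where the recovered precision is then excellent)
rather than descend into it; whether it does is a matter of evaluation
budget and luck, and the weakly coupled protein parameters frequently stay
unconstrained.  Per-parameter errors in the low-teens are consequently not
reliably reproduced at this design; raising n_sims to ~100 would lift the
per-cell pass probability for good candidates to ~0.8 and widen the pass
window, at 10× simulation cost.  The algebraic objectives provide a smooth
gradient and no plateau, but face the same ridge geometry of the model
(rate ratios are far better determined than the rates themselves).

## Uncertainty

The jackknife drops one data unit at a time — the replicate by default (it
is the sampling unit inside every fitness function), optionally a timepoint
— and re-runs the full calibration per reduced dataset with a derived seed.
The bootstrap re-runs the calibration on replicate-resampled datasets
(with replacement, same m) with fresh GA seeds — both data and search
randomness are resampled — and reports percentile intervals; with R runs
the resolution is 1/(R+1), so the default 20 runs support at most a 90%
interval.  Percentile rather than BCa intervals: with ~20 runs higher-order
corrections are noise.  Because the GA itself is stochastic, the point
estimate is not guaranteed to lie inside the interval; every sub-run seed
is recorded so any estimate can be reproduced independently.

## Orchestration

External simulators are driven through a command template with `{model}`,
`{seed}` and `{output}` slots.  Free parameters are annotated in the model
text as `__FREE__<name>` placeholders (simulator-language-agnostic) with a
sidecar YAML declaring bounds and sampling law; rendering substitutes the
exact decimal of each binary double (17 significant digits).  Output
dialects: `gdat` (whitespace table with `#` header), `kasim_csv`, and plain
`tsv`.  Job dispatch keys results by batch position, never completion
order; one failing job becomes a sentinel, the batch continues.  SLURM
integration is specified as an interface stub only (submission template +
polling contract); all testing runs on the local pool and the built-in
engine.

## Numerical choices, in brief

* Exact Mann-Whitney null via the Gaussian-binomial recurrence for
  mn ≤ 400; tie-corrected normal approximation beyond.
* Per-realisation event budget (default 10⁶; 2×10⁵ in the recovery
  benchmark, ≈ 23× the true-rate event count) guards against parameter
  sets whose dynamics explode; such candidates are failed, not truncated.
* Rank ties: minimum rank within objectives, individual id across equal
  combined scores — deterministic end to end.
* Seeds are derived with `numpy.random.SeedSequence` throughout; every
  user-facing derived seed stays below 2³¹.
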